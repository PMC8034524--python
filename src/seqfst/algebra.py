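"""Matrix-like and string-like operations on machines.

Viewing a machine T as an infinite matrix T[x, y] indexed by input and
output sequences, these operations realize the matrix algebra —
composition (matrix product), addition, intersection (pointwise product),
transposition, scalar multiplication, the identity — and the string
algebra: concatenation, reversal, reverse-complement, repetition, Kleene
closure and local (flanked) matching.

Every constructor prunes unreachable states and re-establishes the
topologically-sorted silent subgraph via :func:`seqfst.normalize.tidy`.
"""

from __future__ import annotations

from typing import Iterable

from .core import Machine, Transition, machine, transition
from .expr import Const, ExprLike, UnassignedParameterError, as_expr, mul as expr_mul
from .normalize import tidy
from . import inference

DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


class AlphabetMismatchError(ValueError):
    pass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise AlphabetMismatchError(msg)


def _rename(m: Machine, prefix: str) -> Machine:
    mapping = {s: f"{prefix}{s}" for s in m.states}
    return m.with_(
        states=tuple(mapping[s] for s in m.states),
        transitions=tuple(Transition(mapping[t.src], t.inp, t.out,
                                     mapping[t.dst], t.weight)
                          for t in m.transitions))


def compose(t: Machine, u: Machine) -> Machine:
    """Matrix product TU: (TU)[x, z] = sum over y of T[x, y] * U[y, z].

    Requires T's output alphabet to equal U's input alphabet.  Composite
    states are (T-state, U-state, phase) triples; the phase bit is the
    standard epsilon filter that canonicalizes interleavings of T's
    output-epsilon moves and U's input-epsilon moves so each joint path is
    counted exactly once: from phase 0 both kinds of lone move are
    allowed, a lone U move sets phase 1, from which lone T moves are
    barred until a synchronized symbol exchange resets phase 0.
    """
    _require(set(t.output_alphabet) == set(u.input_alphabet),
             f"compose: T's output alphabet {t.output_alphabet!r} != "
             f"U's input alphabet {u.input_alphabet!r}")
    t_out = t.out_transitions()
    u_out = u.out_transitions()
    u_by_in: dict[str, dict[str, list[Transition]]] = {}
    for s, ts in u_out.items():
        d: dict[str, list[Transition]] = {}
        for tr in ts:
            if tr.inp is not None:
                d.setdefault(tr.inp, []).append(tr)
        u_by_in[s] = d

    def sid(a: str, b: str, ph: int) -> str:
        return f"({a}|{b}|{ph})"

    start = (t.start, u.start, 0)
    states: list[tuple[str, str, int]] = [start]
    seen = {start}
    transitions: list[Transition] = []
    stack = [start]
    while stack:
        a, b, ph = stack.pop()
        src = sid(a, b, ph)

        def emit(dst_key, inp, out, w):
            if dst_key not in seen:
                seen.add(dst_key)
                states.append(dst_key)
                stack.append(dst_key)
            transitions.append(Transition(src, inp, out, sid(*dst_key), w))

        for ta in t_out[a]:
            if ta.out is None:
                if ph == 0:  # lone T move, only from phase 0
                    emit((ta.dst, b, 0), ta.inp, None, ta.weight)
            else:
                for ub in u_by_in[b].get(ta.out, ()):  # synchronized exchange
                    emit((ta.dst, ub.dst, 0), ta.inp, ub.out,
                         expr_mul(ta.weight, ub.weight))
        for ub in u_out[b]:
            if ub.inp is None:  # lone U move sets phase 1
                emit((a, ub.dst, 1), None, ub.out, ub.weight)
    # wire every reachable (t.end, u.end, phase) pair into a fresh end state
    end_id = "(end)"
    state_ids = [sid(*s) for s in states]
    for a, b, ph in states:
        if a == t.end and b == u.end:
            transitions.append(transition(sid(a, b, ph), None, None, end_id, 1.0))
    state_ids.append(end_id)
    out = machine(t.input_alphabet, u.output_alphabet, state_ids, transitions,
                  t.params.merge(u.params))
    return tidy(out)


def intersect(t: Machine, u: Machine) -> Machine:
    """Pointwise (Hadamard) product: (T o U)[x, y] = T[x, y] * U[x, y].

    Requires equal input and output alphabets.  Implemented as a
    label-synchronized product with the same epsilon-phase filter as
    :func:`compose`; exact for recognizers, generators and machines whose
    non-silent transitions are letter-synchronized on both tapes.
    """
    _require(set(t.input_alphabet) == set(u.input_alphabet)
             and set(t.output_alphabet) == set(u.output_alphabet),
             "intersect: machines must share input and output alphabets")
    t_out = t.out_transitions()
    u_out = u.out_transitions()

    def sid(a, b, ph):
        return f"({a}&{b}|{ph})"

    start = (t.start, u.start, 0)
    states = [start]
    seen = {start}
    transitions: list[Transition] = []
    stack = [start]
    while stack:
        a, b, ph = stack.pop()
        src = sid(a, b, ph)

        def emit(dst_key, inp, out, w):
            if dst_key not in seen:
                seen.add(dst_key)
                states.append(dst_key)
                stack.append(dst_key)
            transitions.append(Transition(src, inp, out, sid(*dst_key), w))

        for ta in t_out[a]:
            if ta.is_silent:
                if ph == 0:
                    emit((ta.dst, b, 0), None, None, ta.weight)
            else:
                for ub in u_out[b]:
                    if not ub.is_silent and ub.inp == ta.inp and ub.out == ta.out:
                        emit((ta.dst, ub.dst, 0), ta.inp, ta.out,
                             expr_mul(ta.weight, ub.weight))
        for ub in u_out[b]:
            if ub.is_silent:
                emit((a, ub.dst, 1), None, None, ub.weight)
    end_id = "(end)"
    state_ids = [sid(*s) for s in states]
    for a, b, ph in states:
        if a == t.end and b == u.end:
            transitions.append(transition(sid(a, b, ph), None, None, end_id, 1.0))
    state_ids.append(end_id)
    out = machine(t.input_alphabet, t.output_alphabet, state_ids, transitions,
                  t.params.merge(u.params))
    return tidy(out)


def add(t: Machine, u: Machine) -> Machine:
    """Matrix sum: (T + U)[x, y] = T[x, y] + U[x, y]."""
    _require(set(t.input_alphabet) == set(u.input_alphabet)
             and set(t.output_alphabet) == set(u.output_alphabet),
             "add: machines must share input and output alphabets")
    a, b = _rename(t, "L."), _rename(u, "R.")
    states = ["(start)"] + list(a.states) + list(b.states) + ["(end)"]
    transitions = list(a.transitions) + list(b.transitions) + [
        transition("(start)", None, None, a.start, 1.0),
        transition("(start)", None, None, b.start, 1.0),
        transition(a.end, None, None, "(end)", 1.0),
        transition(b.end, None, None, "(end)", 1.0),
    ]
    out = machine(t.input_alphabet, t.output_alphabet, states, transitions,
                  t.params.merge(u.params))
    return tidy(out)


def transpose(t: Machine) -> Machine:
    """Exchange the input and output tapes: transpose(T)[y, x] = T[x, y]."""
    return t.with_(
        input_alphabet=t.output_alphabet,
        output_alphabet=t.input_alphabet,
        transitions=tuple(Transition(tr.src, tr.out, tr.inp, tr.dst, tr.weight)
                          for tr in t.transitions))


def concat(t: Machine, u: Machine) -> Machine:
    """String concatenation: paths of T followed by paths of U, joined by a
    silent weight-1 transition from T's end to U's start."""
    _require(set(t.input_alphabet) == set(u.input_alphabet)
             and set(t.output_alphabet) == set(u.output_alphabet),
             "concat: machines must share input and output alphabets")
    a, b = _rename(t, "L."), _rename(u, "R.")
    states = list(a.states) + list(b.states)
    transitions = (list(a.transitions)
                   + [transition(a.end, None, None, b.start, 1.0)]
                   + list(b.transitions))
    out = machine(t.input_alphabet, t.output_alphabet, states, transitions,
                  t.params.merge(u.params))
    return tidy(out)


def reverse(t: Machine) -> Machine:
    """Reverse both tapes: reverse(T)[rev(x), rev(y)] = T[x, y].
    Every transition is flipped and the state order reversed (so start and
    end swap)."""
    out = t.with_(
        states=tuple(reversed(t.states)),
        transitions=tuple(Transition(tr.dst, tr.inp, tr.out, tr.src, tr.weight)
                          for tr in t.transitions))
    return tidy(out)


def _complement_map(alphabet: tuple[str, ...]) -> dict[str, str] | None:
    s = set(alphabet)
    if not s:
        return None
    if s <= set("ACGT"):
        return DNA_COMPLEMENT
    if s <= set("ACGU"):
        return RNA_COMPLEMENT
    raise ValueError(f"alphabet {alphabet!r} is not nucleic; cannot complement")


def reverse_complement(t: Machine) -> Machine:
    """Reverse, then substitute Watson-Crick complements on every tape whose
    alphabet is nucleic (DNA or RNA).  A non-empty, non-nucleic tape is an
    error."""
    comp_in = _complement_map(t.input_alphabet)
    comp_out = _complement_map(t.output_alphabet)
    r = reverse(t)

    def cc(label, comp):
        return comp[label] if (label is not None and comp is not None) else label

    return r.with_(transitions=tuple(
        Transition(tr.src, cc(tr.inp, comp_in), cc(tr.out, comp_out),
                   tr.dst, tr.weight)
        for tr in r.transitions))


def kleene_star(t: Machine) -> Machine:
    """Kleene closure: T* = sum over n >= 0 of T^n.

    Realized with a silent bypass (the n=0 term) and a silent back
    transition from T's end to its start.  If T's weight on the empty pair
    is numerically >= 1 the closure diverges and an error is raised; with
    symbolic weights divergence detection is deferred to normalization.
    """
    try:
        eps_lw = inference.forward(tidy(t), "", "").log_weight
    except (inference.UnsortedSilentError, UnassignedParameterError):
        eps_lw = None  # symbolic weights: defer divergence detection to normalize
    if eps_lw is not None and eps_lw >= 0.0:
        raise ValueError(
            f"kleene_star: machine's weight on the empty pair is "
            f"exp({eps_lw:.6g}) >= 1; the closure diverges")
    a = _rename(t, "S.")
    states = ["(start)"] + list(a.states) + ["(end)"]
    transitions = list(a.transitions) + [
        transition("(start)", None, None, a.start, 1.0),
        transition("(start)", None, None, "(end)", 1.0),
        transition(a.end, None, None, "(end)", 1.0),
        transition(a.end, None, None, a.start, 1.0),
    ]
    out = machine(t.input_alphabet, t.output_alphabet, states, transitions, t.params)
    return tidy(out)


def repeat_n(t: Machine, n: int) -> Machine:
    """n-fold concatenation of T (n >= 1)."""
    if n < 1:
        raise ValueError(f"repeat_n: n must be >= 1, got {n}")
    out = t
    for _ in range(n - 1):
        out = concat(out, t)
    return out


def scale(alpha: ExprLike, t: Machine) -> Machine:
    """Scalar multiple: (alpha T)[x, y] = alpha * T[x, y].
    alpha may be a non-negative number or a (possibly symbolic) parameter."""
    e = as_expr(alpha)
    if isinstance(e, Const) and e.value < 0:
        raise ValueError(f"scale: negative scalar {e.value!r}")
    a = _rename(t, "S.")
    states = ["(start)"] + list(a.states)
    transitions = [transition("(start)", None, None, a.start, e)] + list(a.transitions)
    out = machine(t.input_alphabet, t.output_alphabet, states, transitions, t.params)
    return tidy(out)


def identity_machine(alphabet: Iterable[str]) -> Machine:
    """The matrix identity for an alphabet: weight 1 when x == y, else 0.
    A single looping state copying each symbol from input to output."""
    alphabet = tuple(alphabet)
    if not alphabet:
        raise ValueError("identity_machine: alphabet must be non-empty")
    trans = [transition("id", c, c, "id", 1.0) for c in alphabet]
    return machine(alphabet, alphabet, ["id"], trans)


def local_flank(t: Machine) -> Machine:
    """Pad a recognizer or generator with weight-1 wildcard self-loops on
    both sides, so the pattern matches anywhere within a longer sequence."""
    if t.is_generator and not t.is_recognizer:
        alphabet, tape = t.output_alphabet, "out"
    elif t.is_recognizer and not t.is_generator:
        alphabet, tape = t.input_alphabet, "in"
    else:
        raise ValueError("local_flank: machine must be a generator or a "
                         "recognizer (exactly one empty alphabet)")
    loops = [transition("w", c if tape == "in" else None,
                        c if tape == "out" else None, "w", 1.0)
             for c in alphabet]
    flank = machine(t.input_alphabet, t.output_alphabet, ["w"], loops)
    return concat(flank, concat(t, flank))
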