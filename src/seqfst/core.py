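"""Machine data model.

A *machine* is a weighted finite-state transducer: a tuple of an input
alphabet, an output alphabet, an ordered list of states (the first is the
start state, the last is the end state; they coincide for single-state
machines), a set of labelled weighted transitions, and a parameter model.
Each transition carries an input label and an output label, either of
which may be epsilon (represented as ``None``), and a weight expression
over named parameters.

A machine assigns every pair of sequences (x, y) a weight T[x, y]: the
total weight of all start-to-end transition paths whose input labels
concatenate to x and output labels to y.  Machines thus behave like
infinite matrices indexed by sequences, and the operations in
:mod:`seqfst.algebra` combine them accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .expr import Expr, ExprLike, as_expr

EPSILON = None  # epsilon labels are represented by None at the API boundary

PROB_SUM_TOL = 1e-9  # absolute tolerance for probability groups summing to 1


@dataclass(frozen=True)
class Transition:
    """One labelled weighted transition.

    ``inp``/``out`` are single-character symbols or ``None`` for epsilon.
    A transition with both labels epsilon is *silent*; one with both labels
    non-epsilon is *IO-conditioned*.
    """

    src: str
    inp: str | None
    out: str | None
    dst: str
    weight: Expr

    @property
    def is_silent(self) -> bool:
        return self.inp is None and self.out is None

    @property
    def is_io_conditioned(self) -> bool:
        return self.inp is not None and self.out is not None

    def __repr__(self) -> str:
        i = self.inp if self.inp is not None else "ε"
        o = self.out if self.out is not None else "ε"
        return f"Transition({self.src!r} --{i}/{o}--> {self.dst!r}, w={self.weight.to_json()!r})"


def transition(src: str, inp: str | None, out: str | None, dst: str,
               weight: ExprLike = 1.0) -> Transition:
    """Convenience constructor coercing the weight to an expression."""
    return Transition(src, inp, out, dst, as_expr(weight))


@dataclass(frozen=True)
class ParamModel:
    """Named parameters, numeric assignments, and constraint classes.

    ``values`` may be partial; unassigned parameters are symbolic.
    ``prob_groups`` are disjoint groups each constrained to sum to 1
    (these are the parameters EM can train); ``rates`` are constrained
    non-negative; everything else is free.
    """

    values: Mapping[str, float] = field(default_factory=dict)
    prob_groups: tuple[tuple[str, ...], ...] = ()
    rates: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "prob_groups",
                           tuple(tuple(g) for g in self.prob_groups))
        object.__setattr__(self, "rates", tuple(self.rates))

    def violations(self) -> list[str]:
        out = []
        seen: dict[str, str] = {}
        for gi, group in enumerate(self.prob_groups):
            for name in group:
                if name in seen:
                    out.append(f"parameter {name!r} appears in more than one "
                               f"constraint class ({seen[name]} and prob_group {gi})")
                seen[name] = f"prob_group {gi}"
            assigned = [self.values[n] for n in group if n in self.values]
            if len(assigned) == len(group) and group:
                total = sum(assigned)
                if abs(total - 1.0) > PROB_SUM_TOL:
                    out.append(f"prob_group {gi} {tuple(group)} sums to {total!r}, not 1")
        for name in self.rates:
            if name in seen:
                out.append(f"parameter {name!r} appears in more than one "
                           f"constraint class ({seen[name]} and rates)")
            seen[name] = "rates"
            if name in self.values and self.values[name] < 0:
                out.append(f"rate parameter {name!r} assigned negative value")
        return out

    def assigned(self, extra: Mapping[str, float] | None = None) -> dict[str, float]:
        env = dict(self.values)
        if extra:
            env.update(extra)
        return env

    def merge(self, other: "ParamModel") -> "ParamModel":
        """Union of two parameter models; clashing names must agree on values."""
        values = dict(self.values)
        for k, v in other.values.items():
            if k in values and values[k] != v:
                raise ValueError(f"conflicting assignments for parameter {k!r}: "
                                 f"{values[k]!r} vs {v!r}")
            values[k] = v
        groups = list(self.prob_groups)
        for g in other.prob_groups:
            if g not in groups:
                groups.append(g)
        rates = tuple(dict.fromkeys(self.rates + other.rates))
        return ParamModel(values, tuple(groups), rates)


@dataclass(frozen=True)
class Machine:
    """A weighted finite-state input/output machine.

    ``states`` is an ordered tuple of string identifiers: the first is the
    start state and the last the end state.  An empty ``input_alphabet``
    makes the machine a generator, an empty ``output_alphabet`` a
    recognizer.
    """

    input_alphabet: tuple[str, ...]
    output_alphabet: tuple[str, ...]
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    params: ParamModel = field(default_factory=ParamModel)

    def __post_init__(self):
        object.__setattr__(self, "input_alphabet", tuple(self.input_alphabet))
        object.__setattr__(self, "output_alphabet", tuple(self.output_alphabet))
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "transitions", tuple(self.transitions))

    @property
    def start(self) -> str:
        return self.states[0]

    @property
    def end(self) -> str:
        return self.states[-1]

    @property
    def is_generator(self) -> bool:
        return len(self.input_alphabet) == 0

    @property
    def is_recognizer(self) -> bool:
        return len(self.output_alphabet) == 0

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}

    def out_transitions(self) -> dict[str, list[Transition]]:
        out: dict[str, list[Transition]] = {s: [] for s in self.states}
        for t in self.transitions:
            out[t.src].append(t)
        return out

    def silent_transitions(self) -> list[Transition]:
        return [t for t in self.transitions if t.is_silent]

    def with_(self, **kw) -> "Machine":
        return replace(self, **kw)

    def __repr__(self) -> str:
        return (f"Machine(|Ω_I|={len(self.input_alphabet)}, "
                f"|Ω_O|={len(self.output_alphabet)}, "
                f"states={len(self.states)}, transitions={len(self.transitions)})")


def machine(input_alphabet: Iterable[str], output_alphabet: Iterable[str],
            states: Sequence[str], transitions: Iterable[Transition],
            params: ParamModel | None = None) -> Machine:
    return Machine(tuple(input_alphabet), tuple(output_alphabet),
                   tuple(states), tuple(transitions),
                   params if params is not None else ParamModel())


def validate_machine(m: Machine) -> list[str]:
    """Return every invariant violation; an empty list means the machine is valid.

    Checked: non-empty ordered state list with unique identifiers; every
    transition endpoint names a declared state; every non-epsilon label lies
    in the corresponding alphabet; every parameter referenced by a weight is
    declared (assigned, in a probability group, or a rate); the parameter
    model's own constraints hold.
    """
    out: list[str] = []
    if not m.states:
        out.append("machine has no states (the state list must be non-empty)")
        return out
    seen_states = set()
    for s in m.states:
        if not isinstance(s, str) or not s:
            out.append(f"state identifier {s!r} is not a non-empty string")
        if s in seen_states:
            out.append(f"duplicate state identifier {s!r}")
        seen_states.add(s)
    in_alpha, out_alpha = set(m.input_alphabet), set(m.output_alphabet)
    if len(in_alpha) != len(m.input_alphabet):
        out.append("input alphabet contains duplicate symbols")
    if len(out_alpha) != len(m.output_alphabet):
        out.append("output alphabet contains duplicate symbols")
    declared = set(m.params.values)
    for g in m.params.prob_groups:
        declared.update(g)
    declared.update(m.params.rates)
    for i, t in enumerate(m.transitions):
        where = f"transition {i} ({t!r})"
        if t.src not in seen_states:
            out.append(f"{where}: source state {t.src!r} is not declared")
        if t.dst not in seen_states:
            out.append(f"{where}: destination state {t.dst!r} is not declared")
        if t.inp is not None and t.inp not in in_alpha:
            out.append(f"{where}: input label {t.inp!r} not in input alphabet")
        if t.out is not None and t.out not in out_alpha:
            out.append(f"{where}: output label {t.out!r} not in output alphabet")
        for name in t.weight.params():
            if name not in declared:
                out.append(f"{where}: weight references undeclared parameter {name!r}")
    out.extend(m.params.violations())
    return out


@dataclass(frozen=True)
class MachineStats:
    n_states: int
    n_transitions: int
    n_io_conditioned: int


def machine_stats(m: Machine) -> MachineStats:
    """Count states, transitions, and IO-conditioned (both-labels-non-epsilon)
    transitions — the sizes conventionally reported for these models."""
    return MachineStats(
        n_states=len(m.states),
        n_transitions=len(m.transitions),
        n_io_conditioned=sum(1 for t in m.transitions if t.is_io_conditioned),
    )


def evaluate_weight(e: Expr, p: ParamModel | Mapping[str, float]) -> float:
    """Evaluate a weight expression under a parameter assignment.

    Raises :class:`~seqfst.expr.UnassignedParameterError` naming the first
    missing parameter, and :class:`~seqfst.expr.WeightDomainError` if the
    result is negative, NaN or infinite.
    """
    env = p.values if isinstance(p, ParamModel) else p
    return e.evaluate(env)


def differentiate_weight(e: Expr, name: str) -> Expr:
    """Symbolic partial derivative of a weight expression."""
    return e.diff(name)
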