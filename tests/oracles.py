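"""Independent brute-force oracles and random-machine generators.

The oracles compute sequence weights by naive recursive path enumeration
over the raw transition list — no dynamic-programming tables, no
topological ordering, no silent-closure algebra — so they can stand as
independent ground truth for the Forward/Viterbi recurrences and the
machine-algebra identities.
"""

from __future__ import annotations

import itertools

import numpy as np

from seqfst.core import Machine, machine, transition


def brute_force_forward(m: Machine, x: str, y: str,
                        env: dict | None = None) -> float:
    """Total weight of all start-to-end walks labelled (x, y), by direct
    recursion.  Exact when the silent subgraph is acyclic (every cycle
    then consumes labels, so walks for a fixed pair are finitely many)."""
    env = dict(m.params.values, **(env or {}))
    out = m.out_transitions()
    weights = {id(t): t.weight.evaluate(env) for ts in out.values() for t in ts}
    end = m.end
    limit = (len(x) + len(y) + 1) * len(m.states) + len(m.states)

    def rec(state: str, i: int, j: int, depth: int) -> float:
        total = 1.0 if (state == end and i == len(x) and j == len(y)) else 0.0
        if depth >= limit:
            return total
        for t in out[state]:
            w = weights[id(t)]
            if w == 0.0:
                continue
            i2, j2 = i, j
            if t.inp is not None:
                if i >= len(x) or x[i] != t.inp:
                    continue
                i2 = i + 1
            if t.out is not None:
                if j >= len(y) or y[j] != t.out:
                    continue
                j2 = j + 1
            total += w * rec(t.dst, i2, j2, depth + 1)
        return total

    return rec(m.start, 0, 0, 0)


def brute_force_best_path(m: Machine, x: str, y: str,
                          env: dict | None = None) -> float:
    """Maximum single-walk weight labelled (x, y), by direct recursion."""
    env = dict(m.params.values, **(env or {}))
    out = m.out_transitions()
    end = m.end
    limit = (len(x) + len(y) + 1) * len(m.states) + len(m.states)

    def rec(state: str, i: int, j: int, depth: int) -> float:
        best = 1.0 if (state == end and i == len(x) and j == len(y)) else 0.0
        if depth >= limit:
            return best
        for t in out[state]:
            w = t.weight.evaluate(env)
            if w == 0.0:
                continue
            i2, j2 = i, j
            if t.inp is not None:
                if i >= len(x) or x[i] != t.inp:
                    continue
                i2 = i + 1
            if t.out is not None:
                if j >= len(y) or y[j] != t.out:
                    continue
                j2 = j + 1
            best = max(best, w * rec(t.dst, i2, j2, depth + 1))
        return best

    return rec(m.start, 0, 0, 0)


def all_strings(alphabet, max_len: int):
    for n in range(max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)


def enumerate_output_weights(m: Machine, max_len: int,
                             env: dict | None = None) -> dict[str, float]:
    """All generator output weights up to a length, via the path oracle."""
    assert m.is_generator
    return {y: w for y in all_strings(m.output_alphabet, max_len)
            if (w := brute_force_forward(m, "", y, env)) > 0.0}


def random_machine(rng: np.random.Generator, n_states: int = 4,
                   in_alpha: str = "ab", out_alpha: str = "xy",
                   n_trans: int = 8, acyclic: bool = False) -> Machine:
    """A random small machine with a topologically-sorted silent subgraph.

    Silent transitions only ever go to strictly later states, so the
    machine is directly usable by the Forward recurrence; with
    ``acyclic=True`` all transitions go forward, bounding path lengths.
    A skeleton start-to-end transition keeps the machine non-trivial.
    """
    states = [f"s{i}" for i in range(n_states)]
    trans = []
    # skeleton: guarantee some accepting path
    skel_inp = in_alpha[0] if in_alpha else None
    skel_out = out_alpha[0] if out_alpha else None
    trans.append(transition(states[0], skel_inp, skel_out, states[-1],
                            round(float(rng.uniform(0.1, 1.0)), 3)))
    for _ in range(n_trans):
        i = int(rng.integers(0, n_states))
        j = int(rng.integers(0, n_states))
        kind = int(rng.integers(0, 4))
        inp = str(rng.choice(list(in_alpha))) if (kind in (1, 3) and in_alpha) else None
        out = str(rng.choice(list(out_alpha))) if (kind in (2, 3) and out_alpha) else None
        if (inp is None and out is None) or acyclic:
            if i >= j:
                continue  # keep silent subgraph (or everything) a sorted DAG
        trans.append(transition(states[i], inp, out, states[j],
                                round(float(rng.uniform(0.1, 1.0)), 3)))
    return machine(tuple(in_alpha), tuple(out_alpha), states, trans)


def ctc_collapse(frames: str, blank: str = "-") -> str:
    """CTC collapsing rule: merge adjacent repeats, then delete blanks."""
    merged = [c for c, _ in itertools.groupby(frames)]
    return "".join(c for c in merged if c != blank)


def ctc_oracle_weight(P: np.ndarray, alphabet: str, y: str) -> float:
    """Total weight of all framewise paths collapsing to y, by exhaustive
    enumeration over (|alphabet|+1)^T paths."""
    T = P.shape[0]
    symbols = list(alphabet) + ["-"]
    total = 0.0
    for path in itertools.product(range(len(symbols)), repeat=T):
        if ctc_collapse("".join(symbols[k] for k in path)) == y:
            w = 1.0
            for t, k in enumerate(path):
                w *= P[t, k]
            total += w
    return total
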