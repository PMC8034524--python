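"""Dynamic programming over (machine, input sequence, output sequence).

All recurrences run in natural-log space with a -inf sentinel for zero
weight, over cells (i, j, state) where i symbols of the input and j
symbols of the output have been consumed/emitted.  Silent transitions are
resolved within a cell by sweeping states in list order, which is why the
silent subgraph must be acyclic and topologically sorted (see
:mod:`seqfst.normalize`).

Provided algorithms: Forward (total path weight), Viterbi (best single
path with traceback), Forward-Backward (posterior expected transition
counts and parameter gradients), and constrained Baum-Welch EM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Machine, ParamModel, Transition
from .expr import UnassignedParameterError

NEG_INF = float("-inf")


@dataclass
class DPResult:
    """Results of dynamic programming on one (x, y) pair.

    ``log_weight`` is ln T[x, y] (total weight of all labelled paths);
    ``best_log_weight`` is the log-weight of the single best path and is
    never above ``log_weight``; ``expected_counts`` maps transition index
    (into ``machine.transitions``) to posterior expected usage; and
    ``gradients`` maps parameter name to dT[x, y]/dparam on the linear
    scale.
    """

    log_weight: float = NEG_INF
    best_log_weight: float = NEG_INF
    best_path: list[Transition] = field(default_factory=list)
    expected_counts: dict[int, float] = field(default_factory=dict)
    gradients: dict[str, float] = field(default_factory=dict)


class UnsortedSilentError(ValueError):
    """The silent subgraph is not topologically sorted in state-list order."""


def _check_silent_sorted(m: Machine) -> None:
    idx = m.state_index()
    for t in m.transitions:
        if t.is_silent and idx[t.src] >= idx[t.dst]:
            raise UnsortedSilentError(
                f"silent transition {t!r} goes from state index {idx[t.src]} "
                f"to {idx[t.dst]}; run normalize.toposort_silent (or "
                "eliminate/break silent cycles) first")


def _log_weights(m: Machine, p: ParamModel | Mapping[str, float] | None) -> list[float]:
    if p is None:
        env = m.params.values
    elif isinstance(p, ParamModel):
        env = m.params.assigned(p.values)
    else:
        env = m.params.assigned(p)
    out = []
    for t in m.transitions:
        w = t.weight.evaluate(env)
        out.append(math.log(w) if w > 0 else NEG_INF)
    return out


def _grouped(m: Machine):
    """Transitions grouped by the DP cell offset they induce."""
    idx = m.state_index()
    silent, in_only, out_only, io = [], {}, {}, {}
    for ti, t in enumerate(m.transitions):
        rec = (ti, idx[t.src], idx[t.dst])
        if t.is_silent:
            silent.append(rec)
        elif t.out is None:
            in_only.setdefault(t.inp, []).append(rec)
        elif t.inp is None:
            out_only.setdefault(t.out, []).append(rec)
        else:
            io.setdefault((t.inp, t.out), []).append(rec)
    silent.sort(key=lambda r: r[1])  # topological sweep order
    return silent, in_only, out_only, io


def forward(m: Machine, x: Sequence[str], y: Sequence[str],
            p: ParamModel | Mapping[str, float] | None = None) -> DPResult:
    """Total log-weight of all paths with input label x and output label y.

    Runs in O(|x| * |y| * |transitions|) time with log-sum-exp
    accumulation.  Returns -inf if no accepting path exists.
    """
    F = _forward_table(m, x, y, p)
    return DPResult(log_weight=F[len(x), len(y), len(m.states) - 1])


def _forward_table(m, x, y, p) -> np.ndarray:
    _check_silent_sorted(m)
    lw = _log_weights(m, p)
    silent, in_only, out_only, io = _grouped(m)
    X, Y, n = len(x), len(y), len(m.states)
    F = np.full((X + 1, Y + 1, n), NEG_INF)
    for i in range(X + 1):
        for j in range(Y + 1):
            cell = F[i, j]
            if i == 0 and j == 0:
                cell[0] = 0.0
            if i > 0:
                for ti, s, d in in_only.get(x[i - 1], ()):
                    cell[d] = np.logaddexp(cell[d], F[i - 1, j, s] + lw[ti])
            if j > 0:
                for ti, s, d in out_only.get(y[j - 1], ()):
                    cell[d] = np.logaddexp(cell[d], F[i, j - 1, s] + lw[ti])
            if i > 0 and j > 0:
                for ti, s, d in io.get((x[i - 1], y[j - 1]), ()):
                    cell[d] = np.logaddexp(cell[d], F[i - 1, j - 1, s] + lw[ti])
            for ti, s, d in silent:  # sorted so sources are final before use
                if cell[s] > NEG_INF:
                    cell[d] = np.logaddexp(cell[d], cell[s] + lw[ti])
    return F


def _backward_table(m, x, y, p) -> np.ndarray:
    _check_silent_sorted(m)
    lw = _log_weights(m, p)
    silent, in_only, out_only, io = _grouped(m)
    X, Y, n = len(x), len(y), len(m.states)
    B = np.full((X + 1, Y + 1, n), NEG_INF)
    B[X, Y, n - 1] = 0.0
    rev_silent = list(reversed(silent))
    for i in range(X, -1, -1):
        for j in range(Y, -1, -1):
            cell = B[i, j]
            if i < X:
                for ti, s, d in in_only.get(x[i], ()):
                    cell[s] = np.logaddexp(cell[s], lw[ti] + B[i + 1, j, d])
            if j < Y:
                for ti, s, d in out_only.get(y[j], ()):
                    cell[s] = np.logaddexp(cell[s], lw[ti] + B[i, j + 1, d])
            if i < X and j < Y:
                for ti, s, d in io.get((x[i], y[j]), ()):
                    cell[s] = np.logaddexp(cell[s], lw[ti] + B[i + 1, j + 1, d])
            for ti, s, d in rev_silent:  # reverse topological sweep
                if cell[d] > NEG_INF:
                    cell[s] = np.logaddexp(cell[s], lw[ti] + cell[d])
    return B


def viterbi(m: Machine, x: Sequence[str], y: Sequence[str],
            p: ParamModel | Mapping[str, float] | None = None) -> DPResult:
    """Best single path with input label x and output label y, with traceback.

    Ties are broken in favour of the transition earliest in serialized
    order (the recurrence keeps the first maximum it sees).  Returns a
    -inf sentinel and an empty path when no accepting path exists.
    """
    _check_silent_sorted(m)
    lw = _log_weights(m, p)
    silent, in_only, out_only, io = _grouped(m)
    X, Y, n = len(x), len(y), len(m.states)
    V = np.full((X + 1, Y + 1, n), NEG_INF)
    ptr: dict[tuple[int, int, int], tuple[int, int, int, int]] = {}

    def relax(i, j, d, cand, ti, pi, pj, ps):
        if cand > V[i, j, d]:
            V[i, j, d] = cand
            ptr[(i, j, d)] = (ti, pi, pj, ps)

    for i in range(X + 1):
        for j in range(Y + 1):
            if i == 0 and j == 0:
                V[0, 0, 0] = 0.0
            if i > 0:
                for ti, s, d in in_only.get(x[i - 1], ()):
                    relax(i, j, d, V[i - 1, j, s] + lw[ti], ti, i - 1, j, s)
            if j > 0:
                for ti, s, d in out_only.get(y[j - 1], ()):
                    relax(i, j, d, V[i, j - 1, s] + lw[ti], ti, i, j - 1, s)
            if i > 0 and j > 0:
                for ti, s, d in io.get((x[i - 1], y[j - 1]), ()):
                    relax(i, j, d, V[i - 1, j - 1, s] + lw[ti], ti, i - 1, j - 1, s)
            for ti, s, d in silent:
                if V[i, j, s] > NEG_INF:
                    relax(i, j, d, V[i, j, s] + lw[ti], ti, i, j, s)

    best = V[X, Y, n - 1]
    if best == NEG_INF:
        return DPResult(best_log_weight=NEG_INF, best_path=[])
    path: list[Transition] = []
    node = (X, Y, n - 1)
    while node != (0, 0, 0):
        ti, pi, pj, ps = ptr[node]
        path.append(m.transitions[ti])
        node = (pi, pj, ps)
    path.reverse()
    return DPResult(best_log_weight=float(best), best_path=path)


def forward_backward(m: Machine, x: Sequence[str], y: Sequence[str],
                     p: ParamModel | Mapping[str, float] | None = None) -> DPResult:
    """Posterior expected transition counts and parameter gradients.

    ``expected_counts[ti]`` is the expected number of uses of transition
    ``m.transitions[ti]`` over paths labelled (x, y); ``gradients[name]``
    is dT[x, y]/dname, assembled from the expected counts and the symbolic
    derivatives of the transition weight expressions.  All transition
    weights must be numeric under the parameter assignment.
    """
    env = m.params.assigned(p.values if isinstance(p, ParamModel) else (p or {}))
    F = _forward_table(m, x, y, p)
    B = _backward_table(m, x, y, p)
    X, Y, n = len(x), len(y), len(m.states)
    logZ = F[X, Y, n - 1]
    if logZ == NEG_INF:
        raise ValueError(f"pair ({''.join(x)!r}, {''.join(y)!r}) has zero weight; "
                         "expected counts are undefined")
    idx = m.state_index()
    lw = _log_weights(m, p)
    counts: dict[int, float] = {}
    for ti, t in enumerate(m.transitions):
        if lw[ti] == NEG_INF:
            counts[ti] = 0.0
            continue
        di = 0 if t.inp is None else 1
        dj = 0 if t.out is None else 1
        s, d = idx[t.src], idx[t.dst]
        acc = NEG_INF
        for i in range(X + 1 - di):
            for j in range(Y + 1 - dj):
                if di and x[i] != t.inp:
                    continue
                if dj and y[j] != t.out:
                    continue
                a = F[i, j, s]
                b = B[i + di, j + dj, d]
                if a > NEG_INF and b > NEG_INF:
                    acc = np.logaddexp(acc, a + lw[ti] + b)
        counts[ti] = float(math.exp(acc - logZ)) if acc > NEG_INF else 0.0

    Z = math.exp(logZ)
    grads: dict[str, float] = {}
    for ti, t in enumerate(m.transitions):
        names = t.weight.params()
        if not names or counts[ti] == 0.0:
            continue
        w = t.weight.evaluate(env)
        for name in names:
            dw = t.weight.diff(name).evaluate_signed(env)
            if dw != 0.0 and w > 0.0:
                grads[name] = grads.get(name, 0.0) + counts[ti] * Z * dw / w
    result = DPResult(log_weight=float(logZ), expected_counts=counts, gradients=grads)
    return result


def fit_em(m: Machine, data: Sequence[tuple[Sequence[str], Sequence[str]]],
           p0: ParamModel | Mapping[str, float] | None = None,
           max_iters: int = 100, tol: float = 1e-6,
           ) -> tuple[ParamModel, list[float]]:
    """Constrained Baum-Welch: fit probability-group parameters to data.

    Trainable parameters are exactly those in the machine's probability
    groups; every transition weight referencing one must be a monomial
    (a constant times a product of parameter powers), so that the M-step
    is the closed-form normalization of expected counts within each group.
    Returns the fitted parameter model and the per-iteration total
    log-likelihood trace, which is non-decreasing.
    """
    trainable: set[str] = set()
    for g in m.params.prob_groups:
        trainable.update(g)
    exponents: dict[int, dict[str, int]] = {}
    for ti, t in enumerate(m.transitions):
        names = t.weight.params() & trainable
        if not names:
            continue
        mono = t.weight.monomial()
        if mono is None:
            raise ValueError(
                f"transition {ti} ({t!r}) has a non-monomial weight over "
                f"trainable parameters {sorted(names)}; EM's closed-form "
                "M-step does not apply")
        exponents[ti] = mono

    values = dict(m.params.values)
    if p0 is not None:
        values.update(p0.values if isinstance(p0, ParamModel) else p0)
    for name in trainable:
        if name not in values:
            raise UnassignedParameterError(name)

    trace: list[float] = []
    for _ in range(max_iters):
        usage = {name: 0.0 for name in trainable}
        total_ll = 0.0
        for di, (x, y) in enumerate(data):
            try:
                res = forward_backward(m, x, y, values)
            except ValueError as e:
                raise ValueError(f"data pair {di} has zero likelihood") from e
            total_ll += res.log_weight
            for ti, count in res.expected_counts.items():
                for name, k in exponents.get(ti, {}).items():
                    if name in usage:
                        usage[name] += k * count
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        for group in m.params.prob_groups:
            tot = sum(usage[name] for name in group)
            if tot > 0:
                for name in group:
                    values[name] = usage[name] / tot
    fitted = ParamModel(values, m.params.prob_groups, m.params.rates)
    return fitted, trace
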