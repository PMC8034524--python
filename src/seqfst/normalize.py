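"""Transition-graph hygiene.

The Forward recurrence processes the states of a machine in list order
within each dynamic-programming cell, so the silent (epsilon/epsilon)
subgraph must be acyclic and topologically sorted.  This module provides
the operations that establish and maintain that property: stable
topological sorting, exact silent-cycle elimination by marginalization,
approximate cycle breaking by back-transition deletion, pruning of
unreachable states, and per-state probabilistic normalization.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .core import Machine, Transition, transition
from .expr import Const, UnassignedParameterError

SPECTRAL_DIVERGENCE_TOL = 1e-12  # spectral radius >= 1 - tol is divergent


class SilentCycleError(ValueError):
    """The silent subgraph contains a cycle."""

    def __init__(self, cycle: list[str], message: str | None = None):
        self.cycle = cycle
        super().__init__(message or
                         f"silent cycle through states {' -> '.join(cycle + cycle[:1])}")


class DivergenceError(ValueError):
    """A silent cycle's weight does not contract (geometric series diverges)."""


def _silent_digraph(m: Machine) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(m.states)
    for i, t in enumerate(m.transitions):
        if t.is_silent:
            g.add_edge(t.src, t.dst, key=i)
    return g


def _find_silent_cycle(g: nx.MultiDiGraph) -> list[str] | None:
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [u for u, _v, _k in cyc]


def toposort_silent(m: Machine) -> Machine:
    """Reorder states so every silent transition goes from a lower to a
    higher index, keeping the start state first and the end state last.

    The sort is stable: among incomparable states the prior relative order
    is preserved, so repeated application is idempotent and serialized
    output is reproducible.  If a silent transition enters the start state
    or leaves the end state, a fresh start/end state is spliced in first
    (pinning would otherwise be impossible).
    """
    if len(m.states) == 1:
        return m
    g = _silent_digraph(m)
    cyc = _find_silent_cycle(g)
    if cyc is not None:
        raise SilentCycleError(cyc)

    states, transitions = list(m.states), list(m.transitions)
    if any(t.is_silent and t.dst == m.start for t in transitions):
        new_start = _fresh_id("start", states)
        transitions.insert(0, transition(new_start, None, None, states[0], 1.0))
        states.insert(0, new_start)
    if any(t.is_silent and t.src == m.states[-1] for t in transitions):
        new_end = _fresh_id("end", states)
        transitions.append(transition(states[-1], None, None, new_end, 1.0))
        states.append(new_end)

    order = {s: i for i, s in enumerate(states)}
    succ: dict[str, list[str]] = {s: [] for s in states}
    indeg = {s: 0 for s in states}
    for t in transitions:
        if t.is_silent:
            succ[t.src].append(t.dst)
            indeg[t.dst] += 1
    start, end = states[0], states[-1]
    remaining = set(states)
    result = [start]
    remaining.discard(start)
    for d in succ[start]:
        indeg[d] -= 1
    while remaining:
        # stable Kahn step: earliest-ordered zero-indegree state, end held back
        candidates = [s for s in states
                      if s in remaining and indeg[s] == 0 and (s != end or len(remaining) == 1)]
        s = candidates[0]
        result.append(s)
        remaining.discard(s)
        for d in succ[s]:
            indeg[d] -= 1
    return m.with_(states=tuple(result), transitions=tuple(transitions))


def _fresh_id(base: str, taken: list[str]) -> str:
    if base not in taken:
        return base
    i = 1
    while f"{base}.{i}" in taken:
        i += 1
    return f"{base}.{i}"


def eliminate_silent_cycles(m: Machine) -> Machine:
    """Replace every silent strongly connected component by its closure.

    Within a silent SCC with weight matrix S, the total weight of silent
    wanderings from entry state a to exit state b is the (a, b) entry of
    (I - S)^-1 — the matrix geometric series.  Each SCC state v is split
    into an entry copy and an exit copy joined by silent transitions
    carrying those closure weights; incoming transitions are redirected to
    the entry copy and outgoing ones re-sourced from the exit copy.
    Forward weights are preserved for every sequence pair.

    Cycle weights must be numeric (assigned parameters) and the SCC's
    spectral radius must be < 1, else the series diverges.
    """
    g = _silent_digraph(m)
    sccs = []
    for comp in nx.strongly_connected_components(g):
        comp = sorted(comp, key=m.state_index().__getitem__)
        if len(comp) > 1 or g.has_edge(comp[0], comp[0]):
            sccs.append(comp)
    if not sccs:
        return toposort_silent(m)

    env = m.params.values
    states = list(m.states)
    transitions = list(m.transitions)
    entry = {}  # original id -> entry-copy id
    exit_ = {}  # original id -> exit-copy id
    in_scc = set()
    new_silent: list[Transition] = []
    drop = set()

    for comp in sccs:
        in_scc.update(comp)
        n = len(comp)
        idx = {s: i for i, s in enumerate(comp)}
        S = np.zeros((n, n))
        for ti, t in enumerate(transitions):
            if t.is_silent and t.src in idx and t.dst in idx:
                try:
                    w = t.weight.evaluate(env)
                except UnassignedParameterError as e:
                    raise ValueError(
                        f"silent cycle through {comp!r} has symbolic weight "
                        f"(parameter {e.name!r} unassigned); assign it or use "
                        f"break_silent_cycles for an approximate result") from e
                S[idx[t.src], idx[t.dst]] += w
                drop.add(ti)
        radius = max(abs(np.linalg.eigvals(S))) if n else 0.0
        if radius >= 1.0 - SPECTRAL_DIVERGENCE_TOL:
            raise DivergenceError(
                f"silent cycle through {comp!r} has spectral radius "
                f"{radius:.6g} >= 1; the path sum diverges")
        M = np.linalg.inv(np.eye(n) - S)
        for s in comp:
            entry[s] = _fresh_id(f"{s}.in", states)
            states.append(entry[s])
            exit_[s] = _fresh_id(f"{s}.out", states)
            states.append(exit_[s])
        for a in comp:
            for b in comp:
                w = M[idx[a], idx[b]]
                if w != 0.0:
                    new_silent.append(transition(entry[a], None, None, exit_[b], w))

    rewired: list[Transition] = []
    for ti, t in enumerate(transitions):
        if ti in drop:
            continue
        src = exit_[t.src] if t.src in in_scc else t.src
        dst = entry[t.dst] if t.dst in in_scc else t.dst
        rewired.append(Transition(src, t.inp, t.out, dst, t.weight))
    rewired.extend(new_silent)

    # splice the split copies into the state order and retire the originals;
    # the start of a split SCC becomes its entry copy, the end its exit copy
    new_states: list[str] = []
    for s in m.states:
        if s in in_scc:
            new_states.extend([entry[s], exit_[s]])
        else:
            new_states.append(s)
    out = m.with_(states=tuple(new_states), transitions=tuple(rewired))
    return toposort_silent(prune(out))


def break_silent_cycles(m: Machine) -> tuple[Machine, list[Transition]]:
    """Delete silent back-transitions until the silent subgraph is acyclic.

    A back-transition is a silent transition whose destination index does
    not exceed its source index in the current state order; they are
    removed one at a time in decreasing source-index order, re-checking
    acyclicity after each deletion.  The result is an approximation: the
    Forward weight of the output never exceeds that of exact
    marginalization.  Returns the machine and the deleted transitions.
    """
    transitions = list(m.transitions)
    deleted: list[Transition] = []
    order = m.state_index()
    while True:
        g = nx.MultiDiGraph()
        g.add_nodes_from(m.states)
        for i, t in enumerate(transitions):
            if t.is_silent:
                g.add_edge(t.src, t.dst, key=i)
        if _find_silent_cycle(g) is None:
            break
        back = [(order[t.src], i) for i, t in enumerate(transitions)
                if t.is_silent and order[t.dst] <= order[t.src]]
        src_idx, i = max(back)
        deleted.append(transitions.pop(i))
    out = m.with_(transitions=tuple(transitions))
    return toposort_silent(out), deleted


def prune(m: Machine) -> Machine:
    """Remove states not reachable from the start or not co-reachable to the
    end.  Forward weights are unchanged for every sequence pair.  If the
    start cannot reach the end at all, the zero machine (two states, no
    transitions) is returned with a warning.
    """
    fwd: dict[str, list[str]] = {s: [] for s in m.states}
    bwd: dict[str, list[str]] = {s: [] for s in m.states}
    for t in m.transitions:
        fwd[t.src].append(t.dst)
        bwd[t.dst].append(t.src)

    def bfs(root: str, adj: dict[str, list[str]]) -> set[str]:
        seen = {root}
        stack = [root]
        while stack:
            for d in adj[stack.pop()]:
                if d not in seen:
                    seen.add(d)
                    stack.append(d)
        return seen

    reach = bfs(m.start, fwd)
    coreach = bfs(m.end, bwd)
    keep = reach & coreach
    if m.start not in keep or m.end not in keep:
        warnings.warn("start state cannot reach end state; returning the zero machine")
        return m.with_(states=("start", "end"), transitions=())
    states = tuple(s for s in m.states if s in keep)
    transitions = tuple(t for t in m.transitions if t.src in keep and t.dst in keep)
    return m.with_(states=states, transitions=transitions)


def normalize_probabilistic(m: Machine) -> tuple[Machine, dict[str, float]]:
    """Rescale each non-end state's outgoing weights to sum to 1.

    All weights must be numeric under the machine's parameter assignment.
    Returns the normalized machine and the per-state scaling factors
    (original outgoing sum).  A non-end state with zero total outgoing
    weight is an error.
    """
    env = m.params.values
    totals: dict[str, float] = {s: 0.0 for s in m.states}
    for t in m.transitions:
        totals[t.src] += t.weight.evaluate(env)
    factors: dict[str, float] = {}
    for s in m.states:
        if s == m.end:
            factors[s] = 1.0
            continue
        if totals[s] == 0.0:
            raise ValueError(f"state {s!r} has zero total outgoing weight; "
                             "cannot normalize")
        factors[s] = totals[s]
    new_transitions = []
    for t in m.transitions:
        f = factors[t.src]
        if f == 1.0:
            new_transitions.append(t)
        else:
            w = t.weight.evaluate(env) / f
            new_transitions.append(Transition(t.src, t.inp, t.out, t.dst, Const(w)))
    return m.with_(transitions=tuple(new_transitions)), factors


def tidy(m: Machine) -> Machine:
    """Post-construction hygiene used by the algebra operations: prune, then
    topologically sort the silent subgraph, marginalizing numeric silent
    cycles exactly when they arise.  Symbolic silent cycles are left in
    place (Forward will refuse them until they are broken or assigned)."""
    m = prune(m)
    try:
        return toposort_silent(m)
    except SilentCycleError:
        try:
            return eliminate_silent_cycles(m)
        except DivergenceError:
            raise
        except ValueError:
            return m  # symbolic silent cycle: defer to break_silent_cycles
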