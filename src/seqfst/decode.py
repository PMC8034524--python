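"""Searching for high-weight output sequences.

Given a machine and (optionally) an input sequence, these routines search
the space of output sequences: exact best-first prefix search, width-
limited beam search, the best single *path* output (for deterministic
codes), and probability-weighted sampling.

All searches operate on a *conditioned generator*: if an input sequence x
is supplied, the machine is first composed on the left with a generator
of x, which turns T into a generator whose weight on output y is T[x, y].
A hypothesis is an output prefix together with the vector of accumulated
path weights per machine state (silent moves already marginalized); its
score is the summed state weight, and its completion weight is the mass
sitting on the end state.  Prefix and beam search both merge hypotheses
with identical output prefixes, so they rank outputs by *summed* path
weight — the CTC notion of sequence probability — rather than by single
best path.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import Machine, ParamModel
from .normalize import tidy
from . import algebra, inference

NEG_INF = float("-inf")


@dataclass
class Hypothesis:
    """An output prefix with per-state accumulated weights (linear scale)."""

    output_prefix: str
    state_weights: np.ndarray

    @property
    def score(self) -> float:
        total = float(self.state_weights.sum())
        return math.log(total) if total > 0 else NEG_INF


class _Search:
    """Shared machinery: conditioned generator, silent closure, per-symbol
    emission matrices."""

    def __init__(self, m: Machine, x: str | None,
                 p: ParamModel | Mapping[str, float] | None):
        if x:
            from .presets import generator  # deferred: presets imports algebra
            m = algebra.compose(generator(x, alphabet=m.input_alphabet), m)
        elif not m.is_generator:
            raise ValueError("an input sequence is required unless the machine "
                             "is a generator")
        m = tidy(m)
        inference._check_silent_sorted(m)
        self.m = m
        env = m.params.assigned(p.values if isinstance(p, ParamModel) else (p or {}))
        n = len(m.states)
        idx = m.state_index()
        A_silent = np.zeros((n, n))
        self.alphabet = tuple(m.output_alphabet)
        A_emit = {c: np.zeros((n, n)) for c in self.alphabet}
        self.out_sums = np.zeros(n)
        for t in m.transitions:
            w = t.weight.evaluate(env)
            self.out_sums[idx[t.src]] += w
            if t.is_silent:
                A_silent[idx[t.src], idx[t.dst]] += w
            else:
                A_emit[t.out][idx[t.src], idx[t.dst]] += w
        closure = np.linalg.inv(np.eye(n) - A_silent)  # finite: silent DAG
        # Hypothesis state weights are kept at "resting" states (just after
        # an emission, silent moves not yet taken), so each path contributes
        # to exactly one state: extending closes silently then emits, and
        # completing closes silently into the end state.
        self.E = {c: closure @ A_emit[c] for c in self.alphabet}
        self.close_end = closure[:, n - 1]
        w0 = np.zeros(n)
        w0[0] = 1.0
        self.w0 = w0
        self.end = n - 1

    def completion(self, w: np.ndarray) -> float:
        return float(w @ self.close_end)

    def check_substochastic(self, tol: float = 1e-6) -> None:
        # Admissibility: from every state, one emission step plus immediate
        # termination must carry total mass <= 1; by induction all future
        # completion mass is then <= 1 and a hypothesis's summed state
        # weight bounds every extension's completion weight.  Implied by
        # raw per-state outgoing sums <= 1, but also admits machines whose
        # silent entry edges split sub-unit mass.
        g = self.close_end.copy()
        for c in self.alphabet:
            g = g + self.E[c].sum(axis=1)
        bad = [(self.m.states[i], v) for i, v in enumerate(g) if v > 1.0 + tol]
        if bad:
            raise ValueError(
                "machine is not substochastic; continuation mass exceeds 1 at "
                + ", ".join(f"{s!r} (mass {v:.6g})" for s, v in bad))

    def default_max_len(self, x: str | None) -> int:
        return 2 * ((len(x) if x else 0) + 1) * len(self.m.states)


def _better(cand: tuple[float, str], best: tuple[float, str]) -> bool:
    # higher log-weight wins; ties go to the lexicographically smaller output
    if cand[0] != best[0]:
        return cand[0] > best[0]
    return cand[1] < best[1]


def prefix_search(m: Machine, x: str | None = None,
                  p: ParamModel | Mapping[str, float] | None = None,
                  max_len: int | None = None) -> tuple[str | None, float]:
    """Exact argmax over output sequences of T[x, y] by best-first search.

    Requires the machine to be substochastic (per-state outgoing weight
    sums <= 1), which makes a hypothesis's score an admissible bound on
    every extension's completion weight.  Returns (best output, its
    natural-log weight), or (None, -inf) if nothing with positive weight
    is found within ``max_len``.
    """
    srch = _Search(m, x, p)
    srch.check_substochastic()
    if max_len is None:
        max_len = srch.default_max_len(x)
    done0 = srch.completion(srch.w0)
    best = (math.log(done0) if done0 > 0 else NEG_INF, "")
    heap: list[tuple[float, str, np.ndarray]] = []
    h0 = Hypothesis("", srch.w0)
    if h0.score > NEG_INF:
        heapq.heappush(heap, (-h0.score, "", srch.w0))
    while heap:
        neg_score, prefix, w = heapq.heappop(heap)
        if -neg_score <= best[0]:
            break  # no extension can beat the best completed output
        if len(prefix) >= max_len:
            continue
        for c in srch.alphabet:
            w2 = w @ srch.E[c]
            total = float(w2.sum())
            if total <= 0.0:
                continue
            y2 = prefix + c
            done = srch.completion(w2)
            if done > 0 and _better((math.log(done), y2), best):
                best = (math.log(done), y2)
            heapq.heappush(heap, (-math.log(total), y2, w2))
    if best[0] == NEG_INF:
        return None, NEG_INF
    return best[1], best[0]


def beam_search(m: Machine, x: str | None = None,
                p: ParamModel | Mapping[str, float] | None = None,
                width: int = 5, max_len: int | None = None) -> tuple[str | None, float]:
    """Heuristic search keeping the top ``width`` output prefixes per output
    length.  Hypotheses with identical prefixes are merged (their state
    weights summed), so scores aggregate over paths as in CTC decoding.
    As the width grows the result converges to :func:`prefix_search` on
    substochastic machines.
    """
    if width < 1:
        raise ValueError(f"beam width must be >= 1, got {width}")
    srch = _Search(m, x, p)
    if max_len is None:
        max_len = srch.default_max_len(x)
    done0 = srch.completion(srch.w0)
    best = (math.log(done0) if done0 > 0 else NEG_INF, "")
    beam: dict[str, np.ndarray] = {"": srch.w0}
    for _ in range(max_len):
        scored = sorted(beam.items(),
                        key=lambda kv: (-float(kv[1].sum()), kv[0]))[:width]
        nxt: dict[str, np.ndarray] = {}
        for prefix, w in scored:
            for c in srch.alphabet:
                w2 = w @ srch.E[c]
                total = float(w2.sum())
                if total <= 0.0:
                    continue
                y2 = prefix + c
                if y2 in nxt:
                    nxt[y2] = nxt[y2] + w2
                else:
                    nxt[y2] = w2
        for y2, w2 in nxt.items():
            done = srch.completion(w2)
            if done > 0 and _better((math.log(done), y2), best):
                best = (math.log(done), y2)
        if not nxt:
            break
        beam = nxt
    if best[0] == NEG_INF:
        return None, NEG_INF
    return best[1], best[0]


def sample_output(m: Machine, x: str | None = None,
                  p: ParamModel | Mapping[str, float] | None = None,
                  n_samples: int = 1, seed: int = 0,
                  max_steps: int = 100000) -> list[str]:
    """Draw i.i.d. output sequences with probability proportional to weight.

    The (conditioned) machine must be probabilistically normalized: every
    non-end state's outgoing weights sum to 1, and the end state's
    residual mass is the termination probability.  Deterministic given the
    seed.
    """
    srch = _Search(m, x, p)
    mach = srch.m
    env = mach.params.assigned(p.values if isinstance(p, ParamModel) else (p or {}))
    out_trans = mach.out_transitions()
    for s in mach.states:
        total = sum(t.weight.evaluate(env) for t in out_trans[s])
        if s != mach.end and abs(total - 1.0) > 1e-6:
            raise ValueError(f"state {s!r} outgoing weights sum to {total:.6g}; "
                             "machine must be probabilistically normalized")
        if s == mach.end and total > 1.0 + 1e-6:
            raise ValueError(f"end state outgoing weights sum to {total:.6g} > 1")
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    for _ in range(n_samples):
        s = mach.start
        emitted: list[str] = []
        for _step in range(max_steps):
            opts = out_trans[s]
            weights = [t.weight.evaluate(env) for t in opts]
            stop_p = max(0.0, 1.0 - sum(weights)) if s == mach.end else 0.0
            if s == mach.end and (not opts or rng.random() < stop_p):
                break
            u = rng.random() * sum(weights)
            acc = 0.0
            chosen = opts[-1]
            for t, w in zip(opts, weights):
                acc += w
                if u < acc:
                    chosen = t
                    break
            if chosen.out is not None:
                emitted.append(chosen.out)
            s = chosen.dst
        else:
            raise RuntimeError("sampling did not terminate; is termination "
                               "reachable from every state?")
        samples.append("".join(emitted))
    return samples


def viterbi_output(m: Machine, x: str,
                   p: ParamModel | Mapping[str, float] | None = None,
                   ) -> tuple[str | None, float]:
    """Best single *path* given the full input x, with its output projection.

    A best-path search (Dijkstra on negative log-weights) over nodes
    (input position, state).  For functional machines such as the storage
    and parity codes this is exact encoding/decoding and runs in
    near-linear time in |x| * |states|.
    """
    env = m.params.assigned(p.values if isinstance(p, ParamModel) else (p or {}))
    idx = m.state_index()
    n = len(m.states)
    by_src: dict[int, list[tuple[float, int, str | None, str | None]]] = {
        i: [] for i in range(n)}
    for t in m.transitions:
        w = t.weight.evaluate(env)
        if w > 0:
            by_src[idx[t.src]].append((-math.log(w), idx[t.dst], t.inp, t.out))
    start, end = 0, n - 1
    X = len(x)
    dist: dict[tuple[int, int], float] = {(0, start): 0.0}
    back: dict[tuple[int, int], tuple[tuple[int, int], str | None]] = {}
    heap = [(0.0, (0, start))]
    seen: set[tuple[int, int]] = set()
    while heap:
        d, node = heapq.heappop(heap)
        if node in seen:
            continue
        seen.add(node)
        i, s = node
        if node == (X, end):
            out: list[str] = []
            cur = node
            while cur in back:
                cur, sym = back[cur]
                if sym is not None:
                    out.append(sym)
            return "".join(reversed(out)), -d
        for cost, dst, inp, out_sym in by_src[s]:
            if inp is None:
                node2 = (i, dst)
            elif i < X and x[i] == inp:
                node2 = (i + 1, dst)
            else:
                continue
            d2 = d + cost
            if d2 < dist.get(node2, math.inf):
                dist[node2] = d2
                back[node2] = (node, out_sym)
                heapq.heappush(heap, (d2, node2))
    return None, NEG_INF
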