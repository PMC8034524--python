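# Methods

## The machine model

A machine is (Ω_I, Ω_O, Φ, τ, Θ, Ψ, υ): input and output alphabets (either
may be empty), a non-empty ordered state list whose first element is the
start state and whose last is the end state, transitions labelled with an
input and/or output symbol (ε meaning none; both-ε transitions are
*silent*, both-non-ε transitions *IO-conditioned*), and a weight function
assigning each transition a closed-form differentiable expression over
named parameters.  The expression grammar is: non-negative constants,
parameter references, +, −, ×, ÷, powers, exp and log.  Parameters are
partitioned into mutually-exclusive probability groups (each summing to 1,
absolute tolerance 1e−9), non-negative rates, and free values; only
probability-group parameters are trainable by EM.

The weight of a sequence pair, T[x, y], is the total weight of all
start-to-end paths whose input labels concatenate to x and output labels to
y.  Symbols are single unicode characters at the API boundary; ε is
represented by the *absence* of a label (both in Python, as `None`, and in
the JSON format, as an absent field), so alphabets may contain any
printable character.

## Dynamic programming

All recurrences run in natural-log space with log-sum-exp accumulation and
a −∞ sentinel for zero weight.  Cells are (i, j, state), i input symbols
consumed and j output symbols emitted; within a cell, silent transitions
are swept in state-list order, which requires the silent subgraph to be
acyclic and topologically sorted.  Tables are kept in full,
(|x|+1)×(|y|+1)×|Φ| — this is a prototyping-scale implementation;
checkpointed or linear-space variants are deliberately out of scope.
Viterbi replaces sum with max and breaks ties in favour of the transition
earliest in serialized order, making tracebacks deterministic.
Forward–Backward expected counts are assembled per transition from the
forward and backward tables; parameter gradients ∂T[x, y]/∂λ combine the
counts with the symbolic derivatives of each weight expression, and are
verified against central finite differences in the tests.

### Silent-subgraph hygiene

Every algebra constructor prunes states that are unreachable from the
start or cannot reach the end, then re-establishes the topological order of
the silent subgraph.  The stable Kahn sort pins the start state first and
the end state last; if a construction has produced a silent transition into
the start or out of the end, a fresh boundary state is spliced in first.
Silent cycles are marginalized exactly when their weights are numeric: each
silent strongly connected component with weight matrix S is replaced by its
closure (I − S)⁻¹, realized by splitting every member state into an entry
and an exit copy joined by closure-weighted silent transitions — this
preserves T[x, y] exactly and is verified against truncated path sums.
Divergence is declared when the component's spectral radius reaches
1 − 1e−12.  With symbolic weights in a cycle, exact marginalization is
impossible and the cycle is left for `break_silent_cycles`, the approximate
fallback that deletes silent back-transitions (highest source index first,
re-checking acyclicity after each deletion); its result is a lower bound on
the exact Forward weight.  A third conceivable policy — leaving cycles in
place and accepting a stale Forward value — is not offered: Forward here
refuses unsorted silent subgraphs outright.

### Composition and intersection

Composite states are (T-state, U-state, phase).  The phase bit is the
standard ε-filter: interleavings of T's output-ε moves and U's input-ε
moves describe the same joint path, so paths are canonicalized — from phase
0 both lone moves are allowed, a lone U move sets phase 1, from which lone
T moves are barred until a synchronized symbol exchange resets phase 0.
Because independent moves commute, every joint path is counted exactly
once and weights are preserved.  Intersection uses the same filter but
synchronizes on the full (input, output) label pair; it is exact for
recognizers, generators and letter-synchronized transducers, which covers
its intended uses (constraining codes, point products of recognizers).

## EM

`fit_em` trains exactly the parameters in probability groups, and requires
every transition weight that mentions one to be a monomial (a constant
times a product of parameter powers).  Under that restriction the M-step is
closed-form: each parameter's new value is its exponent-weighted expected
count normalized within its group, the standard Baum–Welch update, and the
log-likelihood is provably non-decreasing.  Richer weight expressions are
rejected with an error naming the offending transition rather than being
silently mis-fit; rate parameters are accepted in machines but are not
trainable.  Defaults: tolerance 1e−6 in total log-likelihood, at most 100
iterations.

## Decoding

Search operates on a *conditioned generator*: given an input x, the
machine is composed on the left with a generator of x, reducing every
search to best-output search on a generator.  A hypothesis is an output
prefix with a vector of path weights over "resting" states (just after an
emission, silent moves not yet taken), so each path contributes to exactly
one state; extension closes silently then emits one symbol, and completion
closes silently into the end state.  Prefix search is best-first on the
summed state weight, which is an admissible bound when the machine is
substochastic — checked as one-step continuation mass ≤ 1 from every state,
a condition implied by per-state outgoing sums ≤ 1.  Beam search is
synchronous in output length, keeps the top-W prefixes, and merges
hypotheses with equal prefixes by summing their state vectors — this is
what makes it rank outputs by total path weight, the CTC notion of sequence
probability, rather than by single best path; with growing width it
converges to prefix search.  Ties everywhere go to the lexicographically
smallest output.  The default search horizon is 2·(|x|+1)·|Φ| output
symbols, a safety bound against pathological machines.  `viterbi_output`
is the complementary tool for functional machines (codes): a Dijkstra
best-path search over (input position, state) that recovers the best
output projection in near-linear time, used by the storage and parity
codec helpers.  Sampling requires a per-state normalized machine and walks
transitions proportionally to weight; it is deterministic given a seed.

## Preset conventions

Where the machines' published descriptions leave details open, this
package fixes them as follows:

- **binary→ternary**: bits are batched most-significant-first; the batch
  value v emits base-3 digits high-then-low (⌊v/3⌋, v mod 3).  Since v ≤ 7,
  the *aligned* trit pair "22" never arises from data and is emitted once
  at end of input as the end-of-message marker.  (As a raw substring "22"
  can straddle a pair boundary — e.g. batches 5, 7 give "12"+"21"; the
  decoder reads aligned pairs, so the marker stays unambiguous.)  Messages
  whose length is not a multiple of 3 are zero-padded before the marker;
  the padding is invisible to the decoder, so callers keep the original
  bit length (the CLI takes `--n-bits`).
- **ternary→DNA**: from previous base b, trit t emits the t-th base in
  alphabetical order of {A,C,G,T}∖{b}; the start state is deemed to have
  previous base T so the start rule is the generic rule.  Five states:
  start/prev-T, one per other previous base, end.
- **Hamming(7,4)**: codeword layout p1 p2 d1 p3 d2 d3 d4 with even parity
  (p1 over positions 1,3,5,7; p2 over 2,3,6,7; p3 over 4,5,6,7).
- **error models**: the symmetric context-independent model has match,
  insert and delete states plus start and end (5 states), a 4×4
  substitution table and one shared gap-open/extend pair, all as named
  symbolic parameters with numeric defaults.  The asymmetric
  context-dependent model replicates the M/I/D triple over the 16
  (previous reference base × current reference base) flanking contexts —
  48 context states plus start and end, 50 in total — with per-context
  substitution, insertion and deletion parameters (insertions and
  deletions separate, hence asymmetric).  The reference is treated as
  left-padded with 'A' for the first position's context; this boundary
  convention is the package's own choice.  Default numeric values (match
  0.85–0.91, mismatch/gap 0.02–0.03) are generic placeholders for
  prototyping, not fitted to any instrument.
- **CTC recognizer**: states track (frame index, previous frame symbol);
  a frame equal to the previous non-blank symbol consumes no label
  (repeats merge), a blank consumes nothing and resets the repeat context,
  any other symbol consumes one label.  Weights need not be normalized.
- **protein→codon**: standard genetic code (via Biopython's table),
  uniform synonymous-codon weights by default, each codon emitted through
  two intermediate states.  No amino-acid substitution scoring and no
  splice/frameshift structure — the aligner is assembled by composing with
  an error model.
- **regular expressions**: literals, classes, '.', '*', '+', '?', '|' and
  grouping, built by the machine algebra itself (union = add, closure =
  Kleene star); accepted strings get weight 1 provided the pattern is
  unambiguous.
- **motif avoidance**: a de Bruijn graph over (k−1)-mers with transitions
  spelling prohibited k-mers deleted, exposed as a weight-1 recognizer to
  intersect with other machines.

## What the synthetic tests do and do not show

No real sequencing reads ship with the package, so the empirical questions
those would answer (how much a context-dependent error model improves
discrimination on nanopore data; basecaller accuracy deltas between
Viterbi and beam decoding) are *not* tested here.  What the suite
establishes instead is the correctness of the machinery those experiments
rely on: Forward/Viterbi agree with brute-force path enumeration on
hundreds of random machines; every algebra operation satisfies its
defining matrix/string identity against enumeration oracles; gradients
match finite differences; EM is monotone and recovers known parameters
from 500 sampled sequences within 0.05; the storage code round-trips every
message up to 12 bits exhaustively and meets its 3/2 rate on a 3,000-bit
message; Hamming decoding corrects all 112 single-bit corruptions; the CTC
recognizer matches the exhaustive collapse-rule sum on 4-frame matrices;
and beam search at width 64 equals exact prefix search equals enumeration
argmax on substochastic fixtures.  Random test machines are small (≤ 5
states, labels ≤ 4) so the oracles stay exhaustive; sizes were chosen to
keep the oracles exact, and determinism comes from fixed seeds and
derandomized property tests.

## Known limitations

Exact silent-cycle marginalization requires numeric weights; symbolic
cycles must be broken approximately.  Intersection assumes
letter-synchronized operands.  EM handles monomial weights only.  DP
memory is quadratic in the sequence lengths.  The CLI and JSON format are
this package's own dialect (documented in `seqfst.io`), not a
reimplementation of any other tool's file format.
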