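"""Decode the most likely sequence from per-frame symbol probabilities.

Neural-network basecallers trained with CTC emit a per-frame distribution
over symbols plus a blank; a label sequence's probability sums over every
framewise path that collapses to it (merge adjacent repeats, then drop
blanks).  The CTC recognizer machine encodes that collapse rule, so beam
search over its transpose decodes by summed path weight, which can beat
the naive best-single-path (Viterbi) decode.
"""

import numpy as np

from seqfst import beam_search, presets, transpose, viterbi

rng = np.random.default_rng(7)
T = 8
P = rng.dirichlet([0.3] * 5, size=T)  # columns A, C, G, T, blank

ctc = presets.ctc_recognizer(P, "ACGT")
gen = transpose(ctc)

# naive framewise argmax (what a plain Viterbi decode does)
symbols = "ACGT-"
frames = "".join(symbols[k] for k in P.argmax(axis=1))
collapsed = "".join(c for c, prev in zip(frames, "-" + frames)
                    if c != prev and c != "-")

for width in (1, 5, 50):
    y, lw = beam_search(gen, width=width, max_len=T)
    print(f"beam width {width:2d}: {y!r}  log-weight {lw:.4f}")
print(f"framewise argmax collapse: {collapsed!r}")
print("sum over paths (beam) can differ from the single best path when")
print("probability mass is spread across alignments of the same labels.")
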