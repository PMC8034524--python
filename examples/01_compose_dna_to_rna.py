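"""Build a DNA motif generator and convert it to RNA by machine composition.

A machine generating the TaqI restriction site TCGA, multiplied (composed)
with a single-state DNA-to-RNA transducer, yields a machine generating the
corresponding RNA motif UCGA.
"""

import math

from seqfst import compose, forward, machine_stats, presets

taq = presets.generator("TCGA")
d2r = presets.dna_to_rna()
rna_motif = compose(taq, d2r)

print("TaqI generator:", machine_stats(taq))
print("composed RNA motif machine:", machine_stats(rna_motif))
for y in ("UCGA", "TCGA", "UCGG"):
    w = forward(rna_motif, "", y).log_weight
    print(f"  weight of output {y!r}: {math.exp(w) if w > -math.inf else 0.0}")
# UCGA gets weight 1 (the motif, transcribed); everything else weight 0.
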