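"""Score a peptide against noisy DNA through composed machines.

A protein-to-codon translator composed with a context-dependent
sequencing-error model gives a protein-to-noisy-DNA aligner — the modular
machine-multiplication route to GeneWise-style searches with richer error
models.
"""

from seqfst import compose, forward, machine_stats, presets

translate = presets.protein_to_codon()
errors = presets.error_model_acd()
aligner = compose(translate, errors)

print("translator:", machine_stats(translate))
print("error model:", machine_stats(errors), "(48 context states + start/end)")
print("composed aligner:", machine_stats(aligner))

peptide = "MW"
clean = "ATGTGG"        # exact codons for M, W
noisy = "ATGTCG"        # one substitution
unrelated = "CCCCCC"
for dna in (clean, noisy, unrelated):
    lw = forward(aligner, peptide, dna).log_weight
    print(f"  log-weight of {peptide!r} against {dna!r}: {lw:.3f}")
# the clean codons score best, the single error costs a few nats, and
# unrelated DNA scores far lower
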