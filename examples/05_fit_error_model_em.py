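"""Fit emission probabilities by constrained Baum-Welch EM.

A two-state generator with unknown emission distributions is fitted from
sequences sampled at known parameter values; the probability-group
constraints keep each distribution normalized at every M-step, and the
log-likelihood trace is non-decreasing.
"""

from seqfst import ParamModel, fit_em, machine, sample_output, transition
from seqfst.expr import Param

truth = {"eA": 0.7, "eB": 0.3, "fA": 0.2, "fB": 0.3, "stop": 0.5}
pm = ParamModel(truth, (("eA", "eB"), ("fA", "fB", "stop")))
gen = machine((), "AB", ["s0", "s1", "end"], [
    transition("s0", None, "A", "s1", Param("eA")),
    transition("s0", None, "B", "s1", Param("eB")),
    transition("s1", None, "A", "s0", Param("fA")),
    transition("s1", None, "B", "s0", Param("fB")),
    transition("s1", None, None, "end", Param("stop")),
], pm)

data = [("", y) for y in sample_output(gen, n_samples=500, seed=11)]
p0 = {"eA": 0.5, "eB": 0.5, "fA": 0.33, "fB": 0.33, "stop": 0.34}
fitted, trace = fit_em(gen, data, p0=p0, max_iters=60)

print(f"EM converged in {len(trace)} iterations "
      f"(log-likelihood {trace[0]:.2f} -> {trace[-1]:.2f})")
for name in sorted(truth):
    print(f"  {name}: true {truth[name]:.2f}  fitted {fitted.values[name]:.3f}")
# fitted values land within sampling error (~0.02-0.05 at n=500) of truth
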