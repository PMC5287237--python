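"""Test a mutant strain for differential growth against its parent.

Simulates a parent/mutant pair in which the mutant grows 50% slower,
computes the approximate log Bayes factor between f(time, strain) and
f(time), calibrates it with 100 per-time-point strain-label permutations,
and localizes the difference in time with the baseline-corrected posterior
contrast (mutant minus parent latent growth).
"""

import numpy as np

import gpgrowth as gg
from gpgrowth.difftest import STRAIN_TEST, build_design, fit_design

spec = gg.SyntheticSpec(
    strain_effect=gg.Effect(mu_scale=0.5),
    n_replicates=12,
    seed=4,
)
table = gg.subsample_timepoints(gg.simulate_dataset(spec), 6.0)

result = gg.permutation_test(table, STRAIN_TEST, n_perm=100, seed=0)
print(f"log BF = {result.log_bf:.1f}")
print(f"80th percentile of 100 permuted log BFs = {result.threshold:.1f}")
print(f"significant at FDR <= 20%: {result.significant}  "
      f"(empirical FDR at the real score: {result.fdr_at_real:.2f})")

enc, _, alt = build_design(table, STRAIN_TEST)
model = fit_design(enc, alt, restarts=2, seed=0)
series = gg.od_delta(model, np.arange(0.0, 48.01, 6.0), "strain_contrast")
print()
print(series.to_frame().to_string(index=False, float_format="%.3f"))
print()
print("A real strain effect drives the log BF far above the permutation")
print("threshold; the contrast series shows where the mutant's log2-OD")
print("falls below the parent's (significant = the 95% credible interval")
print("excludes zero at that time point).")
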