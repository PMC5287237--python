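"""Combine two studies with a hierarchical GP to unmask a stress phenotype.

Two batches of a four-arm experiment (parent/mutant x standard/stress)
carry opposite smooth systematic offsets of +-0.4 log2 units, and the
mutant has a modest growth defect specific to stress.  Pooling the batches
hides the defect; modeling each batch as a GP deviation around a shared
growth function recovers it.
"""

import numpy as np
import pandas as pd

import gpgrowth as gg
from gpgrowth.difftest import STRESS_TEST

spec = gg.SyntheticSpec(
    include_stress=True,
    n_batches=2,
    n_replicates=3,
    interaction_effect=gg.Effect(mu_scale=0.85),
    batch_offsets=gg.BatchOffsets(mode="sinusoid", amplitudes=(0.4, -0.4)),
    timegrid=np.arange(0.0, 48.01, 6.0),
    seed=101,
)
table = gg.simulate_dataset(spec)
batches = [table.with_data(df) for _, df in table.data.groupby("batch")]

hier = gg.hierarchical_bf(batches, n_perm=20, seed=1)
pooled = gg.GrowthTable(pd.concat([b.data for b in batches], ignore_index=True), True)
plain = gg.permutation_test(pooled, STRESS_TEST, n_perm=20, seed=2)

print(f"pooled test:        log BF = {plain.log_bf:6.2f}  "
      f"threshold = {plain.threshold:6.2f}  significant = {plain.significant}")
print(f"hierarchical test:  log BF = {hier.log_bf:6.2f}  "
      f"threshold = {hier.threshold:6.2f}  significant = {hier.significant}")
print()
print("The interaction term (mutant x stress) carries the defect.  The")
print("pooled model must absorb the opposite batch offsets as noise, so")
print("its log BF collapses toward zero; the hierarchical model explains")
print("the offsets at the batch level and the interaction stays visible.")
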