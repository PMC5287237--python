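"""Compare GP regression against the four classical sigmoid growth models.

Generates stress-shaped curves (growth followed by a post-peak decline,
the shape severe oxidative stress produces) and scores every model by
mean squared error on a held-out 20% of each curve.  Sigmoid models cannot
represent the decline, so their error is far larger than the GP's.
"""

import numpy as np

import gpgrowth as gg

rng = np.random.default_rng(0)
curves = []
for _ in range(12):
    spec = gg.SyntheticSpec(
        include_stress=True,
        stress_effect=gg.Effect(decline_slope=0.08, decline_onset=20.0),
        noise_sd=0.03,
        n_replicates=1,
        timegrid=np.arange(0.0, 48.01, 1.0),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    tab = gg.simulate_dataset(spec)
    mask = (tab.data["strain"] == "parent") & (tab.data["condition"] == "stress")
    curves.append(tab.with_data(tab.data[mask]))

report = gg.benchmark_models(curves, seed=0)
print(report.summary.to_string(index=False, float_format="%.4g"))
print()
print("mean_mse is the held-out MSE averaged over curves; p_gp_less is the")
print("one-sided Welch t-test that the GP's MSE is smaller than that row's")
print("model.  On decline-shaped curves every sigmoid model should lose to")
print("the GP by an order of magnitude with p well below 0.05.")
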