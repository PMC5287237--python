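import numpy as np
import pytest

import gpgrowth as gg


@pytest.fixture(scope="session")
def gompertz_curve_table():
    """Noiseless Gompertz curve (A=2, mu_max=0.3/h, lam=5 h), dense grid."""
    spec = gg.SyntheticSpec(
        noise_sd=0.0, n_replicates=1, timegrid=np.arange(0.0, 48.01, 0.5), seed=0
    )
    return gg.simulate_dataset(spec)


@pytest.fixture(scope="session")
def gompertz_gp(gompertz_curve_table):
    """GP fit to the noiseless Gompertz fixture."""
    tab = gompertz_curve_table
    par = tab.with_data(tab.data[tab.data["strain"] == "parent"])
    return gg.fit_gp(par, ("time",), restarts=2, seed=0)


@pytest.fixture(scope="session")
def noisy_pair_table():
    """Parent + mutant (50% slower growth), 6 reps/arm, 2-h grid."""
    spec = gg.SyntheticSpec(
        strain_effect=gg.Effect(mu_scale=0.5),
        n_replicates=6,
        timegrid=np.arange(0.0, 48.01, 2.0),
        seed=7,
    )
    return gg.simulate_dataset(spec)
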