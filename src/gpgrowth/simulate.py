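"""Synthetic growth datasets with known ground truth.

The generator emulates high-throughput plate-reader experiments on a
parent strain and a mutant, under a standard condition and a chronic
stress condition: log2-OD trajectories follow a Gompertz curve whose
parameters (carrying capacity A, maximum growth rate mu_max, lag time
lambda) can be modified multiplicatively by strain, stress and
strain-by-stress interaction effects; effects can also act as smooth
additive log2 offsets that turn on after inoculation.  Stress can impose
a non-sigmoid late decline (a negative linear ramp after an onset time),
the shape that defeats classical sigmoid models.  Smooth per-batch
offsets (GP draws or fixed sinusoids) emulate study-to-study systematic
variation, and IID Gaussian noise is added to every observation.

Defaults mirror a 48-h experiment sampled every 30 min with 12 replicates
per (strain, condition) arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GrowthTable
from .kernels import KernelSpec, kernel_matrix
from .primary import gompertz


@dataclass
class Effect:
    """How a covariate perturbs the base growth curve.

    ``a_scale`` and ``mu_scale`` multiply carrying capacity and maximum
    growth rate; ``offset`` is an additive log2 shift that ramps in
    smoothly after t0 (saturating over ~``offset_ramp`` hours);
    ``decline_slope`` > 0 subtracts a linear ramp (log2 units per hour)
    starting at ``decline_onset`` hours, producing the post-peak decline
    seen under severe stress.
    """

    a_scale: float = 1.0
    mu_scale: float = 1.0
    offset: float = 0.0
    offset_ramp: float = 4.0
    decline_slope: float = 0.0
    decline_onset: float = 24.0

    @property
    def is_null(self) -> bool:
        return (
            self.a_scale == 1.0
            and self.mu_scale == 1.0
            and self.offset == 0.0
            and self.decline_slope == 0.0
        )


@dataclass
class BatchOffsets:
    """Smooth per-batch systematic offsets, anchored to 0 at t = 0.

    ``mode='gp'`` draws each offset from a squared-exponential GP with the
    given amplitude (sd, log2 units) and lengthscale (hours);
    ``mode='sinusoid'`` uses amplitude * sin(2 pi t / period) with the
    per-batch amplitudes listed in ``amplitudes``.
    """

    mode: str = "gp"
    amplitude: float = 0.3
    lengthscale: float = 12.0
    amplitudes: tuple[float, ...] | None = None  # sinusoid mode, one per batch
    period: float = 48.0


@dataclass
class SyntheticSpec:
    """Full description of one synthetic growth experiment."""

    base_A: float = 2.0
    base_mu_max: float = 0.3
    base_lam: float = 5.0
    strain_effect: Effect = field(default_factory=Effect)
    stress_effect: Effect = field(default_factory=Effect)
    interaction_effect: Effect = field(default_factory=Effect)
    batch_offsets: BatchOffsets = field(default_factory=BatchOffsets)
    n_batches: int = 1
    include_stress: bool = False
    noise_sd: float = 0.05
    n_replicates: int = 12
    timegrid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 48.0 + 1e-9, 0.5)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.timegrid = np.asarray(self.timegrid, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if np.any(np.diff(self.timegrid) <= 0):
            raise ValueError("timegrid must be strictly increasing")


def mean_curve(spec: SyntheticSpec, strain: int, stress: int) -> np.ndarray:
    """Noiseless ground-truth log2-OD trajectory for one arm."""
    t = spec.timegrid
    A, mu = spec.base_A, spec.base_mu_max
    y = np.zeros_like(t)
    active = []
    if strain:
        active.append(spec.strain_effect)
    if stress:
        active.append(spec.stress_effect)
    if strain and stress:
        active.append(spec.interaction_effect)
    for eff in active:
        A *= eff.a_scale
        mu *= eff.mu_scale
    y = gompertz(t, A, mu, spec.base_lam)
    for eff in active:
        if eff.offset:
            y = y + eff.offset * (1.0 - np.exp(-t / eff.offset_ramp))
        if eff.decline_slope:
            y = y - eff.decline_slope * np.maximum(t - eff.decline_onset, 0.0)
    return y


def _batch_offset(spec: SyntheticSpec, b: int, rng: np.random.Generator) -> np.ndarray:
    bo = spec.batch_offsets
    t = spec.timegrid
    if spec.n_batches <= 1:
        return np.zeros_like(t)
    if bo.mode == "sinusoid":
        amps = bo.amplitudes or tuple(
            bo.amplitude * (1 if i % 2 == 0 else -1) for i in range(spec.n_batches)
        )
        return amps[b] * np.sin(2.0 * np.pi * t / bo.period)
    # GP draw, anchored at zero at t=0 so all curves keep a normalized start
    k = KernelSpec("rbf", variance=bo.amplitude**2, lengthscales=np.array([bo.lengthscale]))
    K = kernel_matrix(t[:, None], t[:, None], k) + 1e-10 * np.eye(len(t))
    draw = rng.multivariate_normal(np.zeros(len(t)), K, method="cholesky")
    return draw - draw[0]


def simulate_dataset(spec: SyntheticSpec) -> GrowthTable:
    """Generate a long-format table of log2-OD observations.

    Strains are labeled 'parent'/'mutant', conditions 'standard'/'stress'
    (stress arms only when ``include_stress``), batches 'batch0', 'batch1',
    ...; every record carries IID Gaussian noise of sd ``noise_sd``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.timegrid
    stresses = (0, 1) if spec.include_stress else (0,)
    rows = []
    for b in range(spec.n_batches):
        offset = _batch_offset(spec, b, rng)
        for strain in (0, 1):
            for stress in stresses:
                mean = mean_curve(spec, strain, stress) + offset
                for r in range(spec.n_replicates):
                    noise = (
                        rng.normal(0.0, spec.noise_sd, len(t))
                        if spec.noise_sd > 0
                        else np.zeros(len(t))
                    )
                    rows.append(
                        pd.DataFrame(
                            {
                                "time": t,
                                "od": mean + noise,
                                "replicate": f"b{b}s{strain}c{stress}r{r}",
                                "strain": "mutant" if strain else "parent",
                                "condition": "stress" if stress else "standard",
                                "batch": f"batch{b}",
                            }
                        )
                    )
    df = pd.concat(rows, ignore_index=True)
    if spec.n_batches == 1:
        df = df.drop(columns=["batch"])
    return GrowthTable(df, is_log=True)


def simulate_null_pair(spec: SyntheticSpec | None = None, seed: int = 0) -> GrowthTable:
    """Parent and 'mutant' drawn from the identical generative process.

    All effect terms are zeroed, so the two strains differ only by
    observation noise — the calibration case for permutation tests.
    """
    spec = spec or SyntheticSpec()
    spec = replace(
        spec,
        strain_effect=Effect(),
        interaction_effect=Effect(),
        seed=seed,
    )
    return simulate_dataset(spec)


def ground_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-arm generative parameters, for sidecar files and oracles."""
    rows = []
    stresses = (0, 1) if spec.include_stress else (0,)
    for strain in (0, 1):
        for stress in stresses:
            A, mu = spec.base_A, spec.base_mu_max
            for eff, on in (
                (spec.strain_effect, strain),
                (spec.stress_effect, stress),
                (spec.interaction_effect, strain and stress),
            ):
                if on:
                    A *= eff.a_scale
                    mu *= eff.mu_scale
            rows.append(
                {
                    "strain": "mutant" if strain else "parent",
                    "condition": "stress" if stress else "standard",
                    "A": A,
                    "mu_max": mu,
                    "lam": spec.base_lam,
                }
            )
    return pd.DataFrame(rows)
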