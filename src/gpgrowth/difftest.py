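"""Differential-growth testing on GP regression models.

Covariates (strain background, stress condition, their interaction) enter
the GP as extra kernel input dimensions with per-dimension lengthscales
(ARD), so an irrelevant covariate can be pruned by driving its lengthscale
large.  Differential growth is scored by an approximate log Bayes factor —
the difference between the maximized log marginal likelihoods of a nested
alternative and null design — and calibrated by permuting strain labels
within each time point to build an empirical null, with the false-discovery
rate read off the permutation distribution.

Two posterior contrasts quantify *where* two growth functions differ:
the strain contrast (mutant minus parent latent growth, baseline-corrected
at t0) and the interaction contrast (mutant growth under stress with vs
without the strain-by-stress interaction).  Both are exact linear
functionals of the joint Gaussian posterior.

A two-level (hierarchical) GP shares a growth function across experimental
batches: observations in batch b have covariance
K_g(x, x') + 1[b = b'] K_f(x, x') + nugget I, so the shared function g is
recovered by conditioning through K_g alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.stats

from .exceptions import FitError, NumericalError, ParameterError, ValidationError
from .gp import (
    FittedGP,
    PosteriorMVN,
    _chol_with_jitter,
    _LOG2PI,
    fit_gp,
)
from .io import GrowthTable
from .kernels import KernelSpec, kernel_matrix

STRAIN_TEST = "strain_test"
STRESS_TEST = "stress_test"


@dataclass
class CovariateDesign:
    """Ordered kernel input columns; time is always first.

    Encodings: strain 0 = parent / 1 = mutant, stress 0 = absent /
    1 = present, interaction = strain * stress (always recomputed, never
    read from the input).
    """

    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.columns or self.columns[0] != "time":
            raise ParameterError("design must start with 'time'")


@dataclass
class BFResult:
    """An approximate log Bayes factor with its permutation null."""

    log_bf: float
    perm_log_bfs: np.ndarray
    percentile: float = 80.0

    @property
    def threshold(self) -> float:
        """Empirical permutation quantile the real score must exceed."""
        return float(np.quantile(self.perm_log_bfs, self.percentile / 100.0))

    @property
    def significant(self) -> bool:
        return self.log_bf > self.threshold

    def fdr(self, c: float) -> float:
        """FDR at threshold c: permuted exceedances over real exceedances,
        the single real test counted at the scale of the permutations."""
        n_perm = len(self.perm_log_bfs)
        n_perm_above = int(np.sum(self.perm_log_bfs > c))
        n_real_above = int(self.log_bf > c) * n_perm
        if n_real_above == 0:
            return float("inf")
        return n_perm_above / n_real_above

    @property
    def fdr_at_real(self) -> float:
        """FDR with the threshold placed just below the real score."""
        n_perm = len(self.perm_log_bfs)
        return float(np.sum(self.perm_log_bfs >= self.log_bf)) / n_perm


# -- design construction ---------------------------------------------------


def _binary_encode(series: pd.Series, zero_level, what: str) -> np.ndarray:
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        raise ValidationError(f"{what} has a single level {levels}; nothing to test")
    if len(levels) > 2:
        raise ValidationError(
            f"{what} has {len(levels)} levels {levels}; pairwise tests only"
        )
    if zero_level is None:
        for guess in ("parent", "control", "standard", "0", "False"):
            if guess in levels:
                zero_level = guess
                break
        else:
            raise ParameterError(
                f"cannot infer the reference level of {what} from {levels}; "
                "pass it explicitly"
            )
    elif str(zero_level) not in levels:
        raise ParameterError(f"reference level {zero_level!r} not among {levels}")
    return (series.astype(str) != str(zero_level)).to_numpy(dtype=float)


def encode_table(
    table: GrowthTable,
    *,
    parent: str | None = None,
    baseline_condition: str | None = None,
) -> GrowthTable:
    """Add numeric design columns x_strain, x_stress, x_interaction."""
    df = table.data.copy()
    if "strain" in df.columns and df["strain"].nunique() > 1:
        df["x_strain"] = _binary_encode(df["strain"], parent, "strain")
    if "condition" in df.columns and df["condition"].nunique() > 1:
        df["x_stress"] = _binary_encode(df["condition"], baseline_condition, "condition")
    if "x_strain" in df.columns and "x_stress" in df.columns:
        df["x_interaction"] = df["x_strain"] * df["x_stress"]
    return GrowthTable(df, table.is_log)


def build_design(
    table: GrowthTable,
    which: str,
    *,
    parent: str | None = None,
    baseline_condition: str | None = None,
) -> tuple[GrowthTable, CovariateDesign, CovariateDesign]:
    """Encode covariates and return (encoded table, null design, alt design).

    ``strain_test`` compares f(time) against f(time, strain);
    ``stress_test`` compares f(time, strain, stress) against
    f(time, strain, stress, strain*stress).
    """
    if which == STRAIN_TEST:
        if "strain" not in table.data.columns:
            raise ValidationError("strain column required for the strain test")
        if table.data["strain"].nunique() < 2:
            raise ValidationError("strain test needs both parent and mutant records")
        enc = encode_table(table, parent=parent, baseline_condition=baseline_condition)
        return (
            enc,
            CovariateDesign(("time",)),
            CovariateDesign(("time", "x_strain")),
        )
    if which == STRESS_TEST:
        for col in ("strain", "condition"):
            if col not in table.data.columns:
                raise ValidationError(f"{col} column required for the stress test")
            if table.data[col].nunique() < 2:
                raise ValidationError(f"stress test needs two levels of {col}")
        enc = encode_table(table, parent=parent, baseline_condition=baseline_condition)
        return (
            enc,
            CovariateDesign(("time", "x_strain", "x_stress")),
            CovariateDesign(("time", "x_strain", "x_stress", "x_interaction")),
        )
    raise ParameterError(f"unknown test {which!r}")


# -- Bayes factors ---------------------------------------------------------


def fit_design(
    table: GrowthTable,
    design: CovariateDesign,
    *,
    restarts: int = 1,
    seed: int = 0,
    maxiter: int = 200,
    spec0: KernelSpec | None = None,
) -> FittedGP:
    """Fit an ARD squared-exponential GP over the design's columns."""
    family = "ard_rbf" if len(design.columns) > 1 else "rbf"
    return fit_gp(
        table, design.columns, spec0=spec0, restarts=restarts, seed=seed,
        family=family, maxiter=maxiter,
    )


def bayes_factor(
    table: GrowthTable,
    null_design: CovariateDesign,
    alt_design: CovariateDesign,
    *,
    restarts: int = 1,
    seed: int = 0,
    maxiter: int = 200,
) -> float:
    """Approximate log Bayes factor between two nested designs.

    Both marginal likelihoods use point-estimated (type-II ML)
    hyperparameters, so the Bayes factor is approximate by construction.
    """
    if not set(null_design.columns) <= set(alt_design.columns):
        raise ParameterError("designs must be nested (alt must contain null columns)")
    alt = fit_design(table, alt_design, restarts=restarts, seed=seed, maxiter=maxiter)
    null = fit_design(table, null_design, restarts=restarts, seed=seed, maxiter=maxiter)
    return float(alt.log_marginal - null.log_marginal)


def permute_strain_labels(
    table: GrowthTable,
    covariate: str = "strain",
    seed: int = 0,
    *,
    within: tuple[str, ...] = (),
) -> GrowthTable:
    """Shuffle covariate labels across observations within each time point.

    The multiset of labels at every time point (and within every level of
    the ``within`` columns, e.g. the stress arm or batch) is preserved, so
    the permuted data share the original label distribution exactly.
    """
    if covariate not in table.data.columns:
        raise ParameterError(f"covariate {covariate!r} not in table")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    values = df[covariate].to_numpy().copy()
    keys = ["time"] + [c for c in within if c in df.columns]
    for _, idx in sorted(
        df.groupby(keys, sort=True, observed=True).indices.items(),
        key=lambda kv: str(kv[0]),
    ):
        idx = np.asarray(idx)
        values[idx] = values[idx[rng.permutation(len(idx))]]
    df[covariate] = values
    # any derived encodings are stale; drop so they are recomputed
    df = df.drop(columns=[c for c in ("x_strain", "x_interaction") if c in df.columns])
    return GrowthTable(df, table.is_log)


def permutation_test(
    table: GrowthTable,
    which: str = STRAIN_TEST,
    n_perm: int = 100,
    seed: int = 0,
    *,
    parent: str | None = None,
    baseline_condition: str | None = None,
    percentile: float = 80.0,
    restarts: int = 1,
    maxiter: int = 200,
) -> BFResult:
    """Log Bayes factor with a permutation-calibrated significance call.

    The strain label is shuffled within each time point (within each
    stress arm for the stress test, so the interaction column is rebuilt
    from permuted strain labels); the real score is significant when it
    exceeds the ``percentile``-th percentile of the permuted scores.
    """
    if n_perm < 5:
        raise ParameterError("n_perm < 5 gives an uninformative null")
    enc, null_design, alt_design = build_design(
        table, which, parent=parent, baseline_condition=baseline_condition
    )
    kw = dict(restarts=restarts, maxiter=maxiter)
    alt = fit_design(enc, alt_design, seed=seed, **kw)
    null = fit_design(enc, null_design, seed=seed, **kw)
    real = float(alt.log_marginal - null.log_marginal)

    within = ("condition",) if which == STRESS_TEST else ()
    # the strain-test null design involves only time, so its marginal
    # likelihood is unchanged by the strain permutation and can be reused
    null_is_static = "x_strain" not in null_design.columns

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        pseed = int(rng.integers(0, 2**31 - 1))
        shuffled = permute_strain_labels(table, "strain", pseed, within=within)
        penc, pnull, palt = build_design(
            shuffled, which, parent=parent, baseline_condition=baseline_condition
        )
        palt_fit = fit_design(penc, palt, seed=pseed, **kw)
        if null_is_static:
            pnull_lml = null.log_marginal
        else:
            pnull_lml = fit_design(penc, pnull, seed=pseed, **kw).log_marginal
        perm[i] = palt_fit.log_marginal - pnull_lml
    return BFResult(real, perm, percentile)


# -- posterior contrasts ---------------------------------------------------


@dataclass
class ODDeltaSeries:
    """Baseline-corrected difference of two latent growth functions."""

    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant_mask,
            }
        )


def od_delta(
    model: FittedGP,
    times,
    mode: str = "strain_contrast",
    *,
    t0: float | None = None,
    at: dict | None = None,
    level: float = 0.95,
) -> ODDeltaSeries:
    """Per-time-point posterior contrast between two growth functions.

    ``strain_contrast`` compares mutant vs parent latent growth;
    ``interaction_contrast`` compares mutant growth under stress with and
    without the strain-by-stress interaction term.  For each time t_k the
    quadruple (f_on(t_k), f_on(t0), f_off(t_k), f_off(t0)) is jointly
    Gaussian under the fitted GP, and the contrast a = [1, -1, -1, 1]
    subtracts the t0 difference so the series starts at exactly zero.
    A time point is flagged significant when the central credible interval
    at ``level`` excludes zero.
    """
    times = np.asarray(times, dtype=float).ravel()
    if t0 is None:
        t0 = float(model.X[:, 0].min())
    if not np.any(np.isclose(times, t0)):
        times = np.concatenate([[t0], times])
    order = np.argsort(times)
    times = times[order]

    d = model.X.shape[1]
    design = model.design
    if mode == "strain_contrast":
        if "x_strain" not in design:
            raise ParameterError("model design lacks a strain column")
        switch = design.index("x_strain")
        on_vals, off_vals = 1.0, 0.0
    elif mode == "interaction_contrast":
        if "x_interaction" not in design:
            raise ParameterError("model design lacks an interaction column")
        switch = design.index("x_interaction")
        on_vals, off_vals = 1.0, 0.0
        at = dict(at or {})
        at.setdefault("x_strain", 1.0)
        at.setdefault("x_stress", 1.0)
    else:
        raise ParameterError(f"unknown contrast mode {mode!r}")

    def block(value: float) -> np.ndarray:
        Xs = np.zeros((len(times), d))
        Xs[:, 0] = times
        Xs[:, switch] = value
        if at:
            for name, v in at.items():
                j = design.index(name)
                if j != switch:
                    Xs[:, j] = v
        return Xs

    Xjoint = np.vstack([block(on_vals), block(off_vals)])
    post = model.predict(Xjoint, include_noise=False)
    T = len(times)
    i0 = int(np.argmin(np.abs(times - t0)))
    idx_on, idx_off = np.arange(T), T + np.arange(T)

    a_rows = np.zeros((T, 2 * T))
    a_rows[np.arange(T), idx_on] = 1.0
    a_rows[np.arange(T), idx_on[i0]] -= 1.0
    a_rows[np.arange(T), idx_off] -= 1.0
    a_rows[np.arange(T), idx_off[i0]] += 1.0

    mean = a_rows @ post.mean
    var = np.maximum(np.einsum("ij,jk,ik->i", a_rows, post.cov, a_rows), 0.0)
    mean[i0] = 0.0
    var[i0] = 0.0
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    sd = np.sqrt(var)
    lo, hi = mean - z * sd, mean + z * sd
    sig = (lo > 0) | (hi < 0)
    sig[i0] = False
    return ODDeltaSeries(times, mean, var, lo, hi, sig)


# -- hierarchical (cross-study) model --------------------------------------


@dataclass
class HierarchicalGP:
    """Two-level GP: shared growth function g plus per-batch deviations.

    The joint covariance of observations (x, b) and (x', b') is
    K_g(x, x') + 1[b = b'] K_f(x, x') + nugget 1[(x,b) = (x',b')].
    """

    design: list[str]
    X: np.ndarray
    y: np.ndarray
    batch: np.ndarray
    batches: list
    kernel_shared: KernelSpec
    kernel_batch: KernelSpec
    nugget: float
    log_marginal: float
    chol: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)

    def predict_shared(self, Xstar) -> PosteriorMVN:
        """Posterior of the batch-corrected shared growth function g."""
        Xstar = np.asarray(Xstar, dtype=float)
        if Xstar.ndim == 1:
            Xstar = Xstar[:, None]
        Ks = kernel_matrix(Xstar, self.X, self.kernel_shared)
        Kss = kernel_matrix(Xstar, Xstar, self.kernel_shared)
        mean = Ks @ self.alpha
        V = sla.solve_triangular(self.chol, Ks.T, lower=True)
        cov = Kss - V.T @ V
        return PosteriorMVN(Xstar, mean, 0.5 * (cov + cov.T))

    def predict_batch_deviation(self, b, Xstar) -> PosteriorMVN:
        """Posterior of the deviation f_b of batch b around g."""
        Xstar = np.asarray(Xstar, dtype=float)
        if Xstar.ndim == 1:
            Xstar = Xstar[:, None]
        mask = (self.batch == self.batches.index(b)).astype(float)
        Ks = kernel_matrix(Xstar, self.X, self.kernel_batch) * mask[None, :]
        Kss = kernel_matrix(Xstar, Xstar, self.kernel_batch)
        mean = Ks @ self.alpha
        V = sla.solve_triangular(self.chol, Ks.T, lower=True)
        cov = Kss - V.T @ V
        return PosteriorMVN(Xstar, mean, 0.5 * (cov + cov.T))

    def predict_batch(self, b, Xstar) -> PosteriorMVN:
        """Posterior of batch b's growth function g + f_b."""
        Xstar = np.asarray(Xstar, dtype=float)
        if Xstar.ndim == 1:
            Xstar = Xstar[:, None]
        mask = (self.batch == self.batches.index(b)).astype(float)
        Ks = (
            kernel_matrix(Xstar, self.X, self.kernel_shared)
            + kernel_matrix(Xstar, self.X, self.kernel_batch) * mask[None, :]
        )
        Kss = kernel_matrix(Xstar, Xstar, self.kernel_shared) + kernel_matrix(
            Xstar, Xstar, self.kernel_batch
        )
        mean = Ks @ self.alpha
        V = sla.solve_triangular(self.chol, Ks.T, lower=True)
        cov = Kss - V.T @ V
        return PosteriorMVN(Xstar, mean, 0.5 * (cov + cov.T))


def _stack_batches(tables: list[GrowthTable]) -> GrowthTable:
    frames = []
    for i, t in enumerate(tables):
        df = t.data.copy()
        if "batch" not in df.columns:
            df["batch"] = f"batch{i}"
        frames.append(df)
    return GrowthTable(pd.concat(frames, ignore_index=True), tables[0].is_log)


def _hier_lml_and_grad(theta, X, y, batch_mask, d):
    """theta: log [var_g, ls(d), rho, nugget]; the batch-deviation kernel
    shares the ARD lengthscales of the shared kernel with amplitude
    var_f = rho * var_g, rho <= 1.  Tying the lengthscales keeps the
    two levels identified: the batch level can only carry deviations, not
    re-explain the shared trend with a smoother process."""
    p = np.exp(theta)
    var_g, ls, rho, nug = p[0], p[1 : 1 + d], p[1 + d], p[-1]
    kg = KernelSpec("ard_rbf", variance=var_g, lengthscales=ls)
    kf = KernelSpec("ard_rbf", variance=rho * var_g, lengthscales=ls)
    Kg = kernel_matrix(X, X, kg)
    Kf = Kg * rho * batch_mask
    K = Kg + Kf
    K[np.diag_indices_from(K)] += nug
    L, _ = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * _LOG2PI
    Kinv = sla.cho_solve((L, True), np.eye(len(y)))
    W = np.outer(alpha, alpha) - Kinv
    grads = [Kg + Kf]  # d/dlog var_g (both levels scale with var_g)
    for k in range(d):
        dk2 = (X[:, k][:, None] - X[:, k][None, :]) ** 2 / ls[k] ** 2
        grads.append((Kg + Kf) * 2.0 * dk2)
    grads.append(Kf)  # d/dlog rho
    grads.append(nug * np.eye(len(y)))
    g = np.array([0.5 * np.sum(W * dK) for dK in grads])
    return float(lml), g, (kg, kf, nug, L, alpha)


def hierarchical_fit(
    tables: list[GrowthTable],
    design: CovariateDesign | tuple[str, ...] = ("time",),
    *,
    restarts: int = 1,
    seed: int = 0,
    maxiter: int = 200,
) -> HierarchicalGP | FittedGP:
    """Joint two-level GP fit across experimental batches.

    With a single batch this falls back to a plain GP fit (with a warning);
    with two or more, the shared and per-batch ARD kernels plus the nugget
    are optimized jointly by type-II maximum likelihood.
    """
    cols = design.columns if isinstance(design, CovariateDesign) else tuple(design)
    if len(tables) < 2:
        warnings.warn("single batch: falling back to a plain GP fit", stacklevel=2)
        return fit_gp(tables[0], cols, restarts=restarts, seed=seed, family="ard_rbf")
    stacked = _stack_batches(tables)
    from .gp import _design_matrix  # local import to avoid cycle at module load

    X = _design_matrix(stacked, cols)
    y = stacked.od
    batches = list(pd.unique(stacked.data["batch"]))
    bidx = np.array([batches.index(b) for b in stacked.data["batch"]])
    batch_mask = (bidx[:, None] == bidx[None, :]).astype(float)
    d = X.shape[1]

    var0 = max(float(np.var(y)), 1e-4)
    from .gp import default_init_lengthscales

    ls0 = default_init_lengthscales(X)
    theta0 = np.log(np.concatenate([[var0], ls0, [0.25], [0.1 * var0]]))
    lo = np.concatenate(
        [[np.log(1e-6)], np.full(d, np.log(1e-2)), [np.log(1e-6)], [np.log(1e-10)]]
    )
    hi = np.concatenate(
        [[np.log(1e4)], np.full(d, np.log(1e3)), [0.0], [np.log(1e2)]]
    )
    bounds = list(zip(lo, hi))
    rng = np.random.default_rng(seed)

    def negobj(theta):
        try:
            lml, g, _ = _hier_lml_and_grad(theta, X, y, batch_mask, d)
        except NumericalError:
            return 1e10, np.zeros_like(theta)
        return -lml, -g

    best = None
    for r in range(max(restarts, 1)):
        start = theta0 if r == 0 else np.clip(theta0 + rng.normal(0, 1.0, len(theta0)), lo, hi)
        res = scipy.optimize.minimize(
            negobj, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("hierarchical optimization failed on all restarts")
    lml, _, (kg, kf, nug, L, alpha) = _hier_lml_and_grad(best.x, X, y, batch_mask, d)
    return HierarchicalGP(
        design=list(cols),
        X=X,
        y=y,
        batch=bidx,
        batches=batches,
        kernel_shared=kg,
        kernel_batch=kf,
        nugget=nug,
        log_marginal=lml,
        chol=L,
        alpha=alpha,
    )


def hierarchical_bf(
    tables: list[GrowthTable],
    n_perm: int = 100,
    seed: int = 0,
    *,
    parent: str | None = None,
    baseline_condition: str | None = None,
    percentile: float = 80.0,
    restarts: int = 1,
    maxiter: int = 200,
) -> BFResult:
    """Cross-study interaction test with batch effects modeled.

    The log Bayes factor is the difference of hierarchical log marginal
    likelihoods between the interaction (alternative) and no-interaction
    (null) designs; permutations shuffle strain labels within each
    (batch, time point, stress arm).
    """
    if n_perm < 5:
        raise ParameterError("n_perm < 5 gives an uninformative null")

    def encode_all(tabs):
        return [
            encode_table(t, parent=parent, baseline_condition=baseline_condition)
            for t in tabs
        ]

    alt_cols = ("time", "x_strain", "x_stress", "x_interaction")
    null_cols = ("time", "x_strain", "x_stress")

    def score(tabs, s):
        enc = encode_all(tabs)
        alt = hierarchical_fit(enc, alt_cols, restarts=restarts, seed=s, maxiter=maxiter)
        null = hierarchical_fit(enc, null_cols, restarts=restarts, seed=s, maxiter=maxiter)
        return float(alt.log_marginal - null.log_marginal)

    real = score(tables, seed)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        pseed = int(rng.integers(0, 2**31 - 1))
        shuffled = [
            permute_strain_labels(t, "strain", pseed + j, within=("condition", "batch"))
            for j, t in enumerate(tables)
        ]
        perm[i] = score(shuffled, pseed)
    return BFResult(real, perm, percentile)


# -- enrichment ------------------------------------------------------------


def enrichment_test(
    population: int,
    successes_in_population: int,
    drawn: int,
    successes_drawn: int,
) -> float:
    """Upper-tail hypergeometric P(X >= successes_drawn)."""
    if not (
        0 <= successes_in_population <= population
        and 0 <= drawn <= population
        and 0 <= successes_drawn <= min(drawn, successes_in_population)
    ):
        raise ParameterError("inconsistent counts for the hypergeometric test")
    return float(
        scipy.stats.hypergeom.sf(
            successes_drawn - 1, population, successes_in_population, drawn
        )
    )
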