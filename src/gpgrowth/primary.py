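"""Classical parametric ("primary") growth models and the MSE benchmark.

The four sigmoid models — Gompertz, population logistic, Schnute and
Richards — share the biologically interpreted parameters A (carrying
capacity, absent in Schnute), mu_max (maximum specific growth rate) and
lambda (lag time); Schnute adds shape parameters (a, b) and Richards adds
v.  Parameters are estimated by damped least squares (Levenberg-Marquardt)
and fits are compared to the GP model by mean squared error on held-out
data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .exceptions import DomainError, ParameterError
from .gp import fit_gp
from .io import GrowthTable, train_test_split

MODEL_NAMES = ("gompertz", "logistic", "schnute", "richards")

_E = math.e


def gompertz(t, A, mu_max, lam):
    """A * exp(-exp(mu_max * e / A * (lam - t) + 1))."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu_max * _E / A * (lam - t) + 1.0))


def logistic(t, A, mu_max, lam):
    """A / (1 + exp(4 * mu_max / A * (lam - t) + 2))."""
    t = np.asarray(t, dtype=float)
    return A / (1.0 + np.exp(4.0 * mu_max / A * (lam - t) + 2.0))


def schnute(t, mu_max, lam, a, b):
    """mu_max * (1-b)/a * [(1 - b*exp(a*lam + 1 - b - a*t)) / (1-b)]^(1/b).

    Gompertz is the a > 0, b -> 0 limit of this family.
    """
    if a == 0 or b == 0:
        raise DomainError(
            "a=0 or b=0 are limiting cases of the Schnute family; "
            "use the Gompertz model for the a>0, b->0 limit"
        )
    t = np.asarray(t, dtype=float)
    base = (1.0 - b * np.exp(a * lam + 1.0 - b - a * t)) / (1.0 - b)
    if np.any(base < 0) and not float(1.0 / b).is_integer():
        raise DomainError("negative base with non-integer exponent 1/b")
    return mu_max * (1.0 - b) / a * np.sign(base) * np.abs(base) ** (1.0 / b)


def richards(t, A, mu_max, lam, v):
    """A * [1 + v*exp(1+v) * exp(mu_max/A * (1+v)^(1+1/v) * (lam-t))]^(-1/v).

    Reduces to the population logistic at v = 1.
    """
    if v <= 0:
        raise ParameterError("shape parameter v must be positive")
    t = np.asarray(t, dtype=float)
    inner = mu_max / A * (1.0 + v) ** (1.0 + 1.0 / v) * (lam - t)
    return A * (1.0 + v * np.exp(1.0 + v) * np.exp(inner)) ** (-1.0 / v)


def mse(y, m) -> float:
    """Mean squared error between observations y and model predictions m."""
    y = np.asarray(y, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    if len(y) != len(m):
        raise ParameterError("length mismatch between y and m")
    if len(y) == 0:
        raise ParameterError("empty vectors")
    return float(np.mean((y - m) ** 2))


# -- fitting ---------------------------------------------------------------


def _schnute_safe(t, mu_max, lam, a, b):
    """Schnute evaluation for the optimizer: invalid regions are clipped
    rather than raised so least squares can move through them."""
    t = np.asarray(t, dtype=float)
    a = np.where(np.abs(a) < 1e-8, 1e-8, a)
    b = np.where(np.abs(b) < 1e-8, 1e-8, b)
    with np.errstate(over="ignore", invalid="ignore"):
        base = (1.0 - b * np.exp(np.clip(a * lam + 1.0 - b - a * t, -500, 500))) / (1.0 - b)
        base = np.maximum(base, 1e-12)
        out = mu_max * (1.0 - b) / a * base ** (1.0 / b)
    return np.nan_to_num(out, nan=0.0, posinf=1e6, neginf=-1e6)


def _richards_safe(t, A, mu_max, lam, v):
    t = np.asarray(t, dtype=float)
    v = max(v, 1e-6)
    A = np.where(np.abs(A) < 1e-8, 1e-8, A)
    with np.errstate(over="ignore", invalid="ignore"):
        inner = np.clip(mu_max / A * (1.0 + v) ** (1.0 + 1.0 / v) * (lam - t), -500, 500)
        out = A * (1.0 + v * np.exp(1.0 + v) * np.exp(inner)) ** (-1.0 / v)
    return np.nan_to_num(out, nan=0.0, posinf=1e6, neginf=-1e6)


_FIT_FUNCS = {
    "gompertz": (gompertz, ("A", "mu_max", "lam")),
    "logistic": (logistic, ("A", "mu_max", "lam")),
    "schnute": (_schnute_safe, ("mu_max", "lam", "a", "b")),
    "richards": (_richards_safe, ("A", "mu_max", "lam", "v")),
}


@dataclass
class PrimaryFit:
    """Result of least-squares fitting one primary model to one curve."""

    model_name: str
    params: dict = field(default_factory=dict)
    converged: bool = False
    mse_train: float = float("nan")
    mse_test: float = float("nan")

    def predict(self, t) -> np.ndarray:
        func, names = _FIT_FUNCS[self.model_name]
        return np.asarray(func(t, *[self.params[n] for n in names]), dtype=float)


def _heuristic_init(model_name: str, t: np.ndarray, y: np.ndarray) -> list[float]:
    A = max(float(np.max(y)), 0.1)
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    if len(ts) > 1:
        slopes = np.diff(ys) / np.maximum(np.diff(ts), 1e-9)
        mu = max(float(np.max(slopes)), 1e-3)
        lam = float(ts[np.argmax(slopes)])
    else:
        mu, lam = 0.1, 0.0
    if model_name == "gompertz" or model_name == "logistic":
        return [A, mu, lam]
    if model_name == "schnute":
        return [mu, lam, 0.1, 0.1]
    return [A, mu, lam, 1.0]


def fit_primary(
    model_name: str,
    curve: GrowthTable,
    init: list[float] | None = None,
    *,
    maxfev: int = 5000,
) -> PrimaryFit:
    """Damped least-squares fit of one primary model to a single curve.

    Non-convergence never raises; it is reported through ``converged`` so a
    benchmark over many curves can score failures as missing.
    """
    if model_name not in _FIT_FUNCS:
        raise ParameterError(f"unknown model {model_name!r}")
    if not curve.is_log:
        raise ParameterError("curve must be log2-transformed before fitting")
    t, y = curve.times, curve.od
    func, names = _FIT_FUNCS[model_name]
    p0 = init if init is not None else _heuristic_init(model_name, t, y)
    fit = PrimaryFit(model_name)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.optimize.OptimizeWarning)
            popt, _ = scipy.optimize.curve_fit(
                func, t, y, p0=p0, method="lm", maxfev=maxfev
            )
        if not np.all(np.isfinite(popt)):
            return fit
    except (RuntimeError, ValueError, scipy.optimize.OptimizeWarning):
        return fit
    fit.params = dict(zip(names, [float(v) for v in popt]))
    fit.converged = True
    fit.mse_train = mse(y, fit.predict(t))
    return fit


# -- benchmarking against the GP -------------------------------------------


@dataclass
class BenchmarkReport:
    """Per-curve held-out MSE for the GP and each primary model."""

    per_curve: pd.DataFrame  # columns: curve, model, mse (NaN = unconverged)
    summary: pd.DataFrame  # per model: mean/sd MSE, n_missing, t, p vs GP

    def mean_mse(self, model: str) -> float:
        rows = self.per_curve[self.per_curve["model"] == model]
        return float(rows["mse"].mean())


def benchmark_models(
    tables: list[GrowthTable],
    seed: int = 0,
    *,
    train_frac: float = 0.8,
    models: tuple[str, ...] = MODEL_NAMES,
    gp_restarts: int = 2,
) -> BenchmarkReport:
    """80/20 split benchmark of GP regression against the primary models.

    Each curve is randomly split, every model is fit on the training
    portion, and MSE is measured on the held-out portion (GP predictions
    are the posterior mean).  The summary reports, per primary model, a
    one-sided Welch t-test of whether GP held-out MSE is smaller.
    """
    if len(tables) < 2:
        raise ParameterError("need at least 2 curves to benchmark")
    rows = []
    rng = np.random.default_rng(seed)
    for i, curve in enumerate(tables):
        split_seed = int(rng.integers(0, 2**31 - 1))
        train, test = train_test_split(curve, train_frac, seed=split_seed)
        gp = fit_gp(train, ("time",), restarts=gp_restarts, seed=split_seed)
        pred = gp.predict(test.times[:, None]).mean
        rows.append({"curve": i, "model": "gp", "mse": mse(test.od, pred)})
        for name in models:
            fit = fit_primary(name, train)
            val = mse(test.od, fit.predict(test.times)) if fit.converged else np.nan
            rows.append({"curve": i, "model": name, "mse": val})
    per_curve = pd.DataFrame(rows)

    gp_mse = per_curve.loc[per_curve["model"] == "gp", "mse"].to_numpy()
    summary_rows = []
    for name in ("gp",) + tuple(models):
        vals = per_curve.loc[per_curve["model"] == name, "mse"].to_numpy()
        ok = vals[np.isfinite(vals)]
        row = {
            "model": name,
            "mean_mse": float(np.mean(ok)) if len(ok) else np.nan,
            "sd_mse": float(np.std(ok, ddof=1)) if len(ok) > 1 else np.nan,
            "n_missing": int(np.sum(~np.isfinite(vals))),
        }
        if name != "gp":
            if len(ok) > 1 and (np.std(ok, ddof=1) > 0 or np.std(gp_mse, ddof=1) > 0):
                t, p = scipy.stats.ttest_ind(
                    gp_mse, ok, equal_var=False, alternative="less"
                )
                row["t_gp_less"], row["p_gp_less"] = float(t), float(p)
            else:
                row["t_gp_less"], row["p_gp_less"] = np.nan, np.nan
        summary_rows.append(row)
    return BenchmarkReport(per_curve, pd.DataFrame(summary_rows))


def parameter_ttest(group_a, group_b, alternative: str = "two-sided"):
    """Welch t-test between two populations of parameter estimates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    return scipy.stats.ttest_ind(a, b, equal_var=False, alternative=alternative)


def bonferroni(pvalues, fwer: float = 0.25) -> np.ndarray:
    """Significance mask controlling the family-wise error rate by the
    Bonferroni bound across the tests supplied."""
    p = np.asarray(pvalues, dtype=float)
    return p <= fwer / len(p)
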