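"""GP regression: marginal likelihood, hyperparameter fitting, prediction.

The model is a zero-mean Gaussian process on log2-OD over inputs
(time, covariates...).  With kernel K and nugget variance sigma2_n, the n
training observations are jointly N(0, K(X, X) + sigma2_n I); kernel
hyperparameters are set by maximizing this marginal likelihood (type-II
maximum likelihood) with a log-parameterized L-BFGS-B search and random
restarts.  Prediction is the standard Gaussian conditional.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.optimize

from .exceptions import FitError, NumericalError, ParameterError
from .io import GrowthTable
from .kernels import (
    KernelSpec,
    kernel_gradients,
    kernel_matrix,
    logparams_to_spec,
    spec_to_logparams,
    training_covariance,
)

_LOG2PI = float(np.log(2.0 * np.pi))

#: jitter escalation schedule for Cholesky failures
_JITTERS = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)

#: optimizer bounds, in log space
_BOUNDS = {
    "variance": (np.log(1e-6), np.log(1e4)),
    "lengthscale": (np.log(1e-2), np.log(1e3)),
    "nugget": (np.log(1e-10), np.log(1e2)),
}


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    for jit in _JITTERS:
        try:
            L = sla.cholesky(K + jit * np.eye(len(K)), lower=True)
            return L, jit
        except sla.LinAlgError:
            continue
    smallest = float(np.linalg.eigvalsh(K)[0])
    raise NumericalError(
        f"covariance not positive definite after jitter escalation "
        f"(smallest eigenvalue {smallest:.3e})"
    )


@dataclass
class PosteriorMVN:
    """Multivariate-normal posterior of latent growth (or its derivative)."""

    locations: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    includes_noise: bool = False

    @property
    def var(self) -> np.ndarray:
        return np.maximum(np.diag(self.cov), 0.0)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.var)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.mean - z * self.sd, self.mean + z * self.sd

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Draw n joint samples (rows) using an eigendecomposition with
        negative eigenvalues clipped to zero (PSD up to jitter)."""
        rng = np.random.default_rng(seed)
        C = 0.5 * (self.cov + self.cov.T)
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        A = V * np.sqrt(w)
        z = rng.standard_normal((n, len(self.mean)))
        return self.mean + z @ A.T


def log_marginal_likelihood(X, y, spec: KernelSpec) -> float:
    """log N(y; 0, K(X,X) + nugget I) under the given kernel spec."""
    y = np.asarray(y, dtype=float).ravel()
    K = training_covariance(X, spec)
    if len(y) != len(K):
        raise ParameterError("y length does not match rows of X")
    L, _ = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * _LOG2PI
    )


def _lml_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, template: KernelSpec):
    spec = logparams_to_spec(theta, template)
    K = training_covariance(X, spec)
    L, _ = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * _LOG2PI
    Kinv = sla.cho_solve((L, True), np.eye(len(y)))
    W = np.outer(alpha, alpha) - Kinv
    grads = kernel_gradients(X, spec)
    g = np.array([0.5 * np.sum(W * dK) for dK in grads])
    return float(lml), g


@dataclass
class FittedGP:
    """A trained GP regression model on growth data."""

    design: list[str]
    X: np.ndarray
    y: np.ndarray
    kernel: KernelSpec
    log_marginal: float
    chol: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.y)

    def predict(self, Xstar, include_noise: bool = False) -> PosteriorMVN:
        return predict_posterior(self, Xstar, include_noise)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        k = self.kernel
        return {
            "design": list(self.design),
            "kernel": {
                "family": k.family,
                "variance": float(k.variance),
                "lengthscales": [float(v) for v in k.lengthscales],
                "nugget": float(k.nugget),
                "weights": None if k.weights is None else [float(v) for v in k.weights],
            },
            "log_marginal": float(self.log_marginal),
            "n": self.n,
            "data_digest": hashlib.sha256(
                np.ascontiguousarray(self.X).tobytes()
                + np.ascontiguousarray(self.y).tobytes()
            ).hexdigest()[:16],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _design_matrix(table: GrowthTable, design: Sequence[str]) -> np.ndarray:
    cols = []
    for name in design:
        if name == "time":
            cols.append(table.times)
        else:
            if name not in table.data.columns:
                raise ParameterError(f"design column {name!r} not in table")
            col = table.data[name]
            if not np.issubdtype(col.dtype, np.number):
                raise ParameterError(
                    f"design column {name!r} must be numerically encoded "
                    "(see difftest.build_design)"
                )
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def default_init_lengthscales(X: np.ndarray) -> np.ndarray:
    """Per-dimension starting lengthscales: a quarter of the span for
    continuous inputs, 1.0 for binary-like inputs (where a quarter-span
    start would decorrelate the levels so strongly the gradient dies)."""
    ls = np.empty(X.shape[1])
    for k in range(X.shape[1]):
        n_distinct = len(np.unique(X[:, k]))
        span = X[:, k].max() - X[:, k].min()
        ls[k] = max(span / 4.0, 1e-1) if n_distinct > 3 else 1.0
    return ls


def _default_spec(family: str, X: np.ndarray, y: np.ndarray) -> KernelSpec:
    d = X.shape[1]
    var = max(float(np.var(y)), 1e-4)
    ls_all = default_init_lengthscales(X)
    if family == "ard_rbf":
        ls = ls_all
    else:
        ls = ls_all[:1]
    if family == "linear":
        return KernelSpec("linear", weights=np.ones(d), nugget=0.1 * var)
    return KernelSpec(family, variance=var, lengthscales=ls, nugget=0.1 * var)


def gp_from_spec(X, y, spec: KernelSpec, *, design: Sequence[str] | None = None) -> FittedGP:
    """Build a :class:`FittedGP` at fixed hyperparameters (no optimization)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    K = training_covariance(X, spec)
    L, _ = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), y)
    lml = float(-0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * _LOG2PI)
    return FittedGP(
        design=list(design) if design is not None else [f"x{i}" for i in range(X.shape[1])],
        X=X,
        y=y,
        kernel=spec,
        log_marginal=lml,
        chol=L,
        alpha=alpha,
    )


def fit_gp_xy(
    X,
    y,
    spec0: KernelSpec,
    *,
    design: Sequence[str] | None = None,
    restarts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
) -> FittedGP:
    """Optimize kernel hyperparameters on raw arrays; best of ``restarts``
    random log-space initializations (the first start is ``spec0`` itself)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    theta0 = spec_to_logparams(spec0)
    if spec0.family == "linear":
        bounds = [_BOUNDS["variance"]] * (len(theta0) - 1) + [_BOUNDS["nugget"]]
    else:
        bounds = (
            [_BOUNDS["variance"]]
            + [_BOUNDS["lengthscale"]] * (len(theta0) - 2)
            + [_BOUNDS["nugget"]]
        )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    best = None
    failures = []
    for r in range(max(restarts, 1)):
        start = theta0 if r == 0 else np.clip(theta0 + rng.normal(0, 1.0, len(theta0)), lo, hi)

        def negobj(theta):
            try:
                lml, g = _lml_and_grad(theta, X, y, spec0)
            except NumericalError:
                return 1e10, np.zeros_like(theta)
            return -lml, -g

        try:
            res = scipy.optimize.minimize(
                negobj,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {restarts} restarts failed: {failures}")

    spec = logparams_to_spec(best.x, spec0)
    K = training_covariance(X, spec)
    L, _ = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), y)
    lml = float(-0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * _LOG2PI)
    return FittedGP(
        design=list(design) if design is not None else [f"x{i}" for i in range(X.shape[1])],
        X=X,
        y=y,
        kernel=spec,
        log_marginal=lml,
        chol=L,
        alpha=alpha,
    )


def fit_gp(
    table: GrowthTable,
    design: Sequence[str] = ("time",),
    spec0: KernelSpec | None = None,
    restarts: int = 5,
    seed: int = 0,
    family: str = "rbf",
    maxiter: int = 200,
) -> FittedGP:
    """Fit a GP to a growth table over the given design columns.

    ``design`` lists input columns in order, time first; non-time columns
    must already be numerically encoded.  ``spec0`` overrides the
    data-driven default initialization (whose family is ``family``).
    """
    if not table.is_log:
        raise ParameterError("table must be log2-transformed (is_log=True) before fitting")
    X = _design_matrix(table, design)
    y = table.od
    if spec0 is None:
        spec0 = _default_spec(family, X, y)
    return fit_gp_xy(
        X, y, spec0, design=design, restarts=restarts, seed=seed, maxiter=maxiter
    )


def predict_posterior(model: FittedGP, Xstar, include_noise: bool = False) -> PosteriorMVN:
    """Gaussian conditional of the latent function at the query inputs."""
    Xstar = np.asarray(Xstar, dtype=float)
    if Xstar.ndim == 1:
        Xstar = Xstar[:, None]
    if Xstar.shape[1] != model.X.shape[1]:
        raise ParameterError("query dimension does not match training design")
    Ks = kernel_matrix(Xstar, model.X, model.kernel)
    Kss = kernel_matrix(Xstar, Xstar, model.kernel)
    mean = Ks @ model.alpha
    V = sla.solve_triangular(model.chol, Ks.T, lower=True)
    cov = Kss - V.T @ V
    cov = 0.5 * (cov + cov.T)
    if include_noise:
        cov[np.diag_indices_from(cov)] += model.kernel.nugget
    return PosteriorMVN(Xstar, mean, cov, includes_noise=include_noise)


def bic(model: FittedGP) -> float:
    """Bayesian information criterion, -2 log L + k log n, with k the
    number of kernel hyperparameters and n the number of observations."""
    k = model.kernel.n_params
    return -2.0 * model.log_marginal + k * np.log(model.n)
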