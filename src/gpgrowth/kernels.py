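"""Covariance functions for GP growth-curve regression.

Four families are supported:

``rbf``
    squared exponential with a single lengthscale,
    k(x, x') = sigma2 * exp(-||x - x'||^2 / l^2).
``ard_rbf``
    squared exponential with one lengthscale per input dimension
    (automatic relevance determination),
    k(x, x') = sigma2 * exp(-sum_k (x_k - x'_k)^2 / l_k^2).
``matern32``
    Matern with smoothness 3/2, k(r) = sigma2 * (1 + sqrt(3) r) exp(-sqrt(3) r)
    with r = ||x - x'|| / l.
``linear``
    dot-product kernel k(x, x') = sum_k w_k x_k x'_k.

Note the squared-exponential convention here has no 1/2 factor and uses
l^2 in the denominator; this only reparameterizes the lengthscale relative
to the textbook form.  Observation noise is an additive "nugget" variance
on coincident inputs (one independent draw per observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError

FAMILIES = ("rbf", "ard_rbf", "matern32", "linear")


@dataclass
class KernelSpec:
    """Kernel family plus hyperparameters.

    ``lengthscales`` has one entry for rbf/matern32 and one per input
    dimension for ard_rbf; ``weights`` is used only by the linear family.
    ``nugget`` is the IID Gaussian observation-noise variance.
    """

    family: str
    variance: float = 1.0
    lengthscales: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    nugget: float = 0.0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown kernel family {self.family!r}")
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.weights is not None:
            self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.variance <= 0:
            raise ParameterError("variance must be strictly positive")
        if self.family != "linear" and (self.lengthscales <= 0).any():
            raise ParameterError("lengthscales must be strictly positive")
        if self.family == "linear" and self.weights is not None and (self.weights <= 0).any():
            raise ParameterError("linear weights must be strictly positive")
        if self.nugget < 0:
            raise ParameterError("nugget must be non-negative")

    @property
    def n_params(self) -> int:
        """Number of free hyperparameters (for the BIC penalty)."""
        if self.family == "linear":
            w = self.weights if self.weights is not None else np.array([1.0])
            return len(w) + 1  # weights + nugget
        return 1 + len(self.lengthscales) + 1  # variance + lengthscales + nugget


# -- matrix builders -------------------------------------------------------


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _sq_dists(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Pairwise sum_k (x_k - x'_k)^2 / l_k^2 (ls broadcast over dims)."""
    Z1 = X1 / ls
    Z2 = X2 / ls
    d2 = (
        np.sum(Z1**2, axis=1)[:, None]
        + np.sum(Z2**2, axis=1)[None, :]
        - 2.0 * Z1 @ Z2.T
    )
    return np.maximum(d2, 0.0)


def kernel_matrix(X1, X2, spec: KernelSpec) -> np.ndarray:
    """Noiseless cross-covariance matrix K(X1, X2)."""
    X1, X2 = _as_2d(X1), _as_2d(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ParameterError("input dimension mismatch")
    d = X1.shape[1]
    if spec.family in ("rbf", "matern32"):
        if len(spec.lengthscales) != 1:
            raise ParameterError(f"{spec.family} uses a single lengthscale")
        ls = np.full(d, spec.lengthscales[0])
    elif spec.family == "ard_rbf":
        if len(spec.lengthscales) != d:
            raise ParameterError(
                f"ard_rbf needs one lengthscale per dimension ({d}), "
                f"got {len(spec.lengthscales)}"
            )
        ls = spec.lengthscales
    if spec.family in ("rbf", "ard_rbf"):
        return spec.variance * np.exp(-_sq_dists(X1, X2, ls))
    if spec.family == "matern32":
        r = np.sqrt(_sq_dists(X1, X2, ls))
        s3r = np.sqrt(3.0) * r
        return spec.variance * (1.0 + s3r) * np.exp(-s3r)
    # linear
    w = spec.weights if spec.weights is not None else np.ones(d)
    if len(w) != d:
        raise ParameterError("linear kernel needs one weight per dimension")
    return (X1 * w) @ X2.T


def training_covariance(X, spec: KernelSpec) -> np.ndarray:
    """K(X, X) + nugget * I — one independent noise draw per observation."""
    X = _as_2d(X)
    K = kernel_matrix(X, X, spec)
    K[np.diag_indices_from(K)] += spec.nugget
    return K


# -- scalar forms (the printed single-pair definitions) --------------------


def _pair_value(xi, xj, spec: KernelSpec) -> float:
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    xj = np.atleast_1d(np.asarray(xj, dtype=float))
    k = kernel_matrix(xi[None, :], xj[None, :], spec)[0, 0]
    if spec.family != "linear" and np.array_equal(xi, xj):
        k += spec.nugget
    return float(k)


def rbf_kernel(xi, xj, spec: KernelSpec) -> float:
    """sigma2 * exp(-||xi-xj||^2 / l^2) + nugget * 1[xi == xj]."""
    if spec.family != "rbf":
        raise ParameterError("spec.family must be 'rbf'")
    return _pair_value(xi, xj, spec)


def matern32_kernel(xi, xj, spec: KernelSpec) -> float:
    """sigma2 * (1 + sqrt(3) r) exp(-sqrt(3) r), r = ||xi-xj|| / l."""
    if spec.family != "matern32":
        raise ParameterError("spec.family must be 'matern32'")
    return _pair_value(xi, xj, spec)


def linear_kernel(xi, xj, spec: KernelSpec) -> float:
    """sum_k w_k * xi_k * xj_k."""
    if spec.family != "linear":
        raise ParameterError("spec.family must be 'linear'")
    return _pair_value(xi, xj, spec)


def ard_rbf_kernel(xi, xj, spec: KernelSpec) -> float:
    """sigma2 * exp(-sum_k (xi_k - xj_k)^2 / l_k^2) + nugget * 1[xi == xj]."""
    if spec.family != "ard_rbf":
        raise ParameterError("spec.family must be 'ard_rbf'")
    return _pair_value(xi, xj, spec)


# -- gradients for marginal-likelihood optimization ------------------------


def kernel_gradients(X, spec: KernelSpec) -> list[np.ndarray]:
    """dK/d(log theta) for the training covariance, in the parameter order
    used by the optimizer: [log variance, log lengthscales..., log nugget]
    (linear family: [log weights..., log nugget])."""
    X = _as_2d(X)
    n, d = X.shape
    grads: list[np.ndarray] = []
    if spec.family == "linear":
        w = spec.weights if spec.weights is not None else np.ones(d)
        for k in range(len(w)):
            grads.append(w[k] * np.outer(X[:, k], X[:, k]))
    elif spec.family in ("rbf", "ard_rbf"):
        ls = (
            np.full(d, spec.lengthscales[0])
            if spec.family == "rbf"
            else spec.lengthscales
        )
        Kse = spec.variance * np.exp(-_sq_dists(X, X, ls))
        grads.append(Kse)  # d/dlog sigma2
        if spec.family == "rbf":
            d2 = _sq_dists(X, X, ls)
            grads.append(Kse * 2.0 * d2)  # single l: d/dlog l
        else:
            for k in range(d):
                dk2 = (X[:, k][:, None] - X[:, k][None, :]) ** 2 / ls[k] ** 2
                grads.append(Kse * 2.0 * dk2)
    else:  # matern32
        ls = np.full(d, spec.lengthscales[0])
        r = np.sqrt(_sq_dists(X, X, ls))
        s3r = np.sqrt(3.0) * r
        grads.append(spec.variance * (1.0 + s3r) * np.exp(-s3r))  # d/dlog sigma2
        grads.append(3.0 * spec.variance * r**2 * np.exp(-s3r))  # d/dlog l
    grads.append(spec.nugget * np.eye(X.shape[0]))  # d/dlog nugget
    return grads


def spec_to_logparams(spec: KernelSpec) -> np.ndarray:
    if spec.family == "linear":
        w = spec.weights if spec.weights is not None else np.array([1.0])
        return np.log(np.concatenate([w, [max(spec.nugget, 1e-10)]]))
    return np.log(
        np.concatenate(
            [[spec.variance], spec.lengthscales, [max(spec.nugget, 1e-10)]]
        )
    )


def logparams_to_spec(theta: np.ndarray, template: KernelSpec) -> KernelSpec:
    p = np.exp(theta)
    if template.family == "linear":
        return replace(template, weights=p[:-1], nugget=p[-1])
    return replace(
        template,
        variance=p[0],
        lengthscales=p[1:-1],
        nugget=p[-1],
    )
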