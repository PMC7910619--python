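"""The GTM-LDLV generative model.

Each of N items (e.g. chemical elements) with a D-dimensional feature
vector x_n is generated by one of K mixture components sitting on a latent
manifold: component k emits N(x | y_k, beta^{-1} I) with mixing rate 1/K,
and the component means are

    y_k = f(u_k) = g(u_k) * h(u_k),

the product of a positive scalar scale field g and a D-vector field h, both
functions of the latent node coordinate u_k.  The fields carry Gaussian
process priors:

* g ~ truncated GP (positive values) with the RBF-family covariance
  ``c_g(u_i, u_j) = nu_g * exp(-||u_i - u_j||^2 / (2 l_g))``;
* each coordinate h_d ~ GP with the nonstationary Gibbs covariance

      c_h(u_i, u_j) = {2 l_i l_j / (l_i^2 + l_j^2)}^{L/2}
                      * exp(-||u_i - u_j||^2 / (l_i^2 + l_j^2)),

  whose length-scale l(u) = exp(r(u)) varies over the latent space;
* r ~ GP with the same RBF family as c_g but hyperparameters (nu_r, l_r);
* beta carries a Gamma(a0, b0) prior.

The latent-dependent length-scale is what lets the fitted manifold be
smooth in some regions of the table and wiggly in others.

Note the c_g exponent divides by ``2 l_g`` (length-scale enters linearly,
not squared).  That is the form this model family defines; set
``kernel_g_denominator="l_squared"`` on :class:`Hyperparams` for the
conventional RBF parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ParameterError

__all__ = [
    "Hyperparams",
    "FeatureMatrix",
    "ModelState",
    "cov_g",
    "cov_r",
    "cov_h",
    "manifold_points",
    "log_joint",
    "JITTER",
]

#: diagonal jitter added to every kernel matrix before factorization
JITTER = 1e-6


@dataclass(frozen=True)
class Hyperparams:
    """Fixed hyperparameters of the field priors.

    ``(nu_g, l_g)`` are the variance and length-scale of the scale-field
    covariance; ``(nu_r, l_r)`` the analogous pair for the log-length-scale
    field; ``(a0, b0)`` the shape/rate of the gamma prior on the noise
    precision beta.  The defaults (1/3, 3) are the standard operating point
    for element-table runs.
    """

    nu_g: float = 1.0 / 3.0
    l_g: float = 3.0
    nu_r: float = 1.0 / 3.0
    l_r: float = 3.0
    a0: float = 1e-3
    b0: float = 1e-3
    kernel_g_denominator: str = "l"  # "l" (as defined) or "l_squared"

    def __post_init__(self):
        for name in ("nu_g", "l_g", "nu_r", "l_r", "a0", "b0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if self.kernel_g_denominator not in ("l", "l_squared"):
            raise ParameterError(
                "kernel_g_denominator must be 'l' or 'l_squared'"
            )


@dataclass
class FeatureMatrix:
    """An N x D observation matrix with item labels.

    When built through :meth:`standardized`, each column is shifted/scaled
    to mean 0 and variance 1 and the original column means and standard
    deviations are retained so new data can be projected consistently.
    """

    X: np.ndarray
    item_labels: list
    column_means: Optional[np.ndarray] = None
    column_sds: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ParameterError("X must be an N x D matrix")
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("X must not contain missing/non-finite values")
        self.item_labels = list(self.item_labels)
        if len(self.item_labels) != self.X.shape[0]:
            raise ParameterError("need one label per row of X")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]

    @classmethod
    def standardized(cls, raw: np.ndarray, item_labels: Sequence) -> "FeatureMatrix":
        raw = np.asarray(raw, dtype=float)
        means = raw.mean(axis=0)
        sds = raw.std(axis=0)
        if np.any(sds == 0):
            raise ParameterError("constant columns cannot be standardized")
        return cls((raw - means) / sds, list(item_labels), means, sds)

    @classmethod
    def from_csv(cls, path, label_column=0, standardize: bool = True) -> "FeatureMatrix":
        """Load a CSV/TSV table with one label column and D numeric columns."""
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        if isinstance(label_column, int):
            label_column = df.columns[label_column]
        labels = df[label_column].astype(str).tolist()
        values = df.drop(columns=[label_column]).to_numpy(dtype=float)
        if standardize:
            return cls.standardized(values, labels)
        return cls(values, labels)

    def to_csv(self, path, label_column: str = "item") -> None:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.D)])
        df.insert(0, label_column, self.item_labels)
        df.to_csv(path, index=False)


@dataclass
class ModelState:
    """One complete parameter set theta = {Z, beta, g, H, r}.

    Z is the K x N one-hot assignment matrix (column n marks the node that
    generated item n); beta the observation precision; g the positive scale
    field evaluated at the nodes; H the K x D matrix whose row k is h(u_k);
    r the log length-scale field at the nodes.
    """

    Z: np.ndarray
    beta: float
    g: np.ndarray
    H: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z)
        self.g = np.asarray(self.g, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.r = np.asarray(self.r, dtype=float)

    def validate(self) -> None:
        K, N = self.Z.shape
        if self.g.shape != (K,) or self.r.shape != (K,) or self.H.shape[0] != K:
            raise ParameterError("field shapes inconsistent with Z")
        if not np.all((self.Z == 0) | (self.Z == 1)):
            raise ParameterError("Z must be binary")
        if not np.all(self.Z.sum(axis=0) == 1):
            raise ParameterError("each item must be assigned to exactly one node")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ParameterError("beta must be strictly positive")
        if not np.all(self.g > 0):
            raise ParameterError("g must be strictly positive (truncated-GP support)")

    @property
    def assignments(self) -> np.ndarray:
        """Node index k(n) for each item n."""
        return np.argmax(self.Z, axis=0)

    @property
    def Y(self) -> np.ndarray:
        return manifold_points(self.g, self.H)

    def copy(self) -> "ModelState":
        return ModelState(
            self.Z.copy(), float(self.beta), self.g.copy(), self.H.copy(), self.r.copy()
        )


def _check_positive(name, values):
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ParameterError(f"{name} must be finite and strictly positive")
    return values


def _sq_dists(U1, U2=None):
    U1 = np.atleast_2d(np.asarray(U1, dtype=float))
    U2 = U1 if U2 is None else np.atleast_2d(np.asarray(U2, dtype=float))
    return cdist(U1, U2, metric="sqeuclidean")


def cov_g(U, hyper: Hyperparams, U2=None) -> np.ndarray:
    """Scale-field covariance: nu_g * exp(-||u_i - u_j||^2 / (2 l_g)).

    With ``kernel_g_denominator="l_squared"`` the exponent divides by
    ``2 l_g^2`` instead.
    """
    _check_positive("nu_g", [hyper.nu_g])
    _check_positive("l_g", [hyper.l_g])
    denom = 2.0 * hyper.l_g
    if hyper.kernel_g_denominator == "l_squared":
        denom = 2.0 * hyper.l_g**2
    return hyper.nu_g * np.exp(-_sq_dists(U, U2) / denom)


def cov_r(U, hyper: Hyperparams, U2=None) -> np.ndarray:
    """Log-length-scale-field covariance: the c_g family with (nu_r, l_r)."""
    proxy = replace(hyper, nu_g=hyper.nu_r, l_g=hyper.l_r)
    return cov_g(U, proxy, U2)


def cov_h(U, l_values, U2=None, l_values2=None) -> np.ndarray:
    """Gibbs nonstationary covariance with per-node length-scales.

    Entry (i, j) is ``{2 l_i l_j / (l_i^2 + l_j^2)}^{L/2} *
    exp(-||u_i - u_j||^2 / (l_i^2 + l_j^2))``; the diagonal is exactly 1,
    and for a constant length-scale l the matrix reduces to the stationary
    RBF kernel exp(-d^2 / (2 l^2)).  Cross-covariances between two node
    sets are obtained by passing ``U2``/``l_values2``.
    """
    li = _check_positive("l_values", l_values)
    lj = li if l_values2 is None else _check_positive("l_values2", l_values2)
    U = np.atleast_2d(np.asarray(U, dtype=float))
    L = U.shape[1]
    d2 = _sq_dists(U, U2)
    denom = li[:, None] ** 2 + lj[None, :] ** 2
    prefactor = (2.0 * li[:, None] * lj[None, :] / denom) ** (L / 2.0)
    return prefactor * np.exp(-d2 / denom)


def manifold_points(g, H) -> np.ndarray:
    """Component means y_k = g(u_k) * h(u_k), one row per node."""
    g = np.asarray(g, dtype=float)
    H = np.asarray(H, dtype=float)
    if g.shape[0] != H.shape[0]:
        raise ParameterError("g and H disagree on the number of nodes")
    return g[:, None] * H


def log_joint(X, state: ModelState) -> float:
    """Log of the complete-data likelihood p(X, Z | g, H, beta).

    Equals -N log K plus the sum over items of the log Gaussian density of
    x_n at its assigned manifold point with isotropic variance 1/beta.
    """
    state.validate()
    X = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    K, N = state.Z.shape
    D = X.shape[1]
    Y = state.Y
    resid = X - Y[state.assignments]
    sse = float(np.sum(resid**2))
    value = (
        -N * np.log(K)
        + 0.5 * N * D * (np.log(state.beta) - np.log(2.0 * np.pi))
        - 0.5 * state.beta * sse
    )
    if not np.isfinite(value):
        raise ParameterError("log_joint is not finite")
    return value
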