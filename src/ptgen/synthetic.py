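"""Synthetic data drawn from the generative model itself.

Every stage of the pipeline can be exercised without external data by
sampling from the model's own prior: draw the log length-scale field r
from its GP, the positive scale field g from the truncated GP (by
rejection, deliberately a different mechanism than the inference-side
slice sampler so the two cross-validate), each manifold coordinate h_d
from the Gibbs-kernel GP, assign items to nodes uniformly (or injectively
for one-to-one recovery experiments), and add isotropic Gaussian noise
with precision beta.

Also ships an openly synthetic stand-in for the 54-element x 39-feature
table: smooth trends along atomic number plus group/period-driven periodic
components, standardized column-wise.  It emulates the dimensions and
smooth-plus-periodic character of real element data, not its actual
values.
"""

from __future__ import annotations

import numpy as np

from ._elements import GROUP, PERIOD, SYMBOLS_H_TO_XE
from .errors import ParameterError, SamplingError
from .layouts import NodeLayout
from .mcmc import chol_with_jitter
from .model import JITTER, FeatureMatrix, Hyperparams, ModelState, cov_g, cov_h, cov_r

__all__ = ["generate", "sample_truncated_gp", "element_fixture"]


def sample_truncated_gp(
    chol: np.ndarray, rng: np.random.Generator, max_tries: int = 100_000
) -> np.ndarray:
    """Rejection-sample a zero-mean GP draw restricted to all-positive values."""
    K = chol.shape[0]
    for _ in range(max_tries):
        draw = chol @ rng.standard_normal(K)
        if np.all(draw > 0):
            return draw
    raise SamplingError(
        "truncated-GP rejection budget exhausted; try a smaller nu_g "
        "or fewer/closer nodes"
    )


def generate(
    layout: NodeLayout,
    hyper: Hyperparams,
    N: int,
    D: int,
    beta: float,
    seed: int | np.random.Generator = 0,
    injective: bool = False,
):
    """Draw (FeatureMatrix, ground-truth ModelState) from the model.

    With ``injective=True`` the N items occupy N distinct nodes (requires
    N <= K), which is the setting for one-to-one recovery experiments.
    """
    if beta <= 0:
        raise ParameterError("beta must be positive")
    if injective and N > layout.K:
        raise ParameterError("injective generation needs N <= K")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = layout.K
    U = layout.coords

    r = chol_with_jitter(cov_r(U, hyper)) @ rng.standard_normal(K)
    g = sample_truncated_gp(chol_with_jitter(cov_g(U, hyper)), rng)
    chol_h = chol_with_jitter(cov_h(U, np.exp(r)))
    H = chol_h @ rng.standard_normal((K, D))

    if injective:
        assign = rng.choice(K, size=N, replace=False)
    else:
        assign = rng.integers(0, K, size=N)
    Z = np.zeros((K, N), dtype=np.int8)
    Z[assign, np.arange(N)] = 1

    Y = g[:, None] * H
    X = Y[assign] + rng.standard_normal((N, D)) / np.sqrt(beta)
    truth = ModelState(Z=Z, beta=float(beta), g=g, H=H, r=r)
    truth.validate()
    features = FeatureMatrix(X, [f"item_{i}" for i in range(N)])
    return features, truth


def element_fixture(seed: int = 0) -> FeatureMatrix:
    """A synthetic 54 x 39 element-feature table labelled H..Xe.

    Each feature mixes a smooth trend in atomic number with periodic
    components driven by group and period membership, plus mild noise, so
    the matrix has the smooth-and-periodic structure a topographic
    embedding can latch onto.  Columns are standardized to mean 0,
    variance 1.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n_elements, n_features = 54, 39
    z = np.arange(1, n_elements + 1, dtype=float)
    group = np.array([GROUP[s] for s in SYMBOLS_H_TO_XE], dtype=float)
    period = np.array([PERIOD[s] for s in SYMBOLS_H_TO_XE], dtype=float)

    raw = np.empty((n_elements, n_features))
    for j in range(n_features):
        c = rng.standard_normal(4)
        phase = rng.uniform(0, 2 * np.pi)
        raw[:, j] = (
            c[0] * z / n_elements
            + c[1] * np.sin(2 * np.pi * group / 18.0 + phase)
            + c[2] * group / 18.0
            + c[3] * period / 5.0
            + 0.1 * rng.standard_normal(n_elements)
        )
    return FeatureMatrix.standardized(raw, SYMBOLS_H_TO_XE)
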