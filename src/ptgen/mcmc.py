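"""Gibbs sampling for the GTM-LDLV posterior.

The posterior p(theta | X) over theta = {Z, beta, g, H, r} is approximated
by iteratively sampling each block from its full conditional:

* ``Z``  — exact categorical draw per item, with probabilities
  proportional to exp(-beta/2 ||x_n - y_k||^2);
* ``beta`` — conjugate gamma draw, Gamma(a0 + ND/2, b0 + SSE/2);
* ``H``  — conjugate Gaussian draw per feature dimension (GP prior +
  Gaussian likelihood through y_k = g_k h_k);
* ``g``  — elliptical slice sampling under the N(0, C_g) prior, with the
  positivity of the truncated-GP support enforced as a zero-likelihood
  barrier;
* ``r``  — elliptical slice sampling under the N(0, C_r) prior, the
  "likelihood" being the GP prior density of H evaluated at the Gibbs
  kernel C_h(exp(r)) (r is non-conjugate: it enters only through H's
  prior).

The sweep order is fixed to (Z, beta, H, g, r).  Post-burn-in states form
a :class:`PosteriorEnsemble`; :func:`estimate` turns an ensemble into a
single point estimate by ensemble averaging (argmax of mean
responsibilities for Z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .errors import NumericalError, ParameterError, SamplingError
from .layouts import NodeLayout
from .model import (
    JITTER,
    FeatureMatrix,
    Hyperparams,
    ModelState,
    cov_g,
    cov_h,
    cov_r,
    log_joint,
)

__all__ = [
    "PosteriorEnsemble",
    "sample_Z",
    "sample_beta",
    "sample_H",
    "sample_g",
    "sample_r",
    "run_gibbs",
    "estimate",
    "responsibilities",
    "initial_state",
]

_MAX_SLICE_SHRINK = 200


def _as_X(X) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def chol_with_jitter(M: np.ndarray, jitter: float = JITTER, max_tries: int = 6):
    """Lower Cholesky factor of M + jitter*I, escalating jitter on failure."""
    for _ in range(max_tries):
        try:
            return cholesky(M + jitter * np.eye(M.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError("Cholesky failed after jitter escalation")


def responsibilities(X, state: ModelState) -> np.ndarray:
    """Posterior membership probabilities, one row per item (N x K)."""
    X = _as_X(X)
    d2 = cdist(X, state.Y, metric="sqeuclidean")
    logits = -0.5 * state.beta * d2
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def sample_Z(X, state: ModelState, rng: np.random.Generator) -> np.ndarray:
    """Draw the assignment matrix column-wise from its full conditional.

    Item n goes to node k with probability proportional to
    exp(-beta/2 ||x_n - y_k||^2); the draw is made in log space (Gumbel
    trick) so widely separated nodes cannot underflow to an all-zero row.
    """
    X = _as_X(X)
    d2 = cdist(X, state.Y, metric="sqeuclidean")
    logits = -0.5 * state.beta * d2
    if np.any(np.all(~np.isfinite(logits), axis=1)):
        raise SamplingError("assignment distribution underflowed for some item")
    gumbel = -np.log(-np.log(rng.uniform(size=logits.shape)))
    choice = np.argmax(logits + gumbel, axis=1)
    K, N = state.Z.shape
    Z = np.zeros((K, N), dtype=np.int8)
    Z[choice, np.arange(N)] = 1
    return Z


def sample_beta(X, state: ModelState, prior, rng: np.random.Generator) -> float:
    """Conjugate gamma draw: Gamma(a0 + ND/2, b0 + SSE/2) (shape, rate)."""
    a0, b0 = prior
    X = _as_X(X)
    N, D = X.shape
    resid = X - state.Y[state.assignments]
    sse = float(np.sum(resid**2))
    if not np.isfinite(sse):
        raise SamplingError("non-finite residual sum of squares")
    shape = a0 + 0.5 * N * D
    rate = b0 + 0.5 * sse
    return float(rng.gamma(shape, 1.0 / rate))


def sample_H(
    X,
    state: ModelState,
    layout: NodeLayout,
    hyper: Hyperparams,
    rng: np.random.Generator,
    chol_h: np.ndarray | None = None,
) -> np.ndarray:
    """Conjugate Gaussian draw of the manifold field H, per feature dimension.

    For each d the conditional is N(A^{-1} b_d, A^{-1}) with
    A = C_h^{-1} + beta * diag(g_k^2 m_k) and b_d = beta * g_k * (Z x_d)_k,
    where m_k counts the items currently assigned to node k.  All D
    dimensions share the same precision A, so one factorization serves the
    whole draw.
    """
    X = _as_X(X)
    K = layout.K
    if chol_h is None:
        chol_h = chol_with_jitter(cov_h(layout.coords, np.exp(state.r)))
    eye = np.eye(K)
    C_inv = cho_solve((chol_h, True), eye)
    counts = state.Z.sum(axis=1).astype(float)
    A = C_inv + state.beta * np.diag(state.g**2 * counts)
    B = state.beta * state.g[:, None] * (state.Z @ X)
    L = chol_with_jitter(A, jitter=0.0, max_tries=6)
    mean = cho_solve((L, True), B)
    noise = solve_triangular(L.T, rng.standard_normal((K, X.shape[1])), lower=False)
    return mean + noise


def _ess_step(f, prior_chol, loglik, rng):
    """One elliptical slice sampling transition for a zero-mean GP prior."""
    current = loglik(f)
    if not np.isfinite(current):
        raise SamplingError("elliptical slice started from a zero-density state")
    nu = prior_chol @ rng.standard_normal(f.shape)
    log_y = current + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    for _ in range(_MAX_SLICE_SHRINK):
        proposal = f * np.cos(theta) + nu * np.sin(theta)
        if loglik(proposal) > log_y:
            return proposal
        if theta < 0.0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    raise SamplingError("elliptical slice bracket shrank to nothing")


def sample_g(
    X,
    state: ModelState,
    layout: NodeLayout,
    hyper: Hyperparams,
    rng: np.random.Generator,
    chol_g: np.ndarray | None = None,
) -> np.ndarray:
    """Slice-sample the positive scale field g from its full conditional.

    The prior is the GP N(0, C_g) truncated to the positive orthant; the
    truncation is imposed as a zero-likelihood barrier inside an elliptical
    slice step, which keeps the update rejection-free on the valid region.
    """
    X = _as_X(X)
    if chol_g is None:
        chol_g = chol_with_jitter(cov_g(layout.coords, hyper))
    counts = state.Z.sum(axis=1).astype(float)
    s = state.Z @ X  # per-node sums of assigned items
    a = counts * np.sum(state.H**2, axis=1)  # quadratic coefficient
    b = np.sum(state.H * s, axis=1)  # linear coefficient
    beta = state.beta

    def loglik(g):
        if np.any(g <= 0):
            return -np.inf
        return -0.5 * beta * float(np.sum(a * g**2 - 2.0 * b * g))

    return _ess_step(state.g, chol_g, loglik, rng)


def sample_r(
    X,
    state: ModelState,
    layout: NodeLayout,
    hyper: Hyperparams,
    rng: np.random.Generator,
    chol_r: np.ndarray | None = None,
) -> np.ndarray:
    """Slice-sample the log length-scale field r.

    r has no conjugate update: it enters the model only through the Gibbs
    kernel C_h(exp(r)) acting as the prior covariance of H.  The elliptical
    slice likelihood is therefore the GP density of the current H under
    that kernel; proposals whose kernel fails to factorize are treated as
    zero-density and shrunk away.
    """
    if chol_r is None:
        chol_r = chol_with_jitter(cov_r(layout.coords, hyper))
    U = layout.coords
    H = state.H
    D = H.shape[1]

    def loglik(r):
        C = cov_h(U, np.exp(r)) + JITTER * np.eye(U.shape[0])
        try:
            L = cholesky(C, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        half = solve_triangular(L, H, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return -0.5 * (D * logdet + float(np.sum(half**2)))

    return _ess_step(state.r, chol_r, loglik, rng)


def initial_state(
    X, layout: NodeLayout, rng: np.random.Generator | None = None
) -> ModelState:
    """Deterministic starting point: r=0, g=1, beta=1, H from the top-L
    principal axes of X evaluated at the node coordinates (classic GTM
    initialization), Z by nearest manifold point."""
    X = _as_X(X)
    N, D = X.shape
    K, L = layout.K, layout.L
    Xc = X - X.mean(axis=0)
    # project node coordinates through the dominant principal directions
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_axes = min(L, Vt.shape[0])
    scales = svals[:n_axes] / np.sqrt(max(N - 1, 1))
    W = (scales[:, None] * Vt[:n_axes])  # L x D
    H = layout.coords[:, :n_axes] @ W
    g = np.ones(K)
    d2 = cdist(X, H, metric="sqeuclidean")
    choice = np.argmin(d2, axis=1)
    Z = np.zeros((K, N), dtype=np.int8)
    Z[choice, np.arange(N)] = 1
    return ModelState(Z=Z, beta=1.0, g=g, H=H, r=np.zeros(K))


@dataclass
class PosteriorEnsemble:
    """Post-burn-in MCMC snapshots with their complete-data log densities."""

    states: list
    log_likelihoods: list
    config: dict
    trace: list | None = None  # log_joint at every sweep, for diagnostics

    def __post_init__(self):
        if len(self.states) != len(self.log_likelihoods):
            raise ParameterError("states and log_likelihoods must align")

    def __len__(self):
        return len(self.states)

    def trace_frame(self) -> pd.DataFrame:
        trace = self.trace if self.trace is not None else self.log_likelihoods
        return pd.DataFrame({"sweep": np.arange(len(trace)), "log_joint": trace})

    def save(self, path) -> None:
        """Persist as an npz archive (stacked parameter arrays + config)."""
        import json

        np.savez_compressed(
            path,
            Z=np.stack([s.Z for s in self.states]),
            beta=np.array([s.beta for s in self.states]),
            g=np.stack([s.g for s in self.states]),
            H=np.stack([s.H for s in self.states]),
            r=np.stack([s.r for s in self.states]),
            log_likelihoods=np.asarray(self.log_likelihoods),
            trace=np.asarray(self.trace if self.trace is not None else []),
            config=json.dumps(self.config),
        )

    @classmethod
    def load(cls, path) -> "PosteriorEnsemble":
        import json

        with np.load(path, allow_pickle=False) as data:
            states = [
                ModelState(
                    Z=data["Z"][i],
                    beta=float(data["beta"][i]),
                    g=data["g"][i],
                    H=data["H"][i],
                    r=data["r"][i],
                )
                for i in range(data["beta"].shape[0])
            ]
            trace = data["trace"].tolist() or None
            return cls(
                states,
                data["log_likelihoods"].tolist(),
                json.loads(str(data["config"])),
                trace,
            )


def gibbs_sweep(X, state, layout, hyper, rng, chol_g=None, chol_r=None) -> ModelState:
    """One full sweep in the fixed update order (Z, beta, H, g, r)."""
    state = state.copy()
    state.Z = sample_Z(X, state, rng)
    state.beta = sample_beta(X, state, (hyper.a0, hyper.b0), rng)
    state.H = sample_H(X, state, layout, hyper, rng)
    state.g = sample_g(X, state, layout, hyper, rng, chol_g)
    state.r = sample_r(X, state, layout, hyper, rng, chol_r)
    return state


def run_gibbs(
    X,
    layout: NodeLayout,
    hyper: Hyperparams,
    n_sweeps: int,
    burn_in: int,
    seed: int | np.random.Generator = 0,
    thin: int = 1,
    init: ModelState | None = None,
) -> PosteriorEnsemble:
    """Run the Gibbs sampler for ``n_sweeps`` sweeps, keeping post-burn-in
    states (every ``thin``-th).  Reproducible: the same seed and config
    give a bitwise-identical ensemble."""
    if not (n_sweeps > burn_in >= 0):
        raise ParameterError("need n_sweeps > burn_in >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xarr = _as_X(X)
    state = init.copy() if init is not None else initial_state(Xarr, layout)
    chol_g = chol_with_jitter(cov_g(layout.coords, hyper))
    chol_r = chol_with_jitter(cov_r(layout.coords, hyper))
    states, lls, trace = [], [], []
    for sweep in range(n_sweeps):
        try:
            state = gibbs_sweep(Xarr, state, layout, hyper, rng, chol_g, chol_r)
        except (SamplingError, NumericalError) as exc:
            raise SamplingError(f"sweep {sweep} failed: {exc}") from exc
        ll = log_joint(Xarr, state)
        trace.append(ll)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            states.append(state.copy())
            lls.append(ll)
    config = {
        "n_sweeps": n_sweeps,
        "burn_in": burn_in,
        "thin": thin,
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "hyper": vars(hyper).copy() if hasattr(hyper, "__dict__") else None,
        "layout_kind": layout.kind,
        "layout_structure": list(layout.structure),
    }
    config["hyper"] = {
        "nu_g": hyper.nu_g,
        "l_g": hyper.l_g,
        "nu_r": hyper.nu_r,
        "l_r": hyper.l_r,
        "a0": hyper.a0,
        "b0": hyper.b0,
        "kernel_g_denominator": hyper.kernel_g_denominator,
    }
    return PosteriorEnsemble(states, lls, config, trace)


def estimate(ensemble: PosteriorEnsemble, X=None) -> ModelState:
    """Ensemble-average point estimate.

    beta, g, H and r are posterior means over the stored states.  Z is the
    one-hot argmax of the mean responsibility of each item (ties broken by
    the lowest node index); when X is omitted the mean of the sampled
    one-hot columns stands in for the responsibilities.
    """
    if len(ensemble) == 0:
        raise ParameterError("empty ensemble")
    states = ensemble.states
    beta = float(np.mean([s.beta for s in states]))
    g = np.mean([s.g for s in states], axis=0)
    H = np.mean([s.H for s in states], axis=0)
    r = np.mean([s.r for s in states], axis=0)
    if X is not None:
        resp = np.mean([responsibilities(X, s) for s in states], axis=0)
    else:
        resp = np.mean([s.Z.T for s in states], axis=0)
    choice = np.argmax(resp, axis=1)
    K, N = states[0].Z.shape
    Z = np.zeros((K, N), dtype=np.int8)
    Z[choice, np.arange(N)] = 1
    return ModelState(Z=Z, beta=beta, g=g, H=H, r=r)
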