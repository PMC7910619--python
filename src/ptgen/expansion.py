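"""Coarse-to-fine model transfer by GP interpolation.

After the coarse fit, the node set is refined (``layouts.expand_layout``)
and the latent fields are carried to the new nodes by noiseless GP
conditioning under their respective priors: r under c_r, g under c_g (with
a positivity floor), and each column of H under the Gibbs kernel c_h
evaluated with the freshly interpolated length-scale field l = exp(r).
Values at retained old nodes are reproduced exactly; beta is carried over
unchanged and Z is re-indexed onto the new node numbering (it is
re-sampled or re-solved at the next sweep anyway).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .errors import LayoutError
from .layouts import NodeLayout
from .model import JITTER, Hyperparams, ModelState, cov_g, cov_h, cov_r

__all__ = ["interpolate_state", "match_nodes"]

#: interpolated scale-field values are clipped up to this floor
G_FLOOR = 1e-8


def match_nodes(old_layout: NodeLayout, new_layout: NodeLayout, tol: float = 1e-9):
    """Index of each old node inside the new layout (containment required)."""
    d = cdist(old_layout.coords, new_layout.coords)
    idx = np.argmin(d, axis=1)
    if np.any(d[np.arange(old_layout.K), idx] > tol):
        raise LayoutError("new layout does not contain every old node")
    if len(set(idx.tolist())) != old_layout.K:
        raise LayoutError("old nodes map onto duplicate new nodes")
    return idx


def _gp_mean(K_new_old, K_old_old, values):
    """Conditional mean of a zero-mean GP at new inputs given noiseless
    observations at the old inputs."""
    Koo = K_old_old + JITTER * np.eye(K_old_old.shape[0])
    factor = cho_factor(Koo, lower=True)
    return K_new_old @ cho_solve(factor, values)


def interpolate_state(
    state: ModelState,
    old_layout: NodeLayout,
    new_layout: NodeLayout,
    hyper: Hyperparams,
) -> ModelState:
    """Transfer a fitted state from the coarse node set to the refined one.

    Each field's value at the new nodes is the GP conditional mean given
    its values at the old nodes; on retained old nodes the old values are
    kept exactly.  Interpolated g is floored at a small positive value to
    preserve the truncated-GP support.
    """
    state.validate()
    old_idx = match_nodes(old_layout, new_layout)
    U_old, U_new = old_layout.coords, new_layout.coords

    r_new = _gp_mean(
        cov_r(U_new, hyper, U_old), cov_r(U_old, hyper), state.r
    )
    r_new[old_idx] = state.r

    g_new = _gp_mean(
        cov_g(U_new, hyper, U_old), cov_g(U_old, hyper), state.g
    )
    g_new[old_idx] = state.g
    g_new = np.maximum(g_new, G_FLOOR)

    l_old = np.exp(state.r)
    l_new = np.exp(r_new)
    H_new = _gp_mean(
        cov_h(U_new, l_new, U_old, l_old), cov_h(U_old, l_old), state.H
    )
    H_new[old_idx] = state.H

    Z_new = np.zeros((new_layout.K, state.Z.shape[1]), dtype=np.int8)
    Z_new[old_idx] = state.Z
    return ModelState(Z=Z_new, beta=state.beta, g=g_new, H=H_new, r=r_new)
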