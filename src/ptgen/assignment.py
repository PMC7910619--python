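"""One-to-one item-to-node assignment and final fine-tuning.

In the last stage the categorical draw of Z is replaced by exact
maximization of its log conditional subject to one-item-per-node
constraints:

    max_Z  -sum_{n,k} z_kn ||x_n - y_k||^2
    s.t.   sum_k z_kn = 1 (each item placed), sum_n z_kn <= 1 (no sharing).

This is a transportation problem with unit supplies/demands; the
constraint matrix is totally unimodular, so the LP optimum is integral and
the problem is solved here as a rectangular linear assignment
(scipy's ``linear_sum_assignment``).  A few modified Gibbs sweeps
(Z maximized, the other blocks still sampled) fine-tune the parameters,
and the sweep with the highest complete-data log density supplies the
final table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import AssignmentInfeasibleError, ParameterError
from .layouts import NodeLayout
from .mcmc import chol_with_jitter, sample_H, sample_beta, sample_g, sample_r
from .model import FeatureMatrix, Hyperparams, ModelState, cov_g, cov_r, log_joint

__all__ = ["ElementTable", "solve_assignment", "fine_tune"]


@dataclass
class ElementTable:
    """The artifact's tabular output: an injective item -> node map.

    ``coords[i]`` is the latent coordinate of the node holding item
    ``labels[i]``; provenance records how the table was produced.
    """

    labels: list
    node_ids: np.ndarray
    coords: np.ndarray
    layout: NodeLayout | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.node_ids = np.asarray(self.node_ids)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if len(self.labels) != len(self.node_ids) or len(self.labels) != len(self.coords):
            raise ParameterError("labels, node_ids and coords must align")
        if len(set(self.node_ids.tolist())) != len(self.node_ids):
            raise ParameterError("table is not injective: two items share a node")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("duplicate item labels")

    @property
    def L(self) -> int:
        return self.coords.shape[1]

    def coordinates_of(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    def coordinate_map(self) -> dict:
        return {lab: self.coords[i] for i, lab in enumerate(self.labels)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"u{i + 1}" for i in range(self.L)]
        )
        df.insert(0, "node_id", self.node_ids)
        df.insert(0, "item", self.labels)
        return df

    def to_csv(self, path) -> None:
        # %.17g keeps float64 coordinates bit-exact across a round-trip
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ElementTable":
        df = pd.read_csv(path, float_precision="round_trip")
        coord_cols = [c for c in df.columns if c.startswith("u")]
        return cls(
            labels=df["item"].astype(str).tolist(),
            node_ids=df["node_id"].to_numpy(),
            coords=df[coord_cols].to_numpy(dtype=float),
        )

    def to_json(self, path) -> None:
        payload = {
            "items": [
                {
                    "item": lab,
                    "node_id": int(self.node_ids[i]),
                    "coords": [float(v) for v in self.coords[i]],
                }
                for i, lab in enumerate(self.labels)
            ],
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def solve_assignment(X, Y: np.ndarray, beta: float | None = None) -> np.ndarray:
    """Exact one-to-one assignment minimizing total squared distance.

    Returns the K x N binary matrix maximizing
    ``-sum z_kn ||x_n - y_k||^2`` over the transportation polytope with
    unit demands and at-most-unit supplies.  ``beta`` only rescales the
    objective and never changes the argmax, so it is ignored.
    """
    X = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N, K = X.shape[0], Y.shape[0]
    if K < N:
        raise AssignmentInfeasibleError(
            f"one-to-one assignment needs K >= N (got K={K}, N={N})"
        )
    cost = cdist(X, Y, metric="sqeuclidean")
    rows, cols = linear_sum_assignment(cost)
    Z = np.zeros((K, N), dtype=np.int8)
    Z[cols, rows] = 1
    return Z


def fine_tune(
    X,
    state: ModelState,
    layout: NodeLayout,
    hyper: Hyperparams,
    n_iter: int = 10,
    seed: int | np.random.Generator = 0,
):
    """Modified Gibbs sweeps with Z maximized instead of sampled.

    Each of the ``n_iter`` iterations solves the one-to-one assignment for
    the current manifold, then resamples beta, H, g and r from their full
    conditionals.  The iterate with the highest complete-data log density
    is returned as ``(ElementTable, ModelState)``.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = (
        X.item_labels
        if isinstance(X, FeatureMatrix)
        else [f"item_{i}" for i in range(np.asarray(X).shape[0])]
    )
    Xarr = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    chol_g = chol_with_jitter(cov_g(layout.coords, hyper))
    chol_r = chol_with_jitter(cov_r(layout.coords, hyper))
    state = state.copy()
    best_ll, best_state = -np.inf, None
    for _ in range(n_iter):
        state.Z = solve_assignment(Xarr, state.Y)
        state.beta = sample_beta(Xarr, state, (hyper.a0, hyper.b0), rng)
        state.H = sample_H(Xarr, state, layout, hyper, rng)
        state.g = sample_g(Xarr, state, layout, hyper, rng, chol_g)
        state.r = sample_r(Xarr, state, layout, hyper, rng, chol_r)
        ll = log_joint(Xarr, state)
        if ll > best_ll:
            best_ll, best_state = ll, state.copy()
    node_ids = best_state.assignments
    table = ElementTable(
        labels=labels,
        node_ids=node_ids,
        coords=layout.coords[node_ids],
        layout=layout,
        provenance={"log_joint": best_ll, "n_iter": n_iter},
    )
    return table, best_state
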