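"""Property landscapes: smoothed per-feature heatmaps over the layout.

A landscape shows how one observed feature varies across the latent table:
the feature values sitting at the assigned nodes are smoothed over the
latent domain with a Nadaraya-Watson estimator using a Gaussian kernel,

    L(v) = sum_n w_n(v) feature_n,   w_n(v) ∝ exp(-||v - u_{k(n)}||^2 / (2 h^2)),

so every landscape value is a convex combination of the feature values.
Two-dimensional tables are evaluated on a regular grid over [-1,1]^2;
cone and cylinder tables on the unrolled (angle, height) chart of their
surface, with distances taken in the embedded 3-D space so the angular
seam behaves correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import ElementTable
from .errors import ParameterError

__all__ = ["Landscape", "property_landscape", "default_bandwidth"]


@dataclass
class Landscape:
    """A dense smoothed surface plus the chart it was evaluated on."""

    values: np.ndarray  # (resolution, resolution)
    axis1: np.ndarray
    axis2: np.ndarray
    chart: str  # "planar" or "surface_unrolled"
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {"v1": a1.ravel(), "v2": a2.ravel(), "value": self.values.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, title=None, cmap="viridis"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(self.axis1, self.axis2, self.values.T, cmap=cmap)
        ax.figure.colorbar(mesh, ax=ax)
        if title:
            ax.set_title(title)
        return ax


def default_bandwidth(coords: np.ndarray) -> float:
    """Half the nearest-neighbour spacing among the occupied nodes."""
    from scipy.spatial.distance import pdist

    if coords.shape[0] < 2:
        return 0.5
    return 0.5 * float(pdist(coords).min())


def _cone_embed(theta, z):
    radius = (1.0 - z) / 2.0
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


def _cylinder_embed(theta, z):
    return np.column_stack([np.cos(theta), np.sin(theta), z])


def property_landscape(
    table: ElementTable,
    feature,
    resolution: int = 60,
    bandwidth: float | None = None,
) -> Landscape:
    """Smooth one feature over the latent layout of a finished table.

    ``feature`` holds one value per table item, in table order.  The
    result is a ``resolution x resolution`` surface; its values always lie
    within [min(feature), max(feature)].
    """
    feature = np.asarray(feature, dtype=float)
    if len(table.labels) == 0:
        raise ParameterError("empty table")
    if feature.shape != (len(table.labels),):
        raise ParameterError("need exactly one feature value per table item")
    if not np.all(np.isfinite(feature)):
        raise ParameterError("feature values must be finite")

    coords = table.coords
    kind = table.layout.kind if table.layout is not None else None
    if bandwidth is None:
        bandwidth = default_bandwidth(coords)

    if kind in ("cone", "cylinder"):
        axis1 = np.linspace(-np.pi, np.pi, resolution)
        axis2 = np.linspace(-1.0, 1.0, resolution)
        t, z = np.meshgrid(axis1, axis2, indexing="ij")
        embed = _cone_embed if kind == "cone" else _cylinder_embed
        grid_points = embed(t.ravel(), z.ravel())
        chart = "surface_unrolled"
    else:
        axis1 = np.linspace(-1.0, 1.0, resolution)
        axis2 = np.linspace(-1.0, 1.0, resolution)
        a, b = np.meshgrid(axis1, axis2, indexing="ij")
        grid_points = np.column_stack([a.ravel(), b.ravel()])
        if coords.shape[1] != 2:
            raise ParameterError(
                "planar landscapes need 2-D coordinates; "
                "3-D tables require a cone or cylinder layout reference"
            )
        chart = "planar"

    from scipy.spatial.distance import cdist

    d2 = cdist(grid_points, coords, metric="sqeuclidean")
    logw = -0.5 * d2 / bandwidth**2
    logw -= logw.max(axis=1, keepdims=True)  # delta limit stays stable
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    values = (w @ feature).reshape(resolution, resolution)
    return Landscape(values, axis1, axis2, chart, bandwidth)
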