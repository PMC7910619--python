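"""Node layouts in the latent space.

A layout is a fixed set of K points (nodes) u_1..u_K in an L-dimensional
latent space (L <= 3), confined to the cube [-1, 1]^L.  Items are eventually
assigned one-to-one to nodes, so layouts come with a coarse-to-fine
refinement rule (:func:`expand_layout`) that inserts new nodes between the
existing ones while keeping every original node in place.

All constructors are deterministic functions of their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError

__all__ = [
    "NodeLayout",
    "make_grid",
    "make_cone",
    "make_cylinder",
    "expand_layout",
    "layout_from_spec",
]

_COORD_TOL = 1e-12


@dataclass(frozen=True)
class NodeLayout:
    """A fixed arrangement of K nodes in the L-dimensional latent space.

    Attributes
    ----------
    coords : (K, L) ndarray
        Node coordinates, each inside [-1, 1]^L.
    kind : str
        One of ``square_grid``, ``rect_grid``, ``cuboid``, ``cone``,
        ``cylinder``.
    structure : tuple
        Kind-specific size descriptor (grid side lengths, cone slice
        counts, or (n_rings, nodes_per_ring)).
    """

    coords: np.ndarray
    kind: str
    structure: tuple = field(default=())

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise LayoutError("coords must be a K x L matrix")
        if coords.shape[1] not in (1, 2, 3):
            raise LayoutError("latent dimension must be 1, 2 or 3")
        if not np.all(np.isfinite(coords)):
            raise LayoutError("coords must be finite")
        if np.any(np.abs(coords) > 1.0 + 1e-9):
            raise LayoutError("all coordinates must lie in [-1, 1]")
        # pairwise-distinct rows
        order = np.lexsort(coords.T)
        diffs = np.diff(coords[order], axis=0)
        if coords.shape[0] > 1 and np.any(np.all(np.abs(diffs) < _COORD_TOL, axis=1)):
            raise LayoutError("layout contains duplicate nodes")
        object.__setattr__(self, "coords", coords)

    @property
    def K(self) -> int:
        return self.coords.shape[0]

    @property
    def L(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"u{i + 1}" for i in range(self.L)]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "node_id", np.arange(self.K))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_grid(sides: Sequence[int], bounds=None) -> NodeLayout:
    """Axis-aligned lattice with ``sides[i]`` evenly spaced levels per axis.

    Endpoints of each per-axis interval (default [-1, 1]) are included, so a
    5x5 grid has spacing 0.5 and a 2x2 grid is just the four corners.
    Covers the square (5x5), rectangular (5x18) and cuboid (three sides)
    table templates.
    """
    sides = [int(s) for s in sides]
    if not 1 <= len(sides) <= 3:
        raise LayoutError("grids support 1 to 3 axes")
    if any(s < 2 for s in sides):
        raise LayoutError("each grid side must be >= 2")
    if bounds is None:
        bounds = [(-1.0, 1.0)] * len(sides)
    if len(bounds) != len(sides):
        raise LayoutError("one (lo, hi) bound pair per axis required")
    axes = [np.linspace(lo, hi, s) for (lo, hi), s in zip(bounds, sides)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([m.ravel() for m in mesh])
    if len(sides) == 3:
        kind = "cuboid"
    elif len(sides) == 2 and sides[0] == sides[1]:
        kind = "square_grid"
    else:
        kind = "rect_grid"
    return NodeLayout(coords, kind, tuple(sides))


def _cone_coords(slice_counts: Sequence[int]) -> np.ndarray:
    """Nodes on a cone surface: apex (0,0,1), base circle radius 1 at z=-1.

    Slice i of S sits at height z_i evenly spaced from +1 down to -1; its
    ring radius grows linearly with (1 - z)/2, so it is 0 at the apex and 1
    at the base.  Ring angles start at 0 rad with equal spacing (rings are
    angle-aligned across slices).
    """
    counts = [int(c) for c in slice_counts]
    S = len(counts)
    if S == 1:
        return np.array([[0.0, 0.0, 1.0]])
    heights = np.linspace(1.0, -1.0, S)
    rows = []
    for z, c in zip(heights, counts):
        radius = (1.0 - z) / 2.0
        ang = 2.0 * np.pi * np.arange(c) / c
        rows.append(
            np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(c, z)]
            )
        )
    return np.vstack(rows)


def make_cone(slice_counts: Sequence[int]) -> NodeLayout:
    """Cone-surface layout from per-slice node counts, apex first.

    ``slice_counts[0]`` must be 1 (the apex) and counts must be
    non-decreasing toward the base.  ``slice_counts=[1, 4, 8, 12]`` gives
    the 25-node conical template.
    """
    counts = [int(c) for c in slice_counts]
    if not counts:
        raise LayoutError("slice_counts must be non-empty")
    if counts[0] != 1:
        raise LayoutError("the first slice is the apex and must have count 1")
    if any(b < a for a, b in zip(counts, counts[1:])):
        raise LayoutError("slice counts must be non-decreasing toward the base")
    if any(c < 1 for c in counts):
        raise LayoutError("slice counts must be positive")
    return NodeLayout(_cone_coords(counts), "cone", tuple(counts))


def make_cylinder(n_rings: int, nodes_per_ring: int) -> NodeLayout:
    """Rings of radius 1 at evenly spaced heights in [-1, 1]."""
    n_rings, nodes_per_ring = int(n_rings), int(nodes_per_ring)
    if n_rings < 2:
        raise LayoutError("a cylinder needs at least 2 rings")
    if nodes_per_ring < 3:
        raise LayoutError("a cylinder needs at least 3 nodes per ring")
    heights = np.linspace(-1.0, 1.0, n_rings)
    ang = 2.0 * np.pi * np.arange(nodes_per_ring) / nodes_per_ring
    rows = [
        np.column_stack(
            [np.cos(ang), np.sin(ang), np.full(nodes_per_ring, z)]
        )
        for z in heights
    ]
    return NodeLayout(np.vstack(rows), "cylinder", (n_rings, nodes_per_ring))


def expand_layout(layout: NodeLayout) -> NodeLayout:
    """Coarse-to-fine refinement: insert nodes halfway between existing ones.

    Grids gain every half-step lattice point (side s -> 2s - 1, so 5x5 ->
    9x9); cones double the slice resolution, extending the per-slice counts
    by the arithmetic progression of the base schedule ([1,4,8,12] ->
    [1,4,8,12,16,20,24]); cylinders double both ring count resolution and
    nodes per ring.  The original nodes are always a subset of the refined
    set.
    """
    if layout.kind in ("square_grid", "rect_grid", "cuboid"):
        sides = layout.structure
        lo = layout.coords.min(axis=0)
        hi = layout.coords.max(axis=0)
        new_sides = [2 * s - 1 for s in sides]
        return make_grid(new_sides, bounds=list(zip(lo, hi)))
    if layout.kind == "cone":
        counts = list(layout.structure)
        if len(counts) < 2:
            raise LayoutError("cannot refine a single-slice cone")
        step = counts[-1] - counts[-2]
        new_counts = counts + [
            counts[-1] + step * (i + 1) for i in range(len(counts) - 1)
        ]
        return make_cone(new_counts)
    if layout.kind == "cylinder":
        n_rings, npr = layout.structure
        return make_cylinder(2 * n_rings - 1, 2 * npr)
    raise NotImplementedError(f"no refinement rule for layout kind {layout.kind!r}")


def layout_from_spec(spec: dict) -> NodeLayout:
    """Build a layout from a config mapping: {kind, sides|slice_counts|rings...}."""
    kind = spec.get("kind")
    if kind in ("grid", "square_grid", "rect_grid", "cuboid"):
        layout = make_grid(spec["sides"], bounds=spec.get("bounds"))
    elif kind == "cone":
        layout = make_cone(spec["slice_counts"])
    elif kind == "cylinder":
        layout = make_cylinder(spec["rings"], spec["nodes_per_ring"])
    else:
        raise LayoutError(f"unknown layout kind {kind!r}")
    if spec.get("expand"):
        layout = expand_layout(layout)
    return layout
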