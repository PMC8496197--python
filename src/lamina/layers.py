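"""Equi-volume cortical depth grids and voxel-to-layer assignment.

Gyral crowns and sulcal fundi change the cross-sectional area of the
cortical ribbon between the white-matter and pial boundaries.  Layers that
preserve their *volume* fraction therefore sit at different relative
depths than equidistant layers.  With a locally linear area profile
``A(t) = A_w + (A_p - A_w) t`` along the normal (``A_w`` inner/white patch
area, ``A_p`` outer/pial patch area, both mm^2), the depth ``x`` enclosing
a volume fraction ``alpha`` solves

    A_w x + (A_p - A_w) x^2 / 2 = alpha (A_w + A_p) / 2

which gives the closed form used by :func:`equivolume_fraction`.  Four
depth grids at volume fractions {0, 1/3, 2/3, 1} bound three laminae
(deeper, middle, superficial); each grey-matter voxel is assigned to the
lamina bounded by its two nearest grids (Euclidean distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import LAYER_NAMES


def equivolume_fraction(alpha, inner_area, outer_area):
    """Depth fraction enclosing volume fraction ``alpha`` in a linear-area wedge.

    Parameters are broadcast; ``alpha`` in [0,1], areas strictly positive.
    Reduces to ``alpha`` (equidistant) when the areas are equal.
    """
    alpha = np.asarray(alpha, dtype=float)
    a_w = np.asarray(inner_area, dtype=float)
    a_p = np.asarray(outer_area, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    if np.any(a_w <= 0) or np.any(a_p <= 0):
        raise ValueError("boundary areas must be strictly positive")
    alpha, a_w, a_p = np.broadcast_arrays(alpha, a_w, a_p)
    diff = a_p - a_w
    # quadratic solution; fall back to the equidistant limit where the
    # areas coincide (the formula is 0/0 there but continuous)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (-a_w + np.sqrt((1 - alpha) * a_w**2 + alpha * a_p**2)) / diff
    near_equal = np.abs(diff) <= 1e-12 * np.maximum(a_w, a_p)
    x = np.where(near_equal, alpha, x)
    return x if x.ndim else float(x)


@dataclass
class GridSurfaces:
    """Depth grids: per-column depth fractions plus 3-D grid points.

    ``fractions`` is ``n_columns x n_grids`` (ordered from the white to
    the pial boundary); ``points[k]`` holds the mm coordinates of grid k,
    one point per column.
    """

    fractions: np.ndarray
    points: list[np.ndarray]

    @property
    def n_grids(self) -> int:
        return self.fractions.shape[1]


def build_grids(model, n_grids: int = 4) -> GridSurfaces:
    """Place ``n_grids`` equi-volume depth grids through every column.

    Grid k sits at the depth enclosing volume fraction ``k/(n_grids-1)``
    given the column's inner/outer boundary areas.
    """
    if n_grids < 2:
        raise ValueError("need at least 2 grids to bound a layer")
    alphas = np.arange(n_grids) / (n_grids - 1)
    fractions = np.stack(
        [equivolume_fraction(a, model.inner_area, model.outer_area) for a in alphas],
        axis=1)
    points = []
    for k in range(n_grids):
        pts = np.column_stack([model.column_xy,
                               fractions[:, k] * model.thickness])
        points.append(pts)
    return GridSurfaces(fractions=fractions, points=points)


@dataclass
class LayerAssignment:
    """Per-voxel cortical depth bin.

    ``layer_id`` indexes :data:`~lamina.core.LAYER_NAMES`
    (0=deeper, 1=middle, 2=superficial); ``depth_fraction`` is the
    geometric depth estimate interpolated between the bounding grids.
    """

    layer_id: np.ndarray
    depth_fraction: np.ndarray
    counts: pd.DataFrame        # rows (area, layer) -> voxel count

    def layer_names(self) -> np.ndarray:
        return np.asarray(LAYER_NAMES)[self.layer_id]


def assign_voxels(model, grids: GridSurfaces) -> LayerAssignment:
    """Assign every voxel to the lamina bounded by its two nearest grids.

    Distances are Euclidean distances to the nearest point of each grid.
    A voxel lying exactly on an interior grid is assigned to the shallower
    (more superficial) of the two adjacent bands, deterministically.
    """
    n_vox = model.voxel_positions.shape[0]
    n_grids = grids.n_grids
    dists = np.empty((n_vox, n_grids))
    for k in range(n_grids):
        tree = cKDTree(grids.points[k])
        dists[:, k], _ = tree.query(model.voxel_positions)

    nearest = np.argmin(dists, axis=1)
    layer = np.empty(n_vox, dtype=int)
    depth_fraction = np.empty(n_vox)
    col = model.column_id
    for v in range(n_vox):
        g = nearest[v]
        if g == 0:
            lo = 0
        elif g == n_grids - 1:
            lo = n_grids - 2
        else:
            # second-closest among the two neighbours; exact tie goes to
            # the shallower neighbour so an on-grid voxel lands in the
            # band above the grid
            lo = g if dists[v, g + 1] <= dists[v, g - 1] else g - 1
        layer[v] = min(lo, n_grids - 2)
        # depth estimate: interpolate within the *bracketing* grid pair.
        # A voxel inside a band satisfies d_lo + d_hi ~ band thickness, so
        # the bracket is the pair with least excess over its own gap; this
        # keeps the estimate monotone along a column even where the
        # two-closest band assignment flips at a band boundary
        gaps = np.diff(grids.fractions[col[v]]) * model.thickness
        j = int(np.argmin(dists[v, :-1] + dists[v, 1:] - gaps))
        f_lo = grids.fractions[col[v], j]
        f_hi = grids.fractions[col[v], j + 1]
        d_lo, d_hi = dists[v, j], dists[v, j + 1]
        tot = d_lo + d_hi
        depth_fraction[v] = f_lo if tot == 0 else f_lo + (f_hi - f_lo) * d_lo / tot

    if n_grids == 4:
        names = np.asarray(LAYER_NAMES)[layer]
    else:  # generic band labels for non-default grid counts
        names = np.asarray([f"band{i}" for i in range(n_grids - 1)])[layer]
    counts = (pd.DataFrame({"area": model.area_id, "layer": names})
              .value_counts().rename("n_voxels").reset_index()
              .sort_values(["area", "layer"]).reset_index(drop=True))
    return LayerAssignment(layer_id=layer, depth_fraction=depth_fraction,
                           counts=counts)
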