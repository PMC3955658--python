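"""Regional homogeneity: Kendall's coefficient of concordance (KCC) maps.

ReHo quantifies how synchronously the BOLD series at a location varies with
its immediate spatial neighbors.  For a neighborhood of K series over n
frames, each series is ranked in time (average ranks for ties) and

    W = 12 * S / (K^2 (n^3 - n) - K * sum_j T_j),

where S is the sum of squared deviations of the per-frame rank sums from
their mean and T_j = sum over tie groups of (t^3 - t) is the tie correction
of series j.  W lies in [0, 1]; 1 means all K series share one rank
ordering.

Map variants:

* ``2dReHo``  -- surface, closed one-ring neighborhood (7 series at a
  regular degree-6 vertex);
* ``2dReHo2`` -- surface, closed two-ring (19 series at a regular vertex);
* ``3dReHo``  -- volume, the 3x3x3 cube (26 neighbors plus center).

Surface maps are computed for all vertices at once: ranks and tie terms are
evaluated per vertex series, and neighborhood sums are accumulated through
the sparse membership matrix, which is algebraically identical to calling
:func:`kendalls_w` per neighborhood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .mesh import NeighborhoodTable
from .preprocess import SurfaceBold, VolumeBold

VARIANT_NAMES = {"ring1": "2dReHo", "ring2": "2dReHo2"}


@dataclass
class ReHoMap:
    """Per-vertex (or per-voxel) Kendall's W values.

    Undefined locations (degenerate neighborhoods) are NaN.  ``variant`` is
    one of ``2dReHo``, ``2dReHo2``, ``3dReHo``.
    """

    values: np.ndarray
    variant: str
    smoothed_fwhm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("ReHo values must lie in [0, 1]")


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (constant rows get mid-ranks)."""
    return rankdata(x, axis=-1)


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """Per-row tie correction sum_{tie groups} (t^3 - t), vectorized."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    s = np.sort(x, axis=-1)
    new_group = np.ones(x.shape, dtype=bool)
    new_group[..., 1:] = np.diff(s, axis=-1) != 0
    # group id within each row, then counts per (row, group)
    gid = np.cumsum(new_group, axis=-1) - 1
    rows = x.reshape(-1, n)
    gid = gid.reshape(-1, n)
    offset = (np.arange(rows.shape[0]) * n)[:, None]
    counts = np.bincount((gid + offset).ravel(), minlength=rows.shape[0] * n)
    counts = counts.reshape(rows.shape[0], n).astype(np.float64)
    t3 = counts**3 - counts
    return t3.sum(axis=1).reshape(x.shape[:-1])


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's W of a K x n matrix of series (tie-corrected, in [0, 1]).

    Returns NaN if every series is constant (the statistic is undefined:
    the denominator vanishes).
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("series must be a K x n matrix")
    k, n = series.shape
    if k < 2:
        raise ValueError("need at least 2 series")
    if n < 2:
        raise ValueError("need at least 2 time points")
    ranks = _rank_rows(series)
    col_sums = ranks.sum(axis=0)
    s = float(np.sum((col_sums - col_sums.mean()) ** 2))
    tie = float(_tie_terms(series).sum())
    denom = k * k * (n**3 - n) - k * tie
    if denom <= 0:
        return float("nan")
    w = 12.0 * s / denom
    if w < -1e-9 or w > 1 + 1e-9:
        raise AssertionError(f"Kendall's W out of range: {w}")
    return float(min(max(w, 0.0), 1.0))


def reho_surface(bold: SurfaceBold, neighborhoods: NeighborhoodTable) -> ReHoMap:
    """Vertexwise ReHo map over the given neighborhood table.

    ``values[v]`` equals ``kendalls_w`` of the series of the members of
    ``v``'s neighborhood.  Vertices whose entire neighborhood is constant
    in time are NaN.
    """
    n_vert = len(neighborhoods.members)
    if bold.n_vertices != n_vert:
        raise ValueError("BOLD vertex count does not match neighborhood table")
    n = bold.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    ranks = _rank_rows(bold.data)            # (V, n)
    ties = _tie_terms(bold.data)             # (V,)
    ind = neighborhoods.indicator            # (V, V)
    k = np.asarray(ind.sum(axis=1)).ravel()  # members per vertex
    col_sums = ind @ ranks                   # per-frame rank sums
    mean = k[:, None] * (n + 1) / 2.0
    s = np.sum((col_sums - mean) ** 2, axis=1)
    tie_sums = ind @ ties
    denom = k * k * (n**3 - n) - k * tie_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / denom
    w[denom <= 0] = np.nan
    finite = np.isfinite(w)
    if np.any(w[finite] < -1e-9) or np.any(w[finite] > 1 + 1e-9):
        raise AssertionError("Kendall's W out of range in surface map")
    w[finite] = np.clip(w[finite], 0.0, 1.0)
    variant = VARIANT_NAMES.get(neighborhoods.variant, neighborhoods.variant)
    return ReHoMap(w, variant, meta={"n_frames": n})


def reho_volume(bold: VolumeBold) -> ReHoMap:
    """Voxelwise ReHo over each voxel's 3x3x3 cube, honoring the mask.

    Out-of-mask neighbors are excluded (K shrinks at mask edges rather than
    zero-padding); voxels whose cube retains fewer than 2 in-mask members
    are NaN.  An interior voxel of a full mask uses 27 series (26 neighbors
    plus the center).
    """
    mask = bold.mask
    if not mask.any():
        raise ValueError("empty mask")
    nx, ny, nz, n = bold.data.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    flat = bold.data[mask]                   # (n_mask, n)
    ranks_flat = _rank_rows(flat)
    ties_flat = _tie_terms(flat)
    ranks = np.zeros((nx, ny, nz, n))
    ranks[mask] = ranks_flat
    ties = np.zeros((nx, ny, nz))
    ties[mask] = ties_flat
    m = mask.astype(np.float64)

    col_sums = np.zeros((nx, ny, nz, n))
    k = np.zeros((nx, ny, nz))
    tie_sums = np.zeros((nx, ny, nz))
    for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
        src = tuple(slice(max(d, 0), None if d >= 0 else d) for d in (dx, dy, dz))
        dst = tuple(slice(max(-d, 0), None if d <= 0 else -d) for d in (dx, dy, dz))
        col_sums[dst] += ranks[src]
        k[dst] += m[src]
        tie_sums[dst] += ties[src]

    mean = k[..., None] * (n + 1) / 2.0
    s = np.sum((col_sums - mean) ** 2, axis=-1)
    denom = k * k * (n**3 - n) - k * tie_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / denom
    w[~mask | (k < 2) | (denom <= 0)] = np.nan
    finite = np.isfinite(w)
    w[finite] = np.clip(w[finite], 0.0, 1.0)
    return ReHoMap(w, "3dReHo",
                   meta={"n_frames": n, "max_cube_members": int(k[mask].max())})


def global_mean_reho(reho_map: ReHoMap, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean of defined ReHo values, optionally within a mask."""
    vals = reho_map.values
    if mask is not None:
        vals = vals.reshape(-1)[np.asarray(mask)] if vals.ndim == 1 else vals[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined ReHo values in selection")
    return float(vals.mean())


def extract_cluster_mean(reho_map: ReHoMap, cluster_vertices: np.ndarray) -> float:
    """Mean ReHo over a cluster's vertices (used for clinical correlations)."""
    idx = np.asarray(cluster_vertices, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("empty cluster")
    vals = reho_map.values.reshape(-1)[idx]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cluster contains no defined ReHo values")
    return float(vals.mean())
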