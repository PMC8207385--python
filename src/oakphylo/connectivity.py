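"""Habitat patches, least-cost graphs, and equivalent connectivity area.

The workflow mirrors a resistance-surface connectivity analysis: rescale a
suitability model around a presence threshold, classify terrain ruggedness,
combine the two into a 0-100 habitat layer, extract 8-connected habitat
patches, compute least-cost distances between patches over the resistance
surface (resistance = 101 - habitat), and summarize the landscape with the
ECA index ``sqrt(sum_ij a_i a_j p*_ij)`` where ``p*`` is the maximum
product of per-link dispersal probabilities over graph paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra, shortest_path

from .raster import Raster

__all__ = [
    "thin_occurrences",
    "select_uncorrelated_variables",
    "tri",
    "jenks_breaks",
    "rescale_suitability",
    "combine_habitat",
    "extract_patches",
    "least_cost_distances",
    "eca",
    "area_by_elevation_bin",
    "PatchSet",
    "EcaResult",
]

EARTH_RADIUS_KM = 6371.0088


def _great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(points: np.ndarray, radius_km: float = 10.0) -> np.ndarray:
    """Greedy spatial thinning: keep a point iff no already-kept point lies
    within ``radius_km`` (great-circle).  ``points`` is (n, 2) lat/lon."""
    points = np.asarray(points, dtype=float)
    kept: list[int] = []
    for i in range(points.shape[0]):
        if not kept:
            kept.append(i)
            continue
        d = _great_circle_km(
            points[i, 0], points[i, 1], points[kept, 0], points[kept, 1]
        )
        if np.all(d >= radius_km):
            kept.append(i)
    return points[kept]


def select_uncorrelated_variables(
    rasters: dict[str, Raster], specificity_rank: list[str], r_max: float = 0.7
) -> list[str]:
    """Drop the more specific member of each over-correlated raster pair.

    ``specificity_rank`` lists variable names from most general to most
    specific; whenever two variables correlate with |r| > ``r_max`` over
    jointly valid cells, the later-ranked (more specific) one is removed.
    """
    names = list(rasters)
    base = rasters[names[0]]
    for n in names[1:]:
        if not rasters[n].aligned_with(base):
            raise ValueError(f"raster {n!r} is not aligned with {names[0]!r}")
    keep = [n for n in specificity_rank if n in names]
    changed = True
    while changed:
        changed = False
        for i in range(len(keep)):
            for j in range(i + 1, len(keep)):
                a, b = rasters[keep[i]].masked(), rasters[keep[j]].masked()
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < 3:
                    continue
                r = np.corrcoef(a[ok], b[ok])[0, 1]
                if np.isfinite(r) and abs(r) > r_max:
                    keep.pop(j)  # the more specific of the pair
                    changed = True
                    break
            if changed:
                break
    return keep


def tri(dem: Raster) -> Raster:
    """Topographic ruggedness: per cell, root-sum-of-squares of elevation
    differences to the valid 8-neighbors; nodata cells propagate."""
    z = dem.masked()
    if not np.isfinite(z).any():
        raise ValueError("DEM has no valid cells")
    acc = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            shifted = np.full_like(z, np.nan)
            rs = slice(max(dr, 0), z.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), z.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), z.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), z.shape[1] + min(-dc, 0))
            shifted[rd, cd] = z[rs, cs]
            diff2 = (z - shifted) ** 2
            acc += np.where(np.isfinite(diff2), diff2, 0.0)
    out = np.sqrt(acc)
    out[~np.isfinite(z)] = dem.nodata
    return dem.like(out)


def jenks_breaks(values: np.ndarray, k: int = 10, max_n: int = 2_000) -> np.ndarray:
    """Fisher-Jenks natural breaks: boundaries minimizing within-class SSD.

    Returns ``k + 1`` boundaries (min, k-1 internal upper bounds, max).
    Deterministic; when more than ``max_n`` distinct values are supplied the
    DP runs on an even quantile subsample.  ``k`` is reduced with a warning
    when fewer distinct values exist.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    vals = vals[np.isfinite(vals)]
    distinct = np.unique(vals)
    if distinct.size < k:
        warnings.warn(f"only {distinct.size} distinct values; reducing k", stacklevel=2)
        k = max(int(distinct.size), 1)
    if vals.size > max_n:
        idx = np.unique(np.round(np.linspace(0, vals.size - 1, max_n)).astype(int))
        vals = vals[idx]
    n = vals.size
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    csum2 = np.concatenate([[0.0], np.cumsum(vals**2)])

    def ssd(i: int, j: int) -> float:
        # within-class sum of squared deviations for vals[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best - 1e-12:
                    best, arg = v, i
            cost[c, j], back[c, j] = best, arg
    bounds = [float(vals[-1])]
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        # internal boundary = last value of the preceding class
        bounds.append(float(vals[i - 1]) if c > 1 else float(vals[0]))
        j = i
    return np.array(bounds[::-1])


def classify_by_breaks(raster: Raster, breaks: np.ndarray) -> Raster:
    """Class index (1..k) per cell from Jenks boundaries; nodata propagates."""
    k = len(breaks) - 1
    z = raster.masked()
    cls = np.digitize(z, breaks[1:-1], right=True) + 1.0
    cls = np.clip(cls, 1, k)
    cls[~np.isfinite(z)] = raster.nodata
    return raster.like(cls)


def rescale_suitability(model: Raster, threshold: float) -> Raster:
    """Map a 0-1 suitability model onto a 0-100 scale around a threshold.

    At or above the threshold the cell scores 100; below it the value is
    ``100 - (threshold - v) * 100 / threshold`` (linearly down to 0 at v=0).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    v = model.masked()
    out = np.where(v >= threshold, 100.0, 100.0 - (threshold - v) * 100.0 / threshold)
    out[~np.isfinite(v)] = model.nodata
    return model.like(out)


def tri_class_suitability(tri_classes: Raster, k: int = 10) -> Raster:
    """Map ruggedness classes 1..k to suitability 100, 90, ..., descending."""
    z = tri_classes.masked()
    out = 100.0 - (z - 1.0) * (100.0 / k)
    out[~np.isfinite(z)] = tri_classes.nodata
    return tri_classes.like(out)


def combine_habitat(
    climate_layer: Raster, tri_layer: Raster, weights: tuple[float, float] = (0.5, 0.5)
) -> Raster:
    """Weighted arithmetic mean of two aligned 0-100 layers."""
    if not climate_layer.aligned_with(tri_layer):
        raise ValueError("layers are not aligned")
    wa, wb = weights
    total = wa + wb
    a, b = climate_layer.masked(), tri_layer.masked()
    out = (wa * a + wb * b) / total
    bad = ~np.isfinite(out)
    out[bad] = climate_layer.nodata
    return climate_layer.like(out)


# ----------------------------------------------------------------------
# Patches
# ----------------------------------------------------------------------

@dataclass
class PatchSet:
    labels: np.ndarray  # (rows, cols) int, 0 = background
    areas: np.ndarray  # km^2 per patch (1-based patch ids -> index 0..)
    centroids: np.ndarray  # (n_patches, 2) row/col
    cell_size: float

    @property
    def n_patches(self) -> int:
        return self.areas.size

    def cells(self, patch: int) -> np.ndarray:
        return np.argwhere(self.labels == patch + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patch": np.arange(self.n_patches),
                "area_km2": self.areas,
                "centroid_row": self.centroids[:, 0],
                "centroid_col": self.centroids[:, 1],
            }
        )


_EIGHT = np.ones((3, 3), dtype=int)


def extract_patches(
    habitat: Raster,
    min_mean_value: float = 50.0,
    window_cells: int = 1,
    min_area_cells: int = 1,
) -> PatchSet:
    """8-connected components of cells whose moving-window mean habitat value
    meets ``min_mean_value`` (window of one cell = raw values)."""
    z = habitat.masked()
    if window_cells > 1:
        from scipy.ndimage import uniform_filter

        filled = np.where(np.isfinite(z), z, 0.0)
        weight = uniform_filter(np.isfinite(z).astype(float), size=window_cells)
        mean = uniform_filter(filled, size=window_cells) / np.maximum(weight, 1e-12)
    else:
        mean = z
    core = np.isfinite(mean) & (mean >= min_mean_value)
    labels, n = cc_label(core, structure=_EIGHT)
    if n == 0:
        warnings.warn("no habitat cells above threshold", stacklevel=2)
        return PatchSet(labels, np.empty(0), np.empty((0, 2)), habitat.cell_size)
    keep = []
    for p in range(1, n + 1):
        if (labels == p).sum() >= min_area_cells:
            keep.append(p)
    relabeled = np.zeros_like(labels)
    areas, cents = [], []
    for new_id, p in enumerate(keep, start=1):
        cells = labels == p
        relabeled[cells] = new_id
        areas.append(cells.sum() * habitat.cell_area())
        rc = np.argwhere(cells)
        cents.append(rc.mean(axis=0))
    return PatchSet(relabeled, np.array(areas), np.array(cents), habitat.cell_size)


# ----------------------------------------------------------------------
# Least-cost distances
# ----------------------------------------------------------------------

def resistance_from_habitat(habitat: Raster) -> Raster:
    """Resistance = 101 - habitat value, so traversable cells cost >= 1."""
    z = habitat.masked()
    out = 101.0 - z
    out[~np.isfinite(z)] = habitat.nodata
    return habitat.like(out)


def _grid_graph(resistance: Raster):
    """Sparse 8-neighbor cost graph over valid cells.

    Move cost = mean of the two cells' resistances x (1 rook, sqrt(2)
    diagonal) x cell size.
    """
    z = resistance.masked()
    rows, cols = z.shape
    valid = np.isfinite(z)
    node = -np.ones(z.shape, dtype=int)
    node[valid] = np.arange(valid.sum())
    src, dst, wgt = [], [], []
    for dr, dc, mult in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        c_lo, c_hi = max(-dc, 0), cols - max(dc, 0)
        ra = slice(0, rows - dr)
        ca = slice(c_lo, c_hi)
        rb = slice(dr, rows)
        cb = slice(c_lo + dc, c_hi + dc)
        a, b = node[ra, ca], node[rb, cb]
        za, zb = z[ra, ca], z[rb, cb]
        ok = (a >= 0) & (b >= 0)
        cost = 0.5 * (za + zb) * mult * resistance.cell_size
        src.append(a[ok])
        dst.append(b[ok])
        wgt.append(cost[ok])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    wgt = np.concatenate(wgt)
    n = int(valid.sum())
    g = coo_matrix(
        (np.concatenate([wgt, wgt]), (np.concatenate([src, dst]), np.concatenate([dst, src]))),
        shape=(n, n),
    ).tocsr()
    return g, node


def least_cost_distances(
    resistance: Raster, patches: PatchSet, cost_threshold: float = 100_000.0
) -> np.ndarray:
    """Pairwise least-cost distances between patches (min over cell pairs).

    Multi-source Dijkstra runs from every cell of each patch; distances above
    ``cost_threshold`` are reported as ``inf`` (unreachable)."""
    if patches.n_patches == 0:
        raise ValueError("empty patch set")
    g, node = _grid_graph(resistance)
    k = patches.n_patches
    d = np.zeros((k, k))
    patch_nodes = []
    for p in range(k):
        cells = patches.cells(p)
        ids = node[cells[:, 0], cells[:, 1]]
        ids = ids[ids >= 0]
        patch_nodes.append(ids)
        if ids.size == 0:
            warnings.warn(f"patch {p} lies entirely on nodata cells", stacklevel=2)
    for p in range(k):
        if patch_nodes[p].size == 0:
            d[p, :] = np.inf
            d[:, p] = np.inf
            d[p, p] = 0.0
            continue
        dist = dijkstra(g, indices=patch_nodes[p], min_only=True)
        for q in range(p + 1, k):
            if patch_nodes[q].size == 0:
                d[p, q] = d[q, p] = np.inf
                continue
            best = float(dist[patch_nodes[q]].min())
            d[p, q] = d[q, p] = best if best <= cost_threshold else np.inf
    return d


# ----------------------------------------------------------------------
# ECA
# ----------------------------------------------------------------------

@dataclass
class EcaResult:
    eca: float
    areas: np.ndarray
    distances: np.ndarray
    probabilities: np.ndarray  # max-product p*_ij
    alpha: float
    period: str = ""


def eca(
    patches: PatchSet,
    distances: np.ndarray,
    p_ref: float = 0.5,
    d_ref: float = 1.0,
    direct_only: bool = False,
    period: str = "",
) -> EcaResult:
    """Equivalent connectivity area.

    ``alpha = -ln(p_ref) / d_ref``; direct link probability
    ``p_ij = exp(-alpha d_ij)``; unless ``direct_only``, ``p*_ij`` is the
    maximum product probability over paths in the patch graph (shortest
    path on ``-ln p`` weights).  ``ECA = sqrt(sum_ij a_i a_j p*_ij)``, so a
    single patch yields its own area.
    """
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    if not 0 < p_ref < 1:
        raise ValueError("p_ref must be in (0, 1)")
    a = np.asarray(patches.areas, dtype=float)
    d = np.asarray(distances, dtype=float)
    if d.shape != (a.size, a.size):
        raise ValueError("distance matrix does not match the patch set")
    alpha = -np.log(p_ref) / d_ref
    if direct_only:
        star = alpha * d
    else:
        star = shortest_path(alpha * d, method="FW", directed=False)
    p_star = np.exp(-star)
    np.fill_diagonal(p_star, 1.0)
    value = float(np.sqrt(a @ p_star @ a))
    return EcaResult(value, a, d, p_star, float(alpha), period)


def area_by_elevation_bin(
    dem: Raster,
    bin_width: float = 100.0,
    value_range: tuple[float, float] | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Accumulate cell area into ``[b, b + bin_width)`` elevation bins."""
    z = dem.masked()
    if mask is not None:
        z = np.where(mask, z, np.nan)
    vals = z[np.isfinite(z)]
    if value_range is None:
        lo = np.floor(vals.min() / bin_width) * bin_width if vals.size else 0.0
        hi = np.ceil((vals.max() + 1e-9) / bin_width) * bin_width if vals.size else bin_width
    else:
        lo, hi = value_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "area_km2": counts * dem.cell_area(),
        }
    )
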