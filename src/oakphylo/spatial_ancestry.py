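"""Geographically regularized ancestry-coefficient estimation.

Minimizes ``||X - QG||^2 + lambda * tr(Q' L Q)`` where rows of Q live on the
probability simplex, G is clipped to [0, 1] and L is the graph Laplacian of
a heat-kernel similarity between sampling coordinates.  Optimization is
alternating projected gradient descent with Lipschitz step sizes, so the
objective never increases.  K is chosen by masked-entry cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import _great_circle_km
from .genodata import MISSING, GenotypeTable
from .raster import Raster

__all__ = [
    "encode_genotypes",
    "fit_ancestry",
    "select_k",
    "interpolate_ancestry",
    "AncestryFit",
    "CrossValidationCurve",
]


def encode_genotypes(table: GenotypeTable) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """One-hot frequency encoding of a diploid table.

    ``X[i, (locus, allele)]`` is the fraction of individual i's copies that
    carry the allele (0, 0.5 or 1); columns of a fully typed locus sum to 1
    per row.  Missing loci are imputed with the observed column means so the
    factorization can run on incomplete tables.
    """
    if table.ploidy != 2:
        raise ValueError("encoding requires a diploid table")
    columns: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for j, locus in enumerate(table.loci):
        g = table.alleles[:, j, :]
        observed = np.unique(g[g != MISSING])
        block = np.zeros((table.n_individuals, observed.size))
        miss = (g == MISSING).all(axis=1)
        for k, a in enumerate(observed):
            block[:, k] = (g == a).sum(axis=1) / 2.0
        if miss.any():
            col_mean = block[~miss].mean(axis=0) if (~miss).any() else np.full(observed.size, 1 / max(observed.size, 1))
            block[miss] = col_mean
        blocks.append(block)
        columns.extend((locus, int(a)) for a in observed)
    return np.hstack(blocks), columns


def _project_simplex_rows(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    u = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    idx = np.arange(1, k + 1)
    cond = u - css / idx > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Q - theta[:, None], 0.0)


def _laplacian(coords: np.ndarray) -> np.ndarray:
    """Heat-kernel graph Laplacian (bandwidth = mean pairwise distance),
    rescaled to unit spectral norm so ``lam`` is comparable across sample
    sizes and geographies."""
    lat, lon = coords[:, 0], coords[:, 1]
    d = _great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    off = d[~np.eye(d.shape[0], dtype=bool)]
    sigma = float(off.mean()) if off.size and off.mean() > 0 else 1.0
    w = np.exp(-((d / sigma) ** 2))
    np.fill_diagonal(w, 0.0)
    L = np.diag(w.sum(axis=1)) - w
    top = np.linalg.eigvalsh(L)[-1]
    return L / top if top > 0 else L


@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray  # (n, K), rows on the simplex
    G: np.ndarray  # (K, n_columns), in [0, 1]
    lam: float
    objective: float
    objective_path: np.ndarray
    seed: int | None
    converged: bool


def _objective(X, Q, G, lam, L) -> float:
    r = X - Q @ G
    val = float(np.sum(r * r))
    if lam > 0:
        val += lam * float(np.trace(Q.T @ L @ Q))
    return val


def fit_ancestry(
    X: np.ndarray,
    coords: np.ndarray,
    K: int,
    lam: float = 1.0,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    inner: int = 10,
) -> AncestryFit:
    """Alternating projected gradient fit of the regularized factorization."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != n:
        raise ValueError("coords must align with X rows")
    L = _laplacian(coords) if lam > 0 else np.zeros((n, n))
    lam_L = float(np.linalg.eigvalsh(L)[-1]) if lam > 0 else 0.0

    rng = np.random.default_rng(seed)
    Q = _project_simplex_rows(rng.random((n, K)))
    G = np.clip(rng.random((K, m)), 0.0, 1.0)

    path = [_objective(X, Q, G, lam, L)]
    converged = False
    for _ in range(max_iter):
        # Q block: Lipschitz constant of grad_Q = 2(||GG'|| + lam ||L||)
        GGt = G @ G.T
        lip_q = 2.0 * (np.linalg.norm(GGt, 2) + lam * lam_L) + 1e-12
        for _ in range(inner):
            grad = 2.0 * ((Q @ GGt) - X @ G.T) + 2.0 * lam * (L @ Q)
            Q = _project_simplex_rows(Q - grad / lip_q)
        # G block
        QtQ = Q.T @ Q
        lip_g = 2.0 * np.linalg.norm(QtQ, 2) + 1e-12
        for _ in range(inner):
            grad = 2.0 * (QtQ @ G - Q.T @ X)
            G = np.clip(G - grad / lip_g, 0.0, 1.0)
        obj = _objective(X, Q, G, lam, L)
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite objective; check inputs")
        if obj > path[-1] + 1e-8 * max(1.0, abs(path[-1])):
            raise AssertionError("objective increased; projected gradient step invalid")
        rel = (path[-1] - obj) / max(abs(path[-1]), 1e-12)
        path.append(obj)
        if rel < tol:
            converged = True
            break
    return AncestryFit(K, Q, G, lam, path[-1], np.array(path), seed, converged)


@dataclass
class CrossValidationCurve:
    errors: dict[int, np.ndarray]  # K -> replicate RMSEs
    medians: dict[int, float]
    chosen_k: int
    mask_fraction: float

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"K": list(self.medians), "median_rmse": list(self.medians.values())}
        )


def select_k(
    X: np.ndarray,
    coords: np.ndarray,
    k_range,
    mask_fraction: float = 0.05,
    replicates: int = 10,
    lam: float = 1.0,
    seed: int | None = None,
    column_groups: list | None = None,
    **fit_kwargs,
) -> CrossValidationCurve:
    """Masked-prediction cross-validation over K.

    Per replicate, ``mask_fraction`` of the entries of X are hidden (replaced
    by their column means), the model is fitted, and the RMSE between ``QG``
    and the hidden entries is recorded.  ``column_groups`` assigns each
    column to a locus; columns of one locus are masked together (otherwise
    the complementary one-hot columns leak the held-out genotype).  The
    chosen K is the smallest whose median error lies within one standard
    error of the global minimum.
    """
    if mask_fraction <= 0:
        raise ValueError("mask_fraction must be positive")
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("empty K range")
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if column_groups is None:
        column_groups = list(range(m))
    groups = list(dict.fromkeys(column_groups))
    group_cols = {g: [j for j, gj in enumerate(column_groups) if gj == g] for g in groups}
    rng = np.random.default_rng(seed)
    col_means = X.mean(axis=0)
    errors: dict[int, np.ndarray] = {}
    for K in k_range:
        if K > n:
            warnings.warn(f"K={K} exceeds the number of individuals; skipped", stacklevel=2)
            continue
        errs = []
        for _ in range(replicates):
            block = rng.random((n, len(groups))) < mask_fraction
            if not block.any():
                block[rng.integers(n), rng.integers(len(groups))] = True
            mask = np.zeros((n, m), dtype=bool)
            for gi, g in enumerate(groups):
                mask[np.ix_(block[:, gi], group_cols[g])] = True
            Xm = X.copy()
            Xm[mask] = np.broadcast_to(col_means, X.shape)[mask]
            fit = fit_ancestry(
                Xm, coords, K, lam=lam, seed=int(rng.integers(2**31)), **fit_kwargs
            )
            pred = fit.Q @ fit.G
            errs.append(float(np.sqrt(np.mean((pred[mask] - X[mask]) ** 2))))
        errors[K] = np.array(errs)
    medians = {K: float(np.median(v)) for K, v in errors.items()}
    best_k = min(medians, key=medians.get)
    se = float(np.std(errors[best_k], ddof=1) / np.sqrt(len(errors[best_k]))) if len(errors[best_k]) > 1 else 0.0
    cutoff = medians[best_k] + se
    chosen = min(k for k, v in medians.items() if v <= cutoff)
    return CrossValidationCurve(errors, medians, chosen, mask_fraction)


def interpolate_ancestry(
    fit: AncestryFit,
    coords: np.ndarray,
    grid_shape: tuple[int, int],
    extent: tuple[float, float, float, float] | None = None,
    power: float = 2.0,
) -> list[Raster]:
    """Inverse-distance-weighted interpolation of each ancestry column onto a
    lat/lon grid; a grid cell coincident with a sample takes that sample's Q
    row exactly.  ``extent`` is (lat_min, lat_max, lon_min, lon_max)."""
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("empty grid")
    coords = np.asarray(coords, dtype=float)
    if extent is None:
        extent = (
            coords[:, 0].min(), coords[:, 0].max(),
            coords[:, 1].min(), coords[:, 1].max(),
        )
    lat_min, lat_max, lon_min, lon_max = extent
    lats = np.linspace(lat_max, lat_min, rows)  # row 0 = north
    lons = np.linspace(lon_min, lon_max, cols)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    d = _great_circle_km(
        glat.ravel()[:, None], glon.ravel()[:, None],
        coords[None, :, 0], coords[None, :, 1],
    )
    out = np.empty((rows * cols, fit.K))
    exact = d < 1e-9
    w = 1.0 / np.maximum(d, 1e-9) ** power
    w /= w.sum(axis=1, keepdims=True)
    out = w @ fit.Q
    hit_rows, hit_samples = np.where(exact)
    out[hit_rows] = fit.Q[hit_samples]
    cell = (lon_max - lon_min) / max(cols - 1, 1) if cols > 1 else 1.0
    return [
        Raster(out[:, k].reshape(rows, cols), cell_size=cell or 1.0,
               x_origin=lon_min, y_origin=lat_min)
        for k in range(fit.K)
    ]
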