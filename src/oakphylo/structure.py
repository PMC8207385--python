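"""Hierarchical AMOVA, phylogeographic permutation tests, haplotype network.

AMOVA decomposes squared inter-gene-copy distances over a
region > location > copy hierarchy under either an identity (IAM, 0/1) or a
stepwise (SMM, squared size difference) distance model.  The companion
permutation tests compare distance-aware differentiation (NST for linked
haplotypes, RST for nuclear allele sizes) against nulls that destroy the
ordering information while preserving frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeTable, HaplotypeCatalog

__all__ = [
    "amova",
    "AmovaResult",
    "nst_test",
    "gst_nst_estimates",
    "rst_allele_size_test",
    "PhylogeoTest",
    "minimum_spanning_network",
    "HaplotypeNetwork",
]


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

def _copy_vectors(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand a table into per-gene-copy multilocus vectors.

    Diploid individuals contribute two copy vectors, with alleles sorted
    within each locus so pairing is deterministic.  Copies from individuals
    with any fully missing locus are dropped.  Returns
    ``(vectors (M, n_loci), individual_index (M,), location_index (M,))``.
    """
    complete = ~table.missing_mask().any(axis=1)
    sub = table.subset(np.flatnonzero(complete))
    loc_ids = np.asarray(sub.location_ids)
    locations = sub.locations
    loc_idx = np.array([locations.index(l) for l in loc_ids])
    a = np.sort(sub.alleles, axis=2)  # (n, L, ploidy)
    vecs = a.transpose(0, 2, 1).reshape(-1, sub.n_loci)  # copies grouped per individual
    ind = np.repeat(np.arange(sub.n_individuals), sub.ploidy)
    loc = np.repeat(loc_idx, sub.ploidy)
    return vecs, ind, loc


def squared_distance_matrix(
    vectors: np.ndarray, model: str, motif: float | np.ndarray = 1.0
) -> np.ndarray:
    """Pairwise squared distances between copy vectors.

    IAM: number of loci with different alleles (0/1 per locus).
    SMM: sum over loci of squared size differences in motif units.
    """
    v = np.asarray(vectors, dtype=float)
    if model.upper() == "IAM":
        d = (v[:, None, :] != v[None, :, :]).sum(axis=2).astype(float)
    elif model.upper() == "SMM":
        d = (((v[:, None, :] - v[None, :, :]) / motif) ** 2).sum(axis=2)
    else:
        raise ValueError("model must be 'IAM' or 'SMM'")
    return d


def _ssd(d2: np.ndarray, groups: np.ndarray) -> float:
    """Sum over groups of (1/n_g) * sum_{i<j in g} d2_ij."""
    total = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return total


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with Phi-statistics."""

    table: pd.DataFrame  # rows per level: df, SSD, variance, percent
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_values: dict[str, float] = field(default_factory=dict)
    model: str = "IAM"
    flags: list[str] = field(default_factory=list)

    @property
    def sigma(self) -> np.ndarray:
        return self.table["variance"].to_numpy()


def _decompose(
    d2: np.ndarray, loc: np.ndarray, reg_of_loc: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (df, ssd, sigma) for the design. Three entries when regions are
    present (among-regions, among-locations-within, within-locations), two
    otherwise."""
    N = d2.shape[0]
    P = np.unique(loc).size
    ssd_total = d2[np.triu_indices(N, 1)].sum() / N
    ssd_wp = _ssd(d2, loc)
    n_p = np.bincount(loc)

    if reg_of_loc is None:
        df = np.array([P - 1, N - P], dtype=float)
        ssd_ap = ssd_total - ssd_wp
        sigma_c = ssd_wp / df[1] if df[1] > 0 else 0.0
        n_prime = (N - np.sum(n_p**2) / N) / (P - 1)
        sigma_b = (ssd_ap / df[0] - sigma_c) / n_prime
        return df, np.array([ssd_ap, ssd_wp]), np.array([sigma_b, sigma_c])

    reg = reg_of_loc[loc]
    G = np.unique(reg).size
    ssd_wg = _ssd(d2, reg)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    df = np.array([G - 1, P - G, N - P], dtype=float)
    sigma_c = ssd_wp / df[2] if df[2] > 0 else 0.0

    N_g = np.bincount(reg)
    sum_np2_over_Ng = 0.0
    for g in np.unique(reg_of_loc):
        members = np.flatnonzero(reg_of_loc == g)
        sum_np2_over_Ng += np.sum(n_p[members] ** 2) / N_g[g]
    n1 = (N - sum_np2_over_Ng) / df[1] if df[1] > 0 else np.nan
    n2 = (sum_np2_over_Ng - np.sum(n_p**2) / N) / df[0]
    n3 = (N - np.sum(N_g**2) / N) / df[0]

    sigma_b = (ssd_ap / df[1] - sigma_c) / n1 if df[1] > 0 else 0.0
    sigma_a = (ssd_ag / df[0] - sigma_c - n2 * sigma_b) / n3
    return df, np.array([ssd_ag, ssd_ap, ssd_wp]), np.array([sigma_a, sigma_b, sigma_c])


def amova(
    table: GenotypeTable,
    model: str = "IAM",
    use_regions: bool = True,
    n_perm: int = 10_000,
    seed: int | None = None,
    motif: float | np.ndarray = 1.0,
) -> AmovaResult:
    """Hierarchical AMOVA on gene copies.

    Significance: copies of each individual move together.  Phi_ST p-value
    permutes individuals among locations (ignoring regions); Phi_SC permutes
    individuals among locations within their region; Phi_CT permutes whole
    locations among regions.
    """
    vecs, ind, loc = _copy_vectors(table)
    if np.unique(loc).size < 2:
        raise ValueError("AMOVA needs >= 2 locations")
    d2 = squared_distance_matrix(vecs, model, motif)

    locations = table.locations
    regions = table.regions
    reg_of_loc = None
    if use_regions and len(regions) > 1:
        reg_of_loc = np.array([regions.index(table.region_of(l)) for l in locations])

    flags: list[str] = []
    df, ssd, sigma = _decompose(d2, loc, reg_of_loc)
    total = sigma.sum()
    if total <= 0:
        flags.append("zero total variance; Phi undefined")
        phi_st = phi_sc = phi_ct = float("nan")
    elif reg_of_loc is None:
        phi_st = sigma[0] / total
        phi_sc = phi_ct = None
    else:
        phi_ct = sigma[0] / total
        phi_sc = sigma[1] / (sigma[1] + sigma[2]) if (sigma[1] + sigma[2]) != 0 else float("nan")
        phi_st = (sigma[0] + sigma[1]) / total
    if (sigma < 0).any():
        flags.append("negative variance component retained")

    levels = (
        ["among_locations", "within_locations"]
        if reg_of_loc is None
        else ["among_regions", "among_locations_within_regions", "within_locations"]
    )
    pct = 100.0 * sigma / total if total > 0 else np.full_like(sigma, np.nan)
    out = pd.DataFrame(
        {"df": df.astype(int), "SSD": ssd, "variance": sigma, "percent": pct},
        index=levels,
    )

    p_values: dict[str, float] = {}
    if n_perm > 0 and total > 0:
        rng = np.random.default_rng(seed)
        n_ind = int(ind.max()) + 1
        ind_loc = np.empty(n_ind, dtype=int)
        ind_loc[ind] = loc  # location of each individual

        def phi_from(loc_perm_ind: np.ndarray, regs) -> tuple[float, float | None, float | None]:
            lp = loc_perm_ind[ind]
            _, _, s = _decompose(d2, lp, regs)
            t = s.sum()
            if t <= 0:
                return np.nan, np.nan, np.nan
            if regs is None:
                return s[0] / t, None, None
            sc = s[1] / (s[1] + s[2]) if (s[1] + s[2]) != 0 else np.nan
            return (s[0] + s[1]) / t, sc, s[0] / t

        perm_st = np.empty(n_perm)
        for b in range(n_perm):
            perm_st[b] = phi_from(rng.permutation(ind_loc), reg_of_loc)[0]
        p_values["phi_st"] = (1 + np.nansum(perm_st >= phi_st - 1e-12)) / (1 + n_perm)

        if reg_of_loc is not None:
            # Phi_SC: permute individuals among locations within regions
            perm_sc = np.empty(n_perm)
            ind_reg = reg_of_loc[ind_loc]
            for b in range(n_perm):
                shuffled = ind_loc.copy()
                for g in np.unique(reg_of_loc):
                    members = np.flatnonzero(ind_reg == g)
                    shuffled[members] = shuffled[rng.permutation(members)]
                perm_sc[b] = phi_from(shuffled, reg_of_loc)[1]
            p_values["phi_sc"] = (1 + np.nansum(perm_sc >= (phi_sc or 0) - 1e-12)) / (1 + n_perm)

            # Phi_CT: permute whole locations among regions
            if len(locations) > len(regions):
                perm_ct = np.empty(n_perm)
                for b in range(n_perm):
                    r = reg_of_loc[rng.permutation(len(locations))]
                    perm_ct[b] = phi_from(ind_loc, r)[2]
                p_values["phi_ct"] = (1 + np.nansum(perm_ct >= (phi_ct or 0) - 1e-12)) / (1 + n_perm)
            else:
                flags.append("each region has a single location; Phi_CT test skipped")

    return AmovaResult(out, phi_st, phi_sc, phi_ct, p_values, model.upper(), flags)


# ----------------------------------------------------------------------
# NST / GST (Pons & Petit estimators, populations weighted equally)
# ----------------------------------------------------------------------

def gst_nst_estimates(counts: np.ndarray, D: np.ndarray) -> tuple[float, float]:
    """Return (GST, NST) from a (haplotype x location) count matrix.

    Uses the unbiased estimators with equal population weights and the
    harmonic-mean sample size; with a 0/1 distance matrix NST equals GST
    identically.
    """
    counts = np.asarray(counts, dtype=float)
    n_p = counts.sum(axis=0)
    keep = n_p >= 2
    counts = counts[:, keep]
    n_p = n_p[keep]
    P = counts.shape[1]
    if P < 2:
        raise ValueError("need >= 2 locations with >= 2 samples")
    x = counts / n_p  # frequencies per location
    ntilde = P / np.sum(1.0 / n_p)  # harmonic mean
    xbar = x.mean(axis=1)

    ones = 1.0 - np.eye(counts.shape[0])
    vs_plug = float(np.mean([x[:, p] @ D @ x[:, p] for p in range(P)]))
    hs_plug = float(np.mean([x[:, p] @ ones @ x[:, p] for p in range(P)]))
    vs = ntilde / (ntilde - 1.0) * vs_plug
    hs = ntilde / (ntilde - 1.0) * hs_plug
    vt = float(xbar @ D @ xbar) + vs / (ntilde * P)
    ht = float(xbar @ ones @ xbar) + hs / (ntilde * P)
    gst = (ht - hs) / ht if ht > 0 else float("nan")
    nst = (vt - vs) / vt if vt > 0 else float("nan")
    return gst, nst


@dataclass
class PhylogeoTest:
    observed: float
    permuted_mean: float
    permuted_sd: float
    companion: float  # GST (for NST) or FST-analog (for RST)
    p_value: float
    n_perm: int
    label: str = ""


def nst_test(
    catalog: HaplotypeCatalog, n_perm: int = 9_999, seed: int | None = None
) -> PhylogeoTest:
    """NST versus permuted NST (haplotype identities shuffled in D).

    A significant excess of the observed NST over its permutation
    distribution indicates phylogeographic structure; the permuted mean
    should approach GST.
    """
    counts = catalog.counts.to_numpy()
    if catalog.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    D = catalog.distances
    gst, nst = gst_nst_estimates(counts, D)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    k = catalog.n_haplotypes
    for b in range(n_perm):
        order = rng.permutation(k)
        perm[b] = gst_nst_estimates(counts, D[np.ix_(order, order)])[1]
    p = (1 + np.sum(perm >= nst - 1e-12)) / (1 + n_perm)
    return PhylogeoTest(nst, float(perm.mean()), float(perm.std(ddof=1)), gst, p, n_perm, "NST")


def rst_allele_size_test(
    table: GenotypeTable,
    n_perm: int = 9_999,
    seed: int | None = None,
    motif: float | np.ndarray = 1.0,
) -> PhylogeoTest:
    """RST versus permuted RST (allele sizes shuffled among allelic states).

    RST is the among-location Phi from the SMM AMOVA (locations only, no
    regions).  The null permutes, independently per locus, the mapping of
    observed sizes to allelic states, which preserves IAM information while
    destroying size ordering; the permuted mean approximates FST.
    """
    if len(table.locations) < 2:
        raise ValueError("need >= 2 locations")
    vecs, ind, loc = _copy_vectors(table)

    def phi_st(v: np.ndarray) -> float:
        d2 = squared_distance_matrix(v, "SMM", motif)
        _, _, s = _decompose(d2, loc, None)
        t = s.sum()
        return float(s[0] / t) if t > 0 else float("nan")

    obs = phi_st(vecs)
    d2_iam = squared_distance_matrix(vecs, "IAM")
    _, _, s = _decompose(d2_iam, loc, None)
    companion = float(s[0] / s.sum()) if s.sum() > 0 else float("nan")

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    L = vecs.shape[1]
    for b in range(n_perm):
        v = vecs.copy().astype(float)
        for j in range(L):
            sizes = np.unique(vecs[:, j])
            if sizes.size < 2:
                continue  # monomorphic locus: nothing to permute
            new = sizes[rng.permutation(sizes.size)]
            mapping = dict(zip(sizes.tolist(), new.tolist()))
            v[:, j] = [mapping[x] for x in vecs[:, j]]
        perm[b] = phi_st(v)
    p = (1 + np.nansum(perm >= obs - 1e-12)) / (1 + n_perm)
    return PhylogeoTest(
        obs, float(np.nanmean(perm)), float(np.nanstd(perm, ddof=1)), companion, p, n_perm, "RST"
    )


# ----------------------------------------------------------------------
# Minimum spanning network
# ----------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    nodes: pd.DataFrame  # haplotype id, frequency, n_locations
    edges: pd.DataFrame  # u, v, steps, is_tie
    has_ties: bool

    def to_edge_csv(self, path: str) -> None:
        self.edges.to_csv(path, index=False)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def minimum_spanning_network(catalog: HaplotypeCatalog) -> HaplotypeNetwork:
    """Kruskal with ties: all co-minimal edges joining (pre-level) distinct
    components are retained, so the result is a network containing every
    minimum spanning tree of the step-distance graph."""
    k = catalog.n_haplotypes
    if k < 2:
        raise ValueError("need >= 2 haplotypes")
    D = catalog.distances
    iu, ju = np.triu_indices(k, 1)
    order = np.lexsort((ju, iu, D[iu, ju]))
    edges_sorted = [(D[iu[e], ju[e]], int(iu[e]), int(ju[e])) for e in order]

    uf = _UnionFind(k)
    kept: list[tuple[int, int, float, bool]] = []
    has_ties = False
    i = 0
    while i < len(edges_sorted):
        w = edges_sorted[i][0]
        level = []
        while i < len(edges_sorted) and edges_sorted[i][0] == w:
            level.append(edges_sorted[i])
            i += 1
        snapshot = {v: uf.find(v) for v in range(k)}
        added = []
        for _, u, v in level:
            if snapshot[u] != snapshot[v]:
                added.append((u, v, w))
        # tie flag: more than one retained edge joins the same component pair
        pair_count: dict[tuple[int, int], int] = {}
        for u, v, _ in added:
            key = tuple(sorted((snapshot[u], snapshot[v])))
            pair_count[key] = pair_count.get(key, 0) + 1
        for u, v, wv in added:
            key = tuple(sorted((snapshot[u], snapshot[v])))
            tie = pair_count[key] > 1
            has_ties = has_ties or tie
            kept.append((u, v, wv, tie))
            uf.union(u, v)

    totals = catalog.total_counts
    n_locs = (catalog.counts.to_numpy() > 0).sum(axis=1)
    nodes = pd.DataFrame(
        {"haplotype": np.arange(k), "frequency": totals, "n_locations": n_locs}
    )
    edges = pd.DataFrame(kept, columns=["u", "v", "steps", "is_tie"])
    return HaplotypeNetwork(nodes, edges, has_ties)
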