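"""Within-location diversity statistics for haploid haplotypes and diploid loci.

Implements unbiased gene diversity on unordered alleles (``h``), its
distance-aware ordered counterpart (``v``), hypergeometric rarefaction of
allelic richness, and the standard per-location nuclear summaries (A, Ae,
Ap, Ho, uHe, AR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import MISSING, GenotypeTable, HaplotypeCatalog

__all__ = [
    "gene_diversity_h",
    "ordered_diversity_v",
    "rarefied_richness",
    "nuclear_summary",
    "haplotype_summary",
    "DiversitySummary",
]


def gene_diversity_h(counts) -> float:
    """Unbiased gene diversity ``h = n/(n-1) * (1 - sum p_i^2)``.

    Returns NaN when fewer than two gene copies are available.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def ordered_diversity_v(counts, distances) -> float:
    """Ordered (distance-weighted) diversity ``v = n/(n-1) * sum_ij p_i p_j d_ij``.

    ``distances`` must align with ``counts``; with a 0/1 distance matrix this
    reduces exactly to :func:`gene_diversity_h`.
    """
    counts = np.asarray(counts, dtype=float)
    D = np.asarray(distances, dtype=float)
    if D.shape != (counts.size, counts.size):
        raise ValueError("distance matrix does not align with counts")
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n / (n - 1.0) * (p @ D @ p))


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, g: int) -> float:
    """Expected number of distinct alleles in a random subsample of ``g`` copies.

    ``AR(g) = sum_i [1 - C(n - n_i, g) / C(n, g)]`` (hypergeometric
    expectation); requires ``g <= n``.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if g > n:
        raise ValueError(f"rarefaction size {g} exceeds sample size {int(n)}")
    rest = n - counts
    terms = np.where(
        rest < g, 1.0, 1.0 - np.exp(_log_comb(rest, g) - _log_comb(np.array(n), g))
    )
    return float(terms.sum())


@dataclass
class DiversitySummary:
    """Per-location diversity table plus unweighted means and standard errors."""

    per_location: pd.DataFrame
    means: pd.Series
    standard_errors: pd.Series
    rarefaction_g: int | None = None
    per_region: pd.DataFrame | None = None

    def to_csv(self, path: str) -> None:
        df = self.per_location.copy()
        df.loc["mean"] = self.means
        df.loc["SE"] = self.standard_errors
        df.to_csv(path)


def _locus_allele_counts(table: GenotypeTable, rows: np.ndarray, locus_j: int) -> dict[int, int]:
    vals = table.alleles[rows, locus_j, :].ravel()
    vals = vals[vals != MISSING]
    sizes, counts = np.unique(vals, return_counts=True)
    return dict(zip(sizes.tolist(), counts.tolist()))


def nuclear_summary(
    table: GenotypeTable, rarefaction_g: int | None = None
) -> DiversitySummary:
    """Per-location A, Ae, Ap, Ho, uHe and rarefied richness for diploid data.

    ``A``/``Ae``/``AR`` are means across loci; ``Ap`` counts alleles absent
    from every other location (summed over loci); ``Ho`` is the fraction of
    heterozygous complete genotypes; ``uHe = 2n/(2n-1) * (1 - sum p^2)``
    averaged across loci.  ``rarefaction_g`` defaults to the smallest number
    of complete gene copies at any (location, locus).
    """
    if table.ploidy != 2:
        raise ValueError("nuclear_summary needs a diploid table")
    locations = table.locations
    loc_rows = {loc: table.location_indices(loc) for loc in locations}

    # per (location, locus) allele counts
    counts: dict[str, list[dict[int, int]]] = {
        loc: [_locus_allele_counts(table, loc_rows[loc], j) for j in range(table.n_loci)]
        for loc in locations
    }
    if rarefaction_g is None:
        sizes = [
            sum(c.values())
            for loc in locations
            for c in counts[loc]
            if sum(c.values()) >= 2
        ]
        rarefaction_g = int(min(sizes)) if sizes else 2

    records = []
    for loc in locations:
        rows = loc_rows[loc]
        A, Ae, uHe, AR = [], [], [], []
        ap = 0
        ho_num = ho_den = 0
        for j in range(table.n_loci):
            c = counts[loc][j]
            n = sum(c.values())
            if n == 0:
                continue
            arr = np.array(list(c.values()), dtype=float)
            p = arr / n
            A.append(len(c))
            Ae.append(1.0 / np.sum(p**2))
            if n >= 2:
                uHe.append(n / (n - 1.0) * (1.0 - np.sum(p**2)))
            if n >= rarefaction_g:
                AR.append(rarefied_richness(arr, rarefaction_g))
            # private alleles: absent from all other locations at this locus
            others = set()
            for other in locations:
                if other != loc:
                    others.update(counts[other][j].keys())
            ap += sum(1 for a in c if a not in others)
            # observed heterozygosity over complete genotypes
            g = table.alleles[rows, j, :]
            complete = (g != MISSING).all(axis=1)
            ho_num += int((g[complete, 0] != g[complete, 1]).sum())
            ho_den += int(complete.sum())
        records.append(
            {
                "location": loc,
                "region": table.region_of(loc),
                "n": len(rows),
                "A": float(np.mean(A)) if A else np.nan,
                "Ae": float(np.mean(Ae)) if Ae else np.nan,
                "Ap": ap,
                "Ho": ho_num / ho_den if ho_den else np.nan,
                "uHe": float(np.mean(uHe)) if uHe else np.nan,
                "AR": float(np.mean(AR)) if AR else np.nan,
            }
        )
    per_location = pd.DataFrame.from_records(records).set_index("location")

    # region-level: pooled allele counts, private alleles at region level
    region_records = []
    regions = table.regions
    reg_counts: dict[str, list[dict[int, int]]] = {}
    for reg in regions:
        rows = np.flatnonzero(np.asarray(table.region_ids) == reg)
        reg_counts[reg] = [_locus_allele_counts(table, rows, j) for j in range(table.n_loci)]
    for reg in regions:
        A = [len(c) for c in reg_counts[reg] if c]
        ap = 0
        for j in range(table.n_loci):
            others = set()
            for other in regions:
                if other != reg:
                    others.update(reg_counts[other][j].keys())
            ap += sum(1 for a in reg_counts[reg][j] if a not in others)
        region_records.append(
            {"region": reg, "A": float(np.mean(A)) if A else np.nan, "Ap": ap}
        )
    per_region = pd.DataFrame.from_records(region_records).set_index("region")

    numeric = per_location[["A", "Ae", "Ap", "Ho", "uHe", "AR"]]
    means = numeric.mean()
    ses = numeric.std(ddof=1) / np.sqrt(numeric.notna().sum())
    return DiversitySummary(per_location, means, ses, rarefaction_g, per_region)


def haplotype_summary(
    catalog: HaplotypeCatalog, rarefaction_g: int | None = None
) -> DiversitySummary:
    """Per-location haplotype richness, rarefied richness, ``h`` and ``v``."""
    locations = list(catalog.counts.columns)
    ns = {loc: int(catalog.counts[loc].sum()) for loc in locations}
    if rarefaction_g is None:
        rarefaction_g = min(n for n in ns.values() if n >= 1)
    records = []
    for loc in locations:
        c = catalog.location_counts(loc)
        present = c > 0
        n = int(c.sum())
        records.append(
            {
                "location": loc,
                "n": n,
                "A": int(present.sum()),
                "AR": rarefied_richness(c, rarefaction_g) if n >= rarefaction_g else np.nan,
                "h": gene_diversity_h(c),
                "v": ordered_diversity_v(c, catalog.distances),
            }
        )
    per_location = pd.DataFrame.from_records(records).set_index("location")
    numeric = per_location[["A", "AR", "h", "v"]]
    means = numeric.mean()
    # the paper-style SE column for h/v is the dispersion across locations
    ses = numeric.std(ddof=1)
    return DiversitySummary(per_location, means, ses, rarefaction_g)
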