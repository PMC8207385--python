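"""Marker quality control for diploid microsatellite tables.

Per-locus/per-location Hardy-Weinberg and linkage permutation tests, an EM
estimator for null-allele frequency, inbreeding (FIS), and multilocus
Weir-Cockerham theta with an optional null-allele (ENA-style) correction and
a bootstrap-over-loci confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeTable

__all__ = [
    "hwe_permutation_test",
    "ld_permutation_test",
    "null_allele_em",
    "fst_weir_cockerham",
    "locus_qc_report",
    "LocusQCReport",
]

DEFAULT_PERMS = 9_999


def _perm_p(obs: float, perm: np.ndarray) -> float:
    """Add-one permutation p-value: never exactly zero."""
    return (1.0 + np.sum(perm >= obs - 1e-12)) / (1.0 + perm.size)


# ----------------------------------------------------------------------
# Hardy-Weinberg
# ----------------------------------------------------------------------

def _het_deficit(genos: np.ndarray) -> float:
    """uHe - Ho on an (n, 2) complete genotype array."""
    n = genos.shape[0]
    copies = genos.ravel()
    _, counts = np.unique(copies, return_counts=True)
    p = counts / copies.size
    uhe = copies.size / (copies.size - 1.0) * (1.0 - np.sum(p**2))
    ho = np.mean(genos[:, 0] != genos[:, 1])
    return float(uhe - ho)


def hwe_permutation_test(
    genotypes: np.ndarray, n_perm: int = DEFAULT_PERMS, seed: int | None = None
) -> tuple[float, bool]:
    """One-sided permutation test for heterozygote deficit.

    ``genotypes`` is an (n, 2) array of allele sizes for one locus in one
    location (missing rows removed by the caller or filtered here).  The
    statistic is ``uHe - Ho``; the null is built by shuffling gene copies
    among individuals.  Returns ``(p, monomorphic_flag)``.
    """
    g = np.asarray(genotypes)
    g = g[(g != MISSING).all(axis=1)]
    if g.shape[0] < 2:
        raise ValueError("need >= 2 complete genotypes")
    if np.unique(g).size < 2:
        return 1.0, True
    obs = _het_deficit(g)
    rng = np.random.default_rng(seed)
    copies = g.ravel().copy()
    perm = np.empty(n_perm)
    for b in range(n_perm):
        rng.shuffle(copies)
        perm[b] = _het_deficit(copies.reshape(-1, 2))
    return _perm_p(obs, perm), False


# ----------------------------------------------------------------------
# Linkage disequilibrium
# ----------------------------------------------------------------------

def _geno_codes(genos: np.ndarray) -> np.ndarray:
    """Map unordered genotypes (n, 2) to integer codes."""
    s = np.sort(genos, axis=1)
    _, codes = np.unique(s, axis=0, return_inverse=True)
    return codes


def _g_statistic(a: np.ndarray, b: np.ndarray) -> float:
    tab = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(tab, (a, b), 1.0)
    n = tab.sum()
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    mask = tab > 0
    return float(2.0 * np.sum(tab[mask] * np.log(tab[mask] / exp[mask])))


def ld_permutation_test(
    genos_a: np.ndarray,
    genos_b: np.ndarray,
    n_perm: int = DEFAULT_PERMS,
    seed: int | None = None,
) -> tuple[float, bool]:
    """G-test of independence between two loci's genotype classes.

    The null is built by permuting one locus's genotypes among individuals.
    Returns ``(p, degenerate_flag)``; a table with a single genotype class at
    either locus is degenerate (p = 1).
    """
    a = np.asarray(genos_a)
    b = np.asarray(genos_b)
    ok = (a != MISSING).all(axis=1) & (b != MISSING).all(axis=1)
    a, b = a[ok], b[ok]
    if a.shape[0] < 5:
        raise ValueError("need >= 5 individuals typed at both loci")
    ca, cb = _geno_codes(a), _geno_codes(b)
    if np.unique(ca).size < 2 or np.unique(cb).size < 2:
        return 1.0, True
    obs = _g_statistic(ca, cb)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    shuffled = cb.copy()
    for i in range(n_perm):
        rng.shuffle(shuffled)
        perm[i] = _g_statistic(ca, shuffled)
    return _perm_p(obs, perm), False


# ----------------------------------------------------------------------
# Null alleles
# ----------------------------------------------------------------------

def null_allele_em(
    genotypes: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000
) -> tuple[float, bool]:
    """EM estimate of the null-allele frequency at one diploid locus.

    Observed apparent homozygotes ``ii`` are modelled as a mixture of true
    homozygotes (prob ``p_i^2``) and null heterozygotes (``2 p_i r``) under
    HWE; null homozygotes are unobservable, so visible-genotype
    probabilities are renormalized by ``1 - r^2``.  Returns
    ``(r_hat, converged)``.
    """
    g = np.asarray(genotypes)
    g = g[(g != MISSING).all(axis=1)]
    if g.shape[0] < 1:
        raise ValueError("no complete genotypes")
    alleles, inv = np.unique(g, return_inverse=True)
    inv = inv.reshape(g.shape)
    k = alleles.size
    hom = inv[:, 0] == inv[:, 1]
    n_hom = np.bincount(inv[hom, 0], minlength=k).astype(float)
    # heterozygote allele tallies
    n_het_allele = (
        np.bincount(inv[~hom].ravel(), minlength=k).astype(float)
    )
    n_obs = g.shape[0]

    p = np.bincount(inv.ravel(), minlength=k).astype(float)
    p /= p.sum()
    r = 0.05
    converged = False
    for _ in range(max_iter):
        # E-step: split each apparent homozygote class between true hom / null
        # het, and impute the expected count of unobservable null homozygotes
        denom = p**2 + 2.0 * p * r
        w_null = np.where(denom > 0, (2.0 * p * r) / np.maximum(denom, 1e-300), 0.0)
        e_null_hom = n_obs * r**2 / max(1.0 - r**2, 1e-12)
        exp_null_copies = float(np.sum(n_hom * w_null)) + 2.0 * e_null_hom
        # copies of visible allele i: 2*true_hom + 1*null_het + het occurrences
        copies_i = 2.0 * n_hom * (1.0 - w_null) + n_hom * w_null + n_het_allele
        total = 2.0 * (n_obs + e_null_hom)
        new_r = exp_null_copies / total
        new_p = copies_i / total
        delta = max(abs(new_r - r), float(np.max(np.abs(new_p - p))))
        p, r = new_p, new_r
        if delta < tol:
            converged = True
            break
    return float(r), converged


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

def _wc_components(table: GenotypeTable, locus_j: int, ena: bool) -> tuple[float, float]:
    """Return (numerator a, denominator a+b+c) summed over alleles at one locus."""
    locations = table.locations
    pops = []
    for loc in locations:
        rows = table.location_indices(loc)
        g = table.alleles[rows, locus_j, :]
        g = g[(g != MISSING).all(axis=1)]
        if g.shape[0] >= 1:
            pops.append(g)
    r = len(pops)
    if r < 2:
        return 0.0, 0.0
    all_alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    if all_alleles.size < 2:
        return 0.0, 0.0

    n_i = np.array([g.shape[0] for g in pops], dtype=float)
    nbar = n_i.mean()
    nc = (n_i.sum() - np.sum(n_i**2) / n_i.sum()) / (r - 1)

    # allele frequencies and observed het proportions per pop
    freqs = np.zeros((r, all_alleles.size))
    hets = np.zeros((r, all_alleles.size))
    null_r = np.zeros(r)
    for i, g in enumerate(pops):
        if ena:
            null_r[i], _ = null_allele_em(g)
        for a_idx, a in enumerate(all_alleles):
            match = g == a
            freqs[i, a_idx] = match.sum() / (2.0 * g.shape[0])
            hets[i, a_idx] = np.mean(match.sum(axis=1) == 1)
    if ena:
        # shrink visible frequencies by (1 - r_hat); the null state becomes an
        # extra shared allele; heterozygosity replaced by its HWE expectation
        freqs = freqs * (1.0 - null_r[:, None])
        freqs = np.column_stack([freqs, null_r])
        hets = 2.0 * freqs * (1.0 - freqs)

    num = den = 0.0
    for a_idx in range(freqs.shape[1]):
        p_i = freqs[:, a_idx]
        h_i = hets[:, a_idx]
        pbar = np.sum(n_i * p_i) / n_i.sum()
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / n_i.sum()
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        num += a
        den += a + b + c
    return num, den


@dataclass
class FstResult:
    theta: float
    ci_low: float | None
    ci_high: float | None
    per_locus: dict[str, float]
    ena: bool


def fst_weir_cockerham(
    table: GenotypeTable,
    ena: bool = False,
    n_boot: int = 1_000,
    seed: int | None = None,
) -> FstResult:
    """Multilocus Weir-Cockerham theta with a bootstrap-over-loci CI.

    With ``ena=True`` per-location null-allele frequencies are estimated by
    EM and visible allele frequencies corrected before computing theta.
    """
    if len(table.locations) < 2:
        raise ValueError("theta needs >= 2 locations")
    nums, dens, per_locus = [], [], {}
    for j, locus in enumerate(table.loci):
        num, den = _wc_components(table, j, ena)
        nums.append(num)
        dens.append(den)
        per_locus[locus] = num / den if den > 0 else float("nan")
    nums_arr, dens_arr = np.array(nums), np.array(dens)
    theta = float(nums_arr.sum() / dens_arr.sum())

    ci_low = ci_high = None
    if n_boot > 0:
        if len(table.loci) < 2:
            pass  # CI unavailable with a single locus
        else:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, len(table.loci), size=(n_boot, len(table.loci)))
            with np.errstate(invalid="ignore", divide="ignore"):
                boot = nums_arr[idx].sum(axis=1) / dens_arr[idx].sum(axis=1)
            ci_low, ci_high = (float(q) for q in np.nanquantile(boot, [0.025, 0.975]))
    return FstResult(theta, ci_low, ci_high, per_locus, ena)


def fis_weir_cockerham(table: GenotypeTable) -> float:
    """Multilocus Weir-Cockerham FIS (f), pooled over loci and locations."""
    # FIS = 1 - Ho/He within locations, W&C small-sample form: use b, c terms
    num = den = 0.0
    for j in range(table.n_loci):
        for loc in table.locations:
            rows = table.location_indices(loc)
            g = table.alleles[rows, j, :]
            g = g[(g != MISSING).all(axis=1)]
            n = g.shape[0]
            if n < 2:
                continue
            copies = g.ravel()
            _, counts = np.unique(copies, return_counts=True)
            p = counts / copies.size
            he = copies.size / (copies.size - 1.0) * (1.0 - np.sum(p**2))
            ho = float(np.mean(g[:, 0] != g[:, 1]))
            num += n * (he - ho)
            den += n * he
    return float(num / den) if den > 0 else float("nan")


@dataclass
class LocusQCReport:
    """Collected QC outputs; see :func:`locus_qc_report`."""

    hwe: pd.DataFrame  # locus x location p-values
    null_freq: pd.Series  # per-locus EM r-hat
    fst: FstResult
    fst_ena: FstResult
    fis: float
    ld: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_csv(self, path: str) -> None:
        self.hwe.to_csv(path)


def locus_qc_report(
    table: GenotypeTable,
    n_perm: int = 999,
    n_boot: int = 1_000,
    seed: int | None = None,
    run_ld: bool = False,
) -> LocusQCReport:
    """Run the full QC battery on a diploid table."""
    rng = np.random.default_rng(seed)
    locations = table.locations
    hwe = pd.DataFrame(index=table.loci, columns=locations, dtype=float)
    for j, locus in enumerate(table.loci):
        for loc in locations:
            rows = table.location_indices(loc)
            g = table.alleles[rows, j, :]
            g = g[(g != MISSING).all(axis=1)]
            if g.shape[0] < 2:
                continue
            p, _ = hwe_permutation_test(g, n_perm=n_perm, seed=int(rng.integers(2**31)))
            hwe.loc[locus, loc] = p
    null_freq = pd.Series(
        {
            locus: null_allele_em(table.alleles[:, j, :])[0]
            for j, locus in enumerate(table.loci)
        }
    )
    ld = None
    if run_ld:
        recs = []
        for j1 in range(table.n_loci):
            for j2 in range(j1 + 1, table.n_loci):
                p, flag = ld_permutation_test(
                    table.alleles[:, j1, :],
                    table.alleles[:, j2, :],
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
                recs.append(
                    {"locus_a": table.loci[j1], "locus_b": table.loci[j2], "p": p, "degenerate": flag}
                )
        ld = pd.DataFrame.from_records(recs)
    fst_plain = fst_weir_cockerham(table, ena=False, n_boot=n_boot, seed=int(rng.integers(2**31)))
    fst_ena = fst_weir_cockerham(table, ena=True, n_boot=n_boot, seed=int(rng.integers(2**31)))
    return LocusQCReport(
        hwe=hwe,
        null_freq=null_freq,
        fst=fst_plain,
        fst_ena=fst_ena,
        fis=fis_weir_cockerham(table),
        ld=ld,
    )
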