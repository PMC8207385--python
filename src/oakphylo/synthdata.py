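"""Synthetic data generators with known truth for every pipeline stage.

Nuclear genotypes combine a coalescent stepwise-mutation ancestral allele
pool with Balding-Nichols per-deme frequency draws at a controllable FST;
chloroplast haplotypes are fully linked multilocus profiles drawn the same
way; landscapes are smoothed random DEMs with an elevation-band habitat
whose width grows across periods, so connectivity increases by design.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .abc_demography import Priors, ScenarioSpec, draw_scenario, simulate_coalescent_msat
from .genodata import GenotypeTable, SamplingDesign
from .raster import Raster

__all__ = ["simulate_dataset", "simulate_landscape", "SyntheticTruth"]


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and verify a synthetic dataset."""

    seed: int
    scenario_id: int
    scenario_params: dict[str, float]
    target_fst: float
    n_demes: int
    deme_sizes: list[int]
    regions: list[str]
    landscape: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _balding_nichols(p_anc: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw deme allele frequencies around an ancestral vector at a target FST."""
    if fst <= 0:
        return p_anc.copy()
    conc = (1.0 - fst) / fst
    alpha = np.maximum(p_anc * conc, 1e-6)
    return rng.dirichlet(alpha)


def _pool_frequencies(
    scenario: ScenarioSpec,
    n_loci: int,
    linked: bool,
    rng: np.random.Generator,
    priors: Priors,
    pool_copies: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an ancestral sample; return (distinct profiles, frequencies).

    For unlinked loci profiles are per-locus allele sizes stacked as columns
    of independent pools; for linked loci they are multilocus haplotypes.
    """
    mus = priors.draw_mu(rng, n_loci)
    sample = simulate_coalescent_msat(
        pool_copies, scenario, mus, n_loci, linked=linked, seed=int(rng.integers(2**31))
    )
    # keep sizes positive (high-theta walks can go below zero); every
    # downstream statistic is invariant to this per-locus translation
    sample = sample - sample.min(axis=1, keepdims=True) + 10
    if linked:
        profiles, counts = np.unique(sample.T, axis=0, return_counts=True)
        return profiles, counts / counts.sum()
    return sample, np.array([])


_REGION_NAMES = ["Occidental", "Central", "Oriental"]


def simulate_dataset(
    n_demes: int = 22,
    n_per_deme: tuple[int, int] = (5, 13),
    n_nssr: int = 10,
    n_cpssr: int = 9,
    scenario_id: int = 3,
    target_fst: float = 0.1,
    seed: int = 0,
    priors: Priors | None = None,
) -> tuple[GenotypeTable, GenotypeTable, SamplingDesign, SyntheticTruth]:
    """Generate paired nuclear (diploid) and chloroplast (haploid) tables.

    Returns ``(nuclear, chloroplast, design, truth)``.  Demes are placed on
    three linear "cordilleras"; deme sizes are uniform on ``n_per_deme``.
    """
    if not 0 <= target_fst < 1:
        raise ValueError("target_fst must be in [0, 1)")
    priors = priors or Priors()
    rng = np.random.default_rng(seed)
    scenario = draw_scenario(scenario_id, priors, rng)
    sizes = rng.integers(n_per_deme[0], n_per_deme[1] + 1, size=n_demes)

    # geography: three parallel north-south chains
    region_idx = np.arange(n_demes) % 3
    regions = [_REGION_NAMES[i] for i in region_idx]
    lats = 1.0 + 7.0 * (np.arange(n_demes) // 3) / max((n_demes - 1) // 3, 1)
    lats = lats + rng.normal(0, 0.15, n_demes)
    lons = -77.0 + 1.8 * region_idx + rng.normal(0, 0.1, n_demes)

    # --- nuclear loci: per-locus ancestral pools + Balding-Nichols demes ---
    pool, _ = _pool_frequencies(scenario, n_nssr, linked=False, rng=rng, priors=priors)
    nuc_alleles = np.empty((int(sizes.sum()), n_nssr, 2), dtype=np.int64)
    row = 0
    deme_freqs: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for d in range(n_demes):
        per_locus = []
        for j in range(n_nssr):
            states, counts = np.unique(pool[j], return_counts=True)
            p = _balding_nichols(counts / counts.sum(), target_fst, rng)
            per_locus.append((states, p))
        deme_freqs.append(per_locus)
    for d in range(n_demes):
        for i in range(sizes[d]):
            for j in range(n_nssr):
                states, p = deme_freqs[d][j]
                nuc_alleles[row, j, :] = rng.choice(states, size=2, p=p)
            row += 1

    # --- chloroplast: one linked haplotype system ---
    cp_profiles, cp_freq = _pool_frequencies(scenario, n_cpssr, linked=True, rng=rng, priors=priors)
    cp_alleles = np.empty((int(sizes.sum()), n_cpssr, 1), dtype=np.int64)
    row = 0
    for d in range(n_demes):
        p = _balding_nichols(cp_freq, target_fst, rng)
        picks = rng.choice(cp_profiles.shape[0], size=sizes[d], p=p)
        cp_alleles[row:row + sizes[d], :, 0] = cp_profiles[picks]
        row += sizes[d]

    loc_ids = [f"loc{d + 1:02d}" for d in range(n_demes)]
    ind_loc = np.repeat(np.arange(n_demes), sizes)
    individuals = [f"ind{r + 1:04d}" for r in range(int(sizes.sum()))]
    locations = [loc_ids[d] for d in ind_loc]
    region_list = [regions[d] for d in ind_loc]
    coords = np.column_stack([lats[ind_loc], lons[ind_loc]])

    common = dict(
        individual_ids=individuals,
        location_ids=locations,
        region_ids=region_list,
        coordinates=coords,
    )
    nuclear = GenotypeTable(
        loci=[f"nssr{j + 1:02d}" for j in range(n_nssr)],
        alleles=nuc_alleles, ploidy=2, **common,
    )
    chloroplast = GenotypeTable(
        loci=[f"cpssr{j + 1:02d}" for j in range(n_cpssr)],
        alleles=cp_alleles, ploidy=1, **common,
    )
    design = SamplingDesign(loc_ids, lats, lons, regions, sizes)
    truth = SyntheticTruth(
        seed=seed,
        scenario_id=scenario_id,
        scenario_params=scenario.param_dict,
        target_fst=target_fst,
        n_demes=n_demes,
        deme_sizes=[int(s) for s in sizes],
        regions=regions,
    )
    return nuclear, chloroplast, design, truth


def simulate_landscape(
    rows: int = 60,
    cols: int = 60,
    n_periods: int = 3,
    growth_factor: float = 1.6,
    seed: int = 0,
    cell_size: float = 1.0,
) -> tuple[Raster, list[Raster], dict]:
    """Generate a DEM and per-period 0-1 suitability rasters.

    The DEM is a smoothed random field plus a central ridge; suitability is
    a Gaussian band around a mid-elevation optimum whose width is multiplied
    by ``growth_factor`` each period, so with ``growth_factor > 1`` the
    habitat cell count grows strictly across periods.
    """
    if rows < 20 or cols < 20:
        raise ValueError("landscape must be at least 20 x 20")
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.normal(size=(rows, cols)), sigma=4.0)
    cc = np.arange(cols)
    ridge = np.exp(-((cc - cols / 2.0) / (cols / 5.0)) ** 2)
    dem_vals = 500.0 + 2500.0 * (0.55 * ridge[None, :] + 0.45 * (noise - noise.min()) / np.ptp(noise))
    dem = Raster(dem_vals, cell_size=cell_size)

    z_opt = float(np.quantile(dem_vals, 0.65))
    base_width = 180.0
    suits = []
    widths = []
    for p in range(n_periods):
        width = base_width * growth_factor**p
        widths.append(width)
        s = np.exp(-(((dem_vals - z_opt) / width) ** 2))
        suits.append(Raster(s, cell_size=cell_size))
    truth = {
        "seed": seed,
        "z_opt": z_opt,
        "band_widths": widths,
        "growth_factor": growth_factor,
    }
    return dem, suits, truth
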