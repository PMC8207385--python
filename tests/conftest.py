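import numpy as np
import pandas as pd
import pytest

from oakphylo.genodata import MISSING, GenotypeTable, HaplotypeCatalog


@pytest.fixture
def toy_diploid() -> GenotypeTable:
    """3 individuals, 2 loci, 2 locations."""
    alleles = np.array(
        [
            [[100, 102], [200, 200]],
            [[100, 100], [200, 202]],
            [[102, 104], [202, 202]],
        ],
        dtype=np.int64,
    )
    return GenotypeTable(
        individual_ids=["i1", "i2", "i3"],
        location_ids=["A", "A", "B"],
        region_ids=["R1", "R1", "R2"],
        loci=["L1", "L2"],
        alleles=alleles,
        ploidy=2,
    )


@pytest.fixture
def toy_haploid() -> GenotypeTable:
    alleles = np.array(
        [[[10], [20]], [[10], [20]], [[11], [22]], [[12], [20]]], dtype=np.int64
    )
    return GenotypeTable(
        individual_ids=["c1", "c2", "c3", "c4"],
        location_ids=["A", "A", "B", "B"],
        region_ids=["R", "R", "R", "R"],
        loci=["cp1", "cp2"],
        alleles=alleles,
        ploidy=1,
    )


def make_catalog(haps, counts, locations=None) -> HaplotypeCatalog:
    """Catalog from explicit multilocus vectors and per-location counts."""
    haps = np.asarray(haps, dtype=np.int64)
    counts = np.asarray(counts, dtype=int)
    if counts.ndim == 1:
        counts = counts[:, None]
    locations = locations or [f"p{j}" for j in range(counts.shape[1])]
    D = np.abs(haps[:, None, :] - haps[None, :, :]).sum(axis=2).astype(float)
    return HaplotypeCatalog(
        haplotypes=haps,
        loci=[f"l{i}" for i in range(haps.shape[1])],
        counts=pd.DataFrame(counts, columns=locations),
        distances=D,
    )


@pytest.fixture(scope="session")
def synthetic_pair():
    """A moderate synthetic nuclear + chloroplast dataset (session-scoped)."""
    from oakphylo.synthdata import simulate_dataset

    return simulate_dataset(
        n_demes=8, n_per_deme=(6, 10), n_nssr=6, n_cpssr=5,
        scenario_id=1, target_fst=0.12, seed=42,
    )
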