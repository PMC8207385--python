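"""Genotype tables, sampling designs, and chloroplast haplotype catalogs.

The central container is :class:`GenotypeTable`: an individuals x loci matrix
of allele sizes (two columns per locus for diploid data, one for haploid),
with each individual assigned to a sampling location and each location to a
region.  Missing allele calls are stored as :data:`MISSING` and skipped (with
renormalized denominators) by every downstream statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved sentinel for a missing allele copy.  Input files may encode
#: missing data as 0, empty fields, "NA" or negative numbers; the readers
#: normalize all of those to this value.
MISSING: int = -9

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SamplingDesign",
    "HaplotypeCatalog",
    "read_genotype_table",
    "write_genotype_table",
    "filter_missing",
    "bin_alleles",
    "extract_haplotypes",
]


class GenotypeParseError(ValueError):
    """Raised when an input file cannot be interpreted as a genotype table."""


@dataclass
class SamplingDesign:
    """Per-location metadata: coordinates, region and sample size."""

    location_ids: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    region_ids: list[str]
    n_individuals: np.ndarray

    def __post_init__(self) -> None:
        if len(self.location_ids) < 1:
            raise ValueError("a sampling design needs at least one location")
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        self.n_individuals = np.asarray(self.n_individuals, dtype=int)
        if not (np.isfinite(self.latitude).all() and np.isfinite(self.longitude).all()):
            raise ValueError("coordinates must be finite")

    def coords(self) -> np.ndarray:
        """(n_locations, 2) array of (lat, lon)."""
        return np.column_stack([self.latitude, self.longitude])


@dataclass
class GenotypeTable:
    """Allele-size matrix with a sampling hierarchy.

    Parameters
    ----------
    individual_ids
        One id per row.
    location_ids
        Location assignment per individual.
    region_ids
        Region assignment per individual (must be a function of location).
    loci
        Locus names, in column order.
    alleles
        ``(n_individuals, n_loci, ploidy)`` integer array of allele sizes;
        missing copies hold :data:`MISSING`.
    ploidy
        1 (haploid, e.g. chloroplast) or 2 (diploid nuclear).
    coordinates
        Optional ``(n_individuals, 2)`` (lat, lon) array.
    """

    individual_ids: list[str]
    location_ids: list[str]
    region_ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    ploidy: int
    coordinates: np.ndarray | None = None
    motif_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n = len(self.individual_ids)
        if self.alleles.shape != (n, len(self.loci), self.ploidy):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"({n}, {len(self.loci)}, {self.ploidy})"
            )
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if len(self.location_ids) != n or len(self.region_ids) != n:
            raise ValueError("location/region assignments must match individuals")
        bad = (self.alleles <= 0) & (self.alleles != MISSING)
        if bad.any():
            raise ValueError("allele sizes must be positive or the missing sentinel")
        # every location maps to exactly one region
        loc2reg: dict[str, str] = {}
        for loc, reg in zip(self.location_ids, self.region_ids):
            if loc2reg.setdefault(loc, reg) != reg:
                raise ValueError(f"location {loc!r} assigned to multiple regions")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (n, 2):
                raise ValueError("coordinates must be (n_individuals, 2)")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locations(self) -> list[str]:
        """Distinct location ids, in order of first appearance."""
        return list(dict.fromkeys(self.location_ids))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.region_ids))

    def region_of(self, location: str) -> str:
        idx = self.location_ids.index(location)
        return self.region_ids[idx]

    def location_indices(self, location: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.location_ids) == location)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): locus entirely missing per individual."""
        return (self.alleles == MISSING).all(axis=2)

    def subset(self, row_idx: np.ndarray) -> "GenotypeTable":
        row_idx = np.asarray(row_idx)
        return GenotypeTable(
            individual_ids=[self.individual_ids[i] for i in row_idx],
            location_ids=[self.location_ids[i] for i in row_idx],
            region_ids=[self.region_ids[i] for i in row_idx],
            loci=list(self.loci),
            alleles=self.alleles[row_idx].copy(),
            ploidy=self.ploidy,
            coordinates=None if self.coordinates is None else self.coordinates[row_idx].copy(),
            motif_lengths=dict(self.motif_lengths),
        )

    def sampling_design(self) -> SamplingDesign:
        locs = self.locations
        lat, lon, regs, ns = [], [], [], []
        for loc in locs:
            idx = self.location_indices(loc)
            regs.append(self.region_ids[idx[0]])
            ns.append(len(idx))
            if self.coordinates is not None:
                lat.append(float(np.mean(self.coordinates[idx, 0])))
                lon.append(float(np.mean(self.coordinates[idx, 1])))
            else:
                lat.append(0.0)
                lon.append(0.0)
        return SamplingDesign(locs, np.array(lat), np.array(lon), regs, np.array(ns))


@dataclass
class HaplotypeCatalog:
    """Distinct multilocus haploid profiles with counts and step distances.

    ``distances[i, j]`` is the Manhattan distance between haplotype allele
    vectors in motif units (mononucleotide motifs: base pairs).
    """

    haplotypes: np.ndarray  # (n_haplotypes, n_loci) allele sizes
    loci: list[str]
    counts: pd.DataFrame  # index: haplotype id, columns: location ids
    distances: np.ndarray  # (n_haplotypes, n_haplotypes)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    @property
    def n_individuals(self) -> int:
        return int(self.total_counts.sum())

    def unique_haplotypes(self) -> np.ndarray:
        """Indices of haplotypes present in exactly one location."""
        present = (self.counts.to_numpy() > 0).sum(axis=1)
        return np.flatnonzero(present == 1)

    def location_counts(self, location: str) -> np.ndarray:
        return self.counts[location].to_numpy()

    def to_json(self, path: str) -> None:
        payload = {
            "loci": self.loci,
            "haplotypes": self.haplotypes.tolist(),
            "locations": list(self.counts.columns),
            "counts": self.counts.to_numpy().tolist(),
            "distances": self.distances.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "HaplotypeCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        counts = pd.DataFrame(
            np.asarray(payload["counts"], dtype=int),
            columns=payload["locations"],
        )
        return cls(
            haplotypes=np.asarray(payload["haplotypes"], dtype=np.int64),
            loci=list(payload["loci"]),
            counts=counts,
            distances=np.asarray(payload["distances"], dtype=float),
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_META_COLS = ("ind", "loc", "region", "lat", "lon")


def _normalize_allele(value) -> int:
    if value is None:
        return MISSING
    if isinstance(value, float) and np.isnan(value):
        return MISSING
    s = str(value).strip()
    if s in ("", "0", "NA", "na", "NaN", "-", "?"):
        return MISSING
    try:
        a = int(round(float(s)))
    except ValueError as exc:
        raise GenotypeParseError(f"unparseable allele {value!r}") from exc
    return a if a > 0 else MISSING


def read_genotype_table(path: str, format: str = "csv", ploidy: int = 2) -> GenotypeTable:
    """Read a genotype table from ``path``.

    CSV dialect: header ``ind,loc,region,lat,lon,<locus>_1,<locus>_2,...``
    (diploid) or ``ind,loc,region,lat,lon,<locus>,...`` (haploid); ``lat``
    and ``lon`` columns are optional.  Missing alleles may be coded as 0,
    empty, or NA.  A genepop-like dialect is also accepted.
    """
    if format == "csv":
        return _read_csv(path, ploidy)
    if format in ("genepop", "genepop-like"):
        return _read_genepop(path, ploidy)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: str, ploidy: int) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if not cols or cols[0] != "ind" or "loc" not in cols:
        raise GenotypeParseError("header must start with 'ind' and contain 'loc'")
    meta = [c for c in cols if c in _META_COLS]
    allele_cols = [c for c in cols if c not in _META_COLS]
    if ploidy == 2:
        loci: list[str] = []
        for c in allele_cols:
            if not (c.endswith("_1") or c.endswith("_2")):
                raise GenotypeParseError(
                    f"diploid column {c!r} must end in _1/_2"
                )
            base = c[:-2]
            if base not in loci:
                loci.append(base)
        expected = [f"{l}_{k}" for l in loci for k in (1, 2)]
        if sorted(expected) != sorted(allele_cols):
            raise GenotypeParseError("diploid table needs both _1 and _2 columns per locus")
    else:
        loci = allele_cols

    n = len(df)
    alleles = np.full((n, len(loci), ploidy), MISSING, dtype=np.int64)
    for j, locus in enumerate(loci):
        for k in range(ploidy):
            col = f"{locus}_{k + 1}" if ploidy == 2 else locus
            for i, v in enumerate(df[col].tolist()):
                try:
                    alleles[i, j, k] = _normalize_allele(v)
                except GenotypeParseError as exc:
                    raise GenotypeParseError(f"line {i + 2}: {exc}") from exc

    coords = None
    if "lat" in meta and "lon" in meta:
        coords = np.column_stack(
            [df["lat"].astype(float).to_numpy(), df["lon"].astype(float).to_numpy()]
        )
    regions = df["region"].tolist() if "region" in meta else df["loc"].tolist()
    return GenotypeTable(
        individual_ids=df["ind"].tolist(),
        location_ids=df["loc"].tolist(),
        region_ids=regions,
        loci=loci,
        alleles=alleles,
        ploidy=ploidy,
        coordinates=coords,
    )


def _read_genepop(path: str, ploidy: int) -> GenotypeTable:
    """Minimal genepop dialect: title line, locus names (one per line or
    comma-separated), POP separators, rows ``id , a1a2 a1a2 ...`` with 2 or 3
    digits per allele (000 = missing)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise GenotypeParseError("genepop file too short")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    inds, locs, rows = [], [], []
    pop_idx = 0
    for ln in body[i:]:
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in ln:
            raise GenotypeParseError(f"malformed genepop row: {ln!r}")
        name, geno = ln.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"row {name.strip()!r}: {len(fields)} genotypes for {len(loci)} loci"
            )
        row = np.full((len(loci), ploidy), MISSING, dtype=np.int64)
        for j, f in enumerate(fields):
            width = len(f) // ploidy
            for k in range(ploidy):
                a = int(f[k * width:(k + 1) * width])
                row[j, k] = a if a > 0 else MISSING
        inds.append(name.strip())
        locs.append(f"pop{pop_idx}")
        rows.append(row)
    return GenotypeTable(
        individual_ids=inds,
        location_ids=locs,
        region_ids=list(locs),
        loci=loci,
        alleles=np.stack(rows) if rows else np.empty((0, len(loci), ploidy), dtype=np.int64),
        ploidy=ploidy,
    )


def write_genotype_table(table: GenotypeTable, path: str) -> None:
    """Write the CSV dialect read by :func:`read_genotype_table` (round-trips)."""
    data: dict[str, list] = {
        "ind": table.individual_ids,
        "loc": table.location_ids,
        "region": table.region_ids,
    }
    if table.coordinates is not None:
        data["lat"] = table.coordinates[:, 0].tolist()
        data["lon"] = table.coordinates[:, 1].tolist()
    for j, locus in enumerate(table.loci):
        for k in range(table.ploidy):
            col = f"{locus}_{k + 1}" if table.ploidy == 2 else locus
            vals = table.alleles[:, j, k]
            data[col] = ["" if v == MISSING else int(v) for v in vals]
    pd.DataFrame(data).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def filter_missing(table: GenotypeTable, max_missing_loci: int) -> GenotypeTable:
    """Keep individuals with at most ``max_missing_loci`` fully missing loci."""
    if max_missing_loci < 0:
        raise ValueError("max_missing_loci must be >= 0")
    n_missing = table.missing_mask().sum(axis=1)
    keep = np.flatnonzero(n_missing <= max_missing_loci)
    return table.subset(keep)


def bin_alleles(
    raw_sizes: dict[str, np.ndarray],
    motif_length: int | dict[str, int] = 1,
    offset_grid: int = 20,
) -> dict[str, np.ndarray]:
    """Snap raw fragment sizes onto a per-locus motif lattice.

    For each locus an offset ``o`` on a grid of ``offset_grid`` candidates in
    ``[0, motif)`` is chosen to minimize the total absolute snapping error;
    ties resolve to the smallest offset.  Returns binned integer sizes.
    """
    out: dict[str, np.ndarray] = {}
    for locus, sizes in raw_sizes.items():
        motif = motif_length[locus] if isinstance(motif_length, dict) else motif_length
        if motif < 1:
            raise ValueError("motif_length must be >= 1")
        sizes = np.asarray(sizes, dtype=float)
        valid = sizes != MISSING
        best_offset, best_err = 0.0, np.inf
        for o in np.linspace(0.0, motif, offset_grid, endpoint=False):
            snapped = o + motif * np.round((sizes[valid] - o) / motif)
            err = float(np.abs(sizes[valid] - snapped).sum())
            if err < best_err - 1e-12:
                best_err, best_offset = err, float(o)
        snapped = best_offset + motif * np.round((sizes - best_offset) / motif)
        result = np.rint(snapped).astype(np.int64)
        result[~valid] = MISSING
        out[locus] = result
    return out


def extract_haplotypes(cp_table: GenotypeTable, motif_length: int | dict[str, int] = 1) -> HaplotypeCatalog:
    """Enumerate distinct multilocus haplotypes from a haploid table.

    Individuals with any missing locus are excluded (with a warning).  The
    pairwise distance matrix is the Manhattan step distance
    ``sum_l |size_i - size_j| / motif_l``.
    """
    if cp_table.ploidy != 1:
        raise ValueError("haplotype extraction needs a haploid table")
    complete = ~cp_table.missing_mask().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"excluding {n_dropped} individual(s) with missing loci from haplotypes",
            stacklevel=2,
        )
    table = cp_table.subset(np.flatnonzero(complete))
    profiles = table.alleles[:, :, 0]  # (n, n_loci)

    # stable first-appearance ordering of distinct profiles
    seen: dict[tuple, int] = {}
    assign = np.empty(table.n_individuals, dtype=int)
    for i, row in enumerate(map(tuple, profiles)):
        assign[i] = seen.setdefault(row, len(seen))
    haplotypes = np.array(list(seen.keys()), dtype=np.int64).reshape(len(seen), table.n_loci)

    locations = table.locations
    counts = np.zeros((len(seen), len(locations)), dtype=int)
    loc_index = {loc: j for j, loc in enumerate(locations)}
    for i, loc in enumerate(table.location_ids):
        counts[assign[i], loc_index[loc]] += 1

    motifs = np.array(
        [motif_length[l] if isinstance(motif_length, dict) else motif_length for l in table.loci],
        dtype=float,
    )
    diffs = np.abs(haplotypes[:, None, :] - haplotypes[None, :, :]) / motifs
    distances = diffs.sum(axis=2)

    return HaplotypeCatalog(
        haplotypes=haplotypes,
        loci=list(table.loci),
        counts=pd.DataFrame(counts, columns=locations),
        distances=distances,
    )
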