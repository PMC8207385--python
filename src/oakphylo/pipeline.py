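"""Pipeline orchestration: run the enabled stages from one validated config.

Each stage writes CSV/JSON outputs under its own subdirectory plus a
manifest (input hashes, seeds); a summary document collates the headline
numbers across stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import abc_demography as abc
from . import connectivity as conn
from . import diversity, genodata, quality, structure, synthdata
from .raster import read_ascii_grid, write_ascii_grid
from .spatial_ancestry import encode_genotypes, fit_ancestry, select_k

log = logging.getLogger("oakphylo")

STAGES = ("simulate", "qc", "diversity", "structure", "ancestry", "abc", "connectivity")


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    nuclear_path: str | None = None
    chloroplast_path: str | None = None
    dem_path: str | None = None
    suitability_paths: list[str] = field(default_factory=list)
    n_perm: int = 999
    abc_sims: int = 2_000
    abc_n_loci: int = 10
    abc_tolerance: float = 0.05
    abc_n_closest: int = 200
    ancestry_k_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    ancestry_replicates: int = 5
    ancestry_lambda: float = 1.0
    connectivity_threshold: float = 50.0
    cost_threshold: float = 100_000.0
    p_ref: float = 0.5
    d_ref: float = 1.0
    simulate_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            for stage, needs in (
                ("qc", self.nuclear_path),
                ("diversity", self.nuclear_path),
                ("structure", self.chloroplast_path),
            ):
                if stage in self.stages and needs is None:
                    raise ValueError(f"stage {stage!r} needs input paths or the simulate stage")
        if "connectivity" in self.stages and "simulate" not in self.stages:
            if self.dem_path is None or not self.suitability_paths:
                raise ValueError("connectivity stage needs dem_path and suitability_paths")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the summary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    manifest: dict = {"seed": config.seed, "inputs": {}, "stages": {}}
    rng = np.random.default_rng(config.seed)

    nuclear = chloroplast = None
    dem = None
    suitabilities: list = []

    for p in filter(None, [config.nuclear_path, config.chloroplast_path, config.dem_path]):
        manifest["inputs"][p] = _sha256(Path(p))
    for p in config.suitability_paths:
        manifest["inputs"][p] = _sha256(Path(p))

    if config.nuclear_path:
        nuclear = genodata.read_genotype_table(config.nuclear_path, ploidy=2)
        nuclear = genodata.filter_missing(nuclear, 1)
    if config.chloroplast_path:
        chloroplast = genodata.read_genotype_table(config.chloroplast_path, ploidy=1)
    if config.dem_path:
        dem = read_ascii_grid(config.dem_path)
        suitabilities = [read_ascii_grid(p) for p in config.suitability_paths]

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    def run_stage(name: str, fn) -> None:
        nonlocal summary
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception:
            log.exception("stage %s failed", name)
            raise RuntimeError(f"pipeline aborted in stage {name!r}") from None
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s: done in %.1fs", name, time.time() - t0)

    # ----------------------------------------------------------------
    if "simulate" in config.stages:
        def _simulate():
            nonlocal nuclear, chloroplast, dem, suitabilities
            d = stage_dir("simulate")
            kwargs = dict(config.simulate_kwargs)
            nuc, cp, design, truth = synthdata.simulate_dataset(
                seed=config.seed, **kwargs
            )
            nuclear, chloroplast = nuc, cp
            genodata.write_genotype_table(nuc, str(d / "nuclear.csv"))
            genodata.write_genotype_table(cp, str(d / "chloroplast.csv"))
            truth.to_json(str(d / "truth.json"))
            dem_r, suits, ltruth = synthdata.simulate_landscape(seed=config.seed)
            dem = dem_r
            suitabilities = suits
            write_ascii_grid(dem_r, str(d / "dem.asc"))
            for i, s in enumerate(suits):
                write_ascii_grid(s, str(d / f"suitability_p{i}.asc"))
            (d / "landscape_truth.json").write_text(json.dumps(ltruth, indent=1))
        run_stage("simulate", _simulate)

    if "qc" in config.stages and nuclear is not None:
        def _qc():
            d = stage_dir("qc")
            rep = quality.locus_qc_report(
                nuclear, n_perm=min(config.n_perm, 199),
                n_boot=200, seed=int(rng.integers(2**31)),
            )
            rep.hwe.to_csv(d / "hwe_pvalues.csv")
            rep.null_freq.to_csv(d / "null_allele_freq.csv")
            summary["stages"]["qc"] = {
                "fst": rep.fst.theta,
                "fst_ci": [rep.fst.ci_low, rep.fst.ci_high],
                "fst_ena": rep.fst_ena.theta,
                "fis": rep.fis,
            }
        run_stage("qc", _qc)

    if "diversity" in config.stages and nuclear is not None:
        def _diversity():
            d = stage_dir("diversity")
            nsum = diversity.nuclear_summary(nuclear)
            nsum.to_csv(str(d / "nuclear_diversity.csv"))
            entry = {"mean_uHe": float(nsum.means["uHe"]), "mean_Ho": float(nsum.means["Ho"])}
            if chloroplast is not None:
                catalog = genodata.extract_haplotypes(chloroplast)
                hsum = diversity.haplotype_summary(catalog)
                hsum.to_csv(str(d / "haplotype_diversity.csv"))
                catalog.to_json(str(d / "haplotype_catalog.json"))
                entry.update(
                    n_haplotypes=catalog.n_haplotypes,
                    n_unique=int(catalog.unique_haplotypes().size),
                    mean_h=float(hsum.means["h"]),
                    mean_v=float(hsum.means["v"]),
                )
            summary["stages"]["diversity"] = entry
        run_stage("diversity", _diversity)

    if "structure" in config.stages and (nuclear is not None or chloroplast is not None):
        def _structure():
            d = stage_dir("structure")
            entry: dict = {}
            if chloroplast is not None:
                catalog = genodata.extract_haplotypes(chloroplast)
                am_iam = structure.amova(
                    chloroplast, model="IAM", n_perm=config.n_perm,
                    seed=int(rng.integers(2**31)),
                )
                am_iam.table.to_csv(d / "amova_cp_iam.csv")
                nst = structure.nst_test(
                    catalog, n_perm=config.n_perm, seed=int(rng.integers(2**31))
                )
                net = structure.minimum_spanning_network(catalog)
                net.to_edge_csv(str(d / "haplotype_network_edges.csv"))
                entry.update(
                    cp_phi_st=am_iam.phi_st, nst=nst.observed, pnst=nst.permuted_mean,
                    nst_p=nst.p_value, gst=nst.companion,
                )
            if nuclear is not None:
                rst = structure.rst_allele_size_test(
                    nuclear, n_perm=min(config.n_perm, 199),
                    seed=int(rng.integers(2**31)),
                )
                am_n = structure.amova(
                    nuclear, model="IAM", n_perm=config.n_perm,
                    seed=int(rng.integers(2**31)),
                )
                am_n.table.to_csv(d / "amova_nssr_iam.csv")
                entry.update(
                    rst=rst.observed, prst=rst.permuted_mean, rst_p=rst.p_value,
                    nssr_phi_st=am_n.phi_st,
                    pct_within_locations=float(am_n.table["percent"].iloc[-1]),
                )
            summary["stages"]["structure"] = entry
        run_stage("structure", _structure)

    if "ancestry" in config.stages and nuclear is not None:
        def _ancestry():
            d = stage_dir("ancestry")
            X, cols = encode_genotypes(nuclear)
            coords = nuclear.coordinates
            if coords is None:
                raise ValueError("ancestry stage needs coordinates")
            curve = select_k(
                X, coords, config.ancestry_k_range,
                replicates=config.ancestry_replicates,
                lam=config.ancestry_lambda, seed=int(rng.integers(2**31)),
                column_groups=[c[0] for c in cols],
            )
            fit = fit_ancestry(
                X, coords, curve.chosen_k, lam=config.ancestry_lambda,
                seed=int(rng.integers(2**31)),
            )
            np.savetxt(d / "Q.csv", fit.Q, delimiter=",")
            curve.as_table().to_csv(d / "cross_validation.csv", index=False)
            summary["stages"]["ancestry"] = {
                "chosen_k": curve.chosen_k,
                "min_median_rmse": min(curve.medians.values()),
            }
        run_stage("ancestry", _ancestry)

    if "abc" in config.stages and nuclear is not None:
        def _abc():
            d = stage_dir("abc")
            vecs = nuclear.alleles[:, :, :]
            pooled = vecs.transpose(1, 0, 2).reshape(nuclear.n_loci, -1)
            pooled = np.array([
                row[row != genodata.MISSING] for row in pooled
            ], dtype=object)
            n_min = min(len(r) for r in pooled)
            sample = np.stack([r[:n_min] for r in pooled]).astype(np.int64)
            obs = abc.summary_stats(sample).values
            ref = abc.generate_reference_table(
                config.abc_sims, n_copies=n_min, n_loci=nuclear.n_loci,
                seed=int(rng.integers(2**31)),
            )
            ref.to_csv(d / "reference_table.csv", index=False)
            res = abc.abc_model_choice(
                ref, obs, tolerance=config.abc_tolerance,
                n_closest_direct=min(config.abc_n_closest, len(ref)),
                n_boot=100, seed=int(rng.integers(2**31)),
            )
            summary["stages"]["abc"] = {
                "best_scenario": res.best_scenario,
                "direct": res.direct_probabilities,
                "logistic": res.logistic_probabilities,
            }
        run_stage("abc", _abc)

    if "connectivity" in config.stages and dem is not None:
        def _connectivity():
            d = stage_dir("connectivity")
            rug = conn.tri(dem)
            breaks = conn.jenks_breaks(rug.masked()[np.isfinite(rug.masked())], k=10)
            tri_cls = conn.classify_by_breaks(rug, breaks)
            tri_suit = conn.tri_class_suitability(tri_cls, k=len(breaks) - 1)
            ecas = {}
            for i, suit in enumerate(suitabilities):
                clim = conn.rescale_suitability(suit, threshold=0.5)
                habitat = conn.combine_habitat(clim, tri_suit)
                patches = conn.extract_patches(habitat, config.connectivity_threshold)
                if patches.n_patches == 0:
                    ecas[f"period_{i}"] = 0.0
                    continue
                resistance = conn.resistance_from_habitat(habitat)
                dist = conn.least_cost_distances(resistance, patches, config.cost_threshold)
                result = conn.eca(patches, dist, config.p_ref, config.d_ref, period=str(i))
                patches.to_frame().to_csv(d / f"patches_p{i}.csv", index=False)
                np.savetxt(d / f"lcp_distances_p{i}.csv", dist, delimiter=",")
                ecas[f"period_{i}"] = result.eca
            elev = conn.area_by_elevation_bin(dem)
            elev.to_csv(d / "area_by_elevation.csv", index=False)
            summary["stages"]["connectivity"] = {"eca": ecas}
        run_stage("connectivity", _connectivity)

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
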