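# oakphylo

Microsatellite phylogeography toolkit. Implements a complete analysis
pipeline for diploid nuclear (nSSR) and haploid chloroplast (cpSSR)
microsatellite datasets sampled across a location/region hierarchy:

- **genodata** — genotype-table data model, CSV/genepop-like I/O, allele
  binning, haplotype extraction with step distances.
- **diversity** — unbiased gene diversity (h), ordered diversity (v),
  hypergeometric rarefaction (AR), per-location nuclear summaries
  (A, Ae, Ap, Ho, uHe).
- **quality** — HWE and linkage permutation tests, EM null-allele
  frequency, Weir–Cockerham FST (with null-allele-corrected variant and
  bootstrap CI), FIS.
- **structure** — hierarchical AMOVA under IAM/SMM distances with
  permutation tests, NST vs permuted NST, RST vs allele-size-permuted RST,
  minimum spanning haplotype network with retained ties.
- **spatial_ancestry** — geographically regularized ancestry-coefficient
  factorization with masked cross-validation choice of K and IDW
  interpolation onto rasters.
- **abc_demography** — numba-accelerated coalescent simulator for
  stepwise-mutation microsatellites (piecewise-constant Ne), DIYABC-style
  summary statistics, reference-table generation, scenario choice (direct
  rejection + multinomial logistic regression), local-linear parameter
  estimation, and pseudo-observed error rates.
- **connectivity** — occurrence thinning, raster variable selection, TRI,
  Fisher–Jenks natural breaks, suitability rescaling, habitat patch
  extraction, least-cost patch distances (Dijkstra on the resistance grid),
  and the equivalent connectivity area (ECA) index.
- **synthdata** — synthetic genotype datasets with controllable FST and
  demographic scenario, plus synthetic DEM/suitability rasters, so every
  stage is testable without downloads.
- **pipeline** / **cli** — YAML-configured orchestration with manifests and
  a consolidated summary.

## CLI

```bash
oakphylo simulate --seed 1 --n-demes 22 --target-fst 0.1 --out data/
oakphylo qc data/nuclear.csv --perms 999 --out out/qc
oakphylo diversity data/nuclear.csv --out out/diversity.csv
oakphylo structure data/chloroplast.csv --ploidy 1 --perms 9999 --out out/structure
oakphylo ancestry data/nuclear.csv --k-range 1:8 --out out/ancestry
oakphylo abc data/nuclear.csv --sims 100000 --out out/abc
oakphylo connectivity --dem data/dem.asc \
    --suitability data/suitability_p0.asc \
    --suitability data/suitability_p1.asc \
    --suitability data/suitability_p2.asc --out out/eca.json
oakphylo run --config config.yaml
```

A minimal `config.yaml` for a fully synthetic end-to-end run:

```yaml
output_dir: out
seed: 3
stages: [simulate, qc, diversity, structure, ancestry, abc, connectivity]
simulate_kwargs: {n_demes: 8, target_fst: 0.1}
```

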