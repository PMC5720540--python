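# namqtl

Joint-linkage association mapping toolkit for nested association mapping
(NAM) populations — multiple wild-donor families sharing one recurrent
parent, genotyped as wild-allele dosages (0/1/2) on a centimorgan map and
scored for an ordinal trait across years and replicates.

The package covers the full analysis chain plus a matched simulator:

- **`namqtl.nam_sim`** — synthetic BC1S3 NAM populations: founder
  polymorphism panels, meiosis with Poisson crossovers on the cM scale
  (Haldane, no interference), one backcross plus three selfing
  generations by single seed descent, and ordinal phenotypes driven by a
  QTL with donor-specific effect sizes (an allelic series) plus year,
  genotype-by-year and residual noise.
- **`namqtl.pheno`** — per-line BLUEs (fixed genotype + year, least
  squares), method-of-moments variance components from the balanced
  two-way ANOVA, broad-sense heritability on an entry-mean basis
  `h2 = s2_G / (s2_G + s2_GY/y + s2_R/(y*r))`, and between-year Pearson
  correlation.
- **`namqtl.gwas`** — SNP QC (family polymorphism, <10% missing, <12.5%
  heterozygosity), stepwise forward-backward cofactor selection
  minimizing the Schwarz Bayesian Criterion, per-SNP nested-model F
  tests against the cofactor background, Bonferroni-Holm adjustment,
  allele-substitution effects (2×alpha), single-SNP R² and joint
  adjusted R².
- **`namqtl.crossval`** — prediction ability R²_val from repeated
  family-stratified 80/20 resampling (or strict 5-fold), rerunning
  selection and scan on training lines only.
- **`namqtl.qtl`** — greedy grouping of significant SNPs into QTL
  regions (peak-centred 26 cM windows) and donor-specific cumulated
  allele effects from identity-by-state polymorphism patterns.
- **`namqtl.io_cli`** — headered-TSV readers/writers, YAML pipeline
  configuration, and the `namqtl` command-line interface.

## Command line

Every stage is a subcommand; `run` chains them from one YAML config.

```sh
# simulate a NAM dataset (writes genotypes/map/phenotypes/families TSVs)
namqtl simulate --config sim.yaml --out data/ --seed 7

# heritability, variance components and BLUEs
namqtl h2 --phenotypes data/phenotypes.tsv --out pheno/

# cofactor selection + scan (+ QC and imputation)
namqtl gwas --geno data/genotypes.tsv --map data/map.tsv \
    --blues pheno/blues.tsv --families data/families.tsv \
    --out gwas/ --cofactor-window-cm 26

# QTL regions and donor-specific cumulated effects
namqtl cumulate --gwas gwas/gwas.tsv --map data/map.tsv \
    --founders data/founder_panel.tsv --window-cm 26 --out qtl/

# cross-validated prediction ability
namqtl crossval --geno data/genotypes.tsv --map data/map.tsv \
    --blues pheno/blues.tsv --families data/families.tsv \
    --runs 100 --seed 1 --out cv/

# everything at once
namqtl run --config pipeline.yaml
```

A `pipeline.yaml` holds the `PipelineConfig` fields (paths, QC
thresholds, alpha level, window, CV settings, seed); see
`namqtl.io_cli.PipelineConfig`.

All randomness flows from explicit seeds; reruns with the same seed and
inputs are byte-identical.

## File formats

Tab-separated with a header row; `#` lines carry run metadata and are
skipped on read.

| file | columns |
| --- | --- |
| genotypes | `line`, one column per SNP, values `0/1/2/NA` |
| map | `snp_id`, `chromosome`, `position_cm` |
| phenotypes | `line`, `year`, `replicate`, `score` |
| families | `line`, `family` (+ `carrier` when simulated) |
| founder panel | `family`, one 0/1 column per SNP |
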