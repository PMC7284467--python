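# dietomics

Diet-quality index scoring and proteome/metabolome-wide association scanning,
with a synthetic cohort generator for fully offline, reproducible testing.

The package implements an end-to-end analysis pipeline relating healthy
dietary pattern indices to high-dimensional molecular marker panels:

- **`diet_scoring`** — AHEI (0–110), DASH (8–40), and Mediterranean-style MDS
  (0–25) indices from food-group intake tables, built from declarative
  component specs (anchored-linear, cohort quintile/quartile rank, and
  moderate-alcohol-window scoring), plus the FFQ validity filter
  (<13 blank items, 600 ≤ kcal/day < 4000 for women / < 4200 for men) and
  index standardization.
- **`omics_preprocess`** — per-batch natural-log transform, age/sex OLS
  adjustment, and mean-0/SD-1 standardization for protein matrices;
  pass-through for metabolites; table alignment with a two-step exclusion
  cascade report (invalid diet, then missing covariates).
- **`association_scan`** — one OLS model per (index, marker) pair adjusted
  for age, sex, energy, smoking, physical activity, lipid and
  anti-hypertensive medication, and BMI; Benjamini–Hochberg q-values per
  (index, platform) family; Bonferroni flags at α/m per platform; cross-index
  overlap set summaries.
- **`correlation_structure`** — age/sex-adjusted partial Spearman correlation
  matrices (rank → residualize → Pearson) with an average-linkage display
  ordering.
- **`enrichment_ora`** — GMT parsing, pathway-size filtering ([5, 2000]),
  upper-tail hypergeometric over-representation with enrichment ratios
  (k/n)/(K/N) and BH q-values.
- **`annotation_overlap`** — local joins of significant markers to QTL
  variants and GWAS trait tables.
- **`synthetic_cohort`** — cohort generator with realistic intake/covariate
  marginals, two-batch protein matrices, and planted linear diet→marker
  effects on the standardized index scale, for parameter-recovery and
  calibration testing.
- **`cli_reporting`** — an eight-stage orchestrator with YAML configuration,
  per-stage derived seeds, and a hash-bearing run manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (score extrema,
exclusion cascade counts, FFQ boundary behavior, BH step-up oracle
equivalence, null calibration and parameter recovery of the scan,
hypergeometric enumeration checks, partial Spearman invariances).

## CLI

```bash
dietomics simulate --n 500 --seed 1 --out cohort/
dietomics score --index all --intakes cohort/intakes.tsv \
    --covariates cohort/covariates.tsv --out scores.tsv
dietomics scan --scores scores_std.tsv --markers cohort/metabolites.tsv \
    --covariates cohort/covariates.tsv --platform metabolite --out assoc.tsv
dietomics correlate --markers cohort/metabolites.tsv \
    --covariates cohort/covariates.tsv --out corr.tsv
dietomics enrich --selected sig.txt --gmt pathways.gmt --out enrich.tsv
dietomics overlap --sig sig.txt --qtl qtl.tsv --gwas gwas.tsv --out overlap.tsv
dietomics run --config run.yaml     # full eight-stage pipeline + manifest
```

A minimal `run.yaml`:

```yaml
out_dir: out/demo
seed: 1
n_participants: 500
n_proteins: 25
n_metabolites: 50
effect_entries:
  - [DASH, M0001, 0.4]
```

## Notes

- Numeric anchors for AHEI components and the moderate-alcohol windows are
  shipped defaults taken from the standard published index definitions; they
  are configuration, not ground truth, and every threshold (significance
  levels, FFQ validity bounds, pathway size limits) is overridable.
- Quantile ties fall to the lower bin; duplicate cut-points from
  zero-inflated intakes merge bins downward with a warning.
- All outputs are plain TSV/JSON; pipeline runs are bit-reproducible given
  the config seed.
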