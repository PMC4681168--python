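# methylclf

A tested, reusable pipeline for donor blood DNA-methylation analysis of a
binary clinical outcome ("severe" vs "no/mild"): from β-value matrices
through covariate- and cell-composition-adjusted differential methylation,
region calling, nested leave-one-out shrunken-centroid classification, and
qPCR (MethyLight) PMR replication. A first-class synthetic-data module
emulates the cohort structure the analysis assumes — six-cell-type mixtures,
slide-level batch effects, age/sex covariate effects, planted differential
positions, island-like probe clustering, and 4-fold qPCR dilution series —
with full ground truth, so every stage is verifiable at desk scale.

## Modules

| module                  | what it does |
|-------------------------|--------------|
| `methylclf.synthetic`   | cohorts, probe annotation, cell references, QC tables and qPCR plates with recoverable ground truth |
| `methylclf.preprocess`  | β = M/(M+U+100), the six probe filters, empirical-Bayes location/scale batch adjustment, classical MDS |
| `methylclf.cellcomp`    | reference-based leukocyte deconvolution (nonnegative least squares, no sum-to-one constraint) |
| `methylclf.dmp`         | per-CpG OLS with moderated t-statistics (trigamma-inversion prior), Bonferroni + \|Δβ\| ≥ 0.05 selection |
| `methylclf.dmr`         | probe-lasso region calling with Stouffer-combined, BH-adjusted region p-values |
| `methylclf.classify`    | nearest-shrunken-centroid classifier, nested LOOCV (feature selection inside every fold), pooled ROC/AUC with DeLong CI, recurrence ranking |
| `methylclf.methylight`  | qPCR standard curves, PMR quantification, closest-top-left ROC thresholds, Wilcoxon rank-sum tests |
| `methylclf.pipeline` / `methylclf.cli` | end-to-end discovery and replication arms with JSON+TSV report bundles |

## CLI

```sh
# generate a synthetic cohort (TSV/CSV/JSON) and a qPCR plate
methylclf simulate --config cohort.yaml --out data/ --plate

# discovery arm: filter -> batch adjust -> deconvolve -> DMP -> DMR -> LOOCV
methylclf discovery --inputs data/ --out results/discovery/

# replication arm: standard curve -> PMR -> rank-sum test -> threshold
methylclf replication --plate data/plate.csv --groups groups.csv \
    --out results/replication/
```

`simulate` accepts any `CohortConfig` field in its YAML (cohort shape,
planted effect sizes, batch structure, seed, ...). `discovery` accepts a YAML
with a `params` section (e.g. `alpha`, `min_abs_delta`, `detection_rule`,
stage toggles such as `dmr: false`). All runs are deterministic given the
seed; every report embeds the resolved configuration and SHA-256 hashes of
its inputs. Exit status is nonzero on any stage failure, with the failing
stage named.

## Conventions

- Genomic coordinates are 1-based (hg19-style) everywhere internally; BED
  exports are 0-based half-open.
- β matrices are probes × samples; estimated cell proportions are appended
  to the sample sheet as six separate covariates.
- Undetected qPCR wells are encoded as missing Ct values and excluded from
  group comparisons (reported as exclusions).
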