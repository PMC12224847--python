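# cmmnet

Network-based stratification of cardiometabolic multimorbidity (CMM): a
reusable pipeline from patient-level measurements to disease flags, a
thresholded cosine-similarity patient graph, multilevel-modularity (Louvain)
communities ("CMM patterns"), epidemiological characterization, a
multi-classifier benchmark, and multinomial odds-ratio models. A synthetic
cohort generator with planted subgroup structure stands in for survey data so
every stage is testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `cmmnet.cohort` | synthetic cohorts (`generate_cohort`), diagnostic rules (`flag_diseases`), inclusion filter (`filter_cmm`, ≥ 2 of 5 diseases), CSV/JSON I/O |
| `cmmnet.features` | standardized feature matrices: z-scored continuous variables, one-hot categoricals, train-only scaling for held-out projection |
| `cmmnet.network` | cosine similarity, thresholded graph construction, grid search over threshold ∈ [0.3, 0.7] × resolution ∈ [0.5, 1.5] maximizing modularity |
| `cmmnet.community` | from-scratch resolution-parameterized modularity, Louvain optimizer, exhaustive set-partition oracle (n ≤ 10), planted-partition benchmark graphs |
| `cmmnet.epi` | per-pattern prevalence, Pearson χ², one-way ANOVA (raw data or n/mean/SD summaries), Bonferroni pairwise t tests, rule-based pattern naming |
| `cmmnet.ml` | stratified 70/30 split, confusion-matrix metrics (macro/weighted/micro), six-family classifier benchmark, gradient-boosting feature importance |
| `cmmnet.odds` | univariable (or joint) multinomial logistic odds ratios vs a reference pattern, Wald 95% CIs, separation diagnostics |
| `cmmnet.pipeline` / `cmmnet.cli` | end-to-end orchestration with a hashed, timestamp-free run manifest |

## CLI

```bash
cmmnet simulate --n 2306 --seed 0 --out cohort.csv        # default 4-group template
cmmnet simulate --n 240 --planted --out planted.csv       # separable planted groups
cmmnet flag --cohort cohort.csv --out flags.json
cmmnet graph --cohort cohort.csv --threshold 0.5 --out-edges edges.tsv
cmmnet detect --cohort cohort.csv --thresholds 0.4,0.5,0.6 \
              --resolutions 0.8,1.0,1.2 --seed 0 --out-prefix run
cmmnet characterize --cohort cohort.csv --partition run_partition.tsv --out profile.json
cmmnet bench --cohort cohort.csv --partition run_partition.tsv --out bench.json
cmmnet odds --cohort cohort.csv --partition run_partition.tsv --reference 1 --out odds.csv
cmmnet all --n 300 --seed 0 --out-dir outdir                # full 9-stage pipeline
```

`cmmnet all` also accepts `--config config.yaml` (see
`cmmnet.pipeline.PipelineConfig`).

## Python quick start

```python
from cmmnet.cohort import planted_config, generate_cohort, filter_cmm
from cmmnet.features import build_feature_matrix
from cmmnet.network import grid_search
from cmmnet.epi import characterize

records = filter_cmm(generate_cohort(planted_config(240, seed=3)))
fm = build_feature_matrix(records)
result = grid_search(fm, thresholds=(0.4, 0.5, 0.6), resolutions=(0.8, 1.0, 1.2), seed=3)
labels = result.partition.labels_for(fm.row_ids)
profile = characterize(records, list(labels))
print(profile.names, result.modularity)
```

## Notes

- Diagnostic comparators follow the printed definitions exactly (e.g. SBP
  cutoff is strict `> 140`, total cholesterol is inclusive `>= 5.18`, HDL is
  strict `< 1.04`; the hyperuricemia cutoff is sex-specific).
- Graph adjacency for modularity is binary; a weighted variant is available
  via `weighted=True`. Grid cells are compared on Q evaluated at γ = 1; γ
  only shapes the Louvain objective (both values are reported).
- Disease flags are included as graph features by default and excluded from
  classifier features (label leakage); both are switchable.
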