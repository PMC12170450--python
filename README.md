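# lesionmap

A lesion-symptom mapping pipeline for neurosurgical cohorts: aphasia-battery
harmonization, mass-univariate (VLSM) and multivariate (SVR-MLSM)
lesion-symptom mapping with permutation correction, LSM-ROI construction via
cluster intersection, cohort classification, and relative-risk / odds-ratio
statistics. A synthetic-cohort generator with recoverable ground truth stands
in for non-public patient data.

## Modules

| Module | Purpose |
| --- | --- |
| `lesionmap.synthetic` | Ellipsoidal lesion masks on a 2 mm grid, behavior tables with a planted critical-region deficit, paired WAB/QAB assessments |
| `lesionmap.harmonization` | WAB/QAB subscores → shared 0–10 metrics (self-generated speech, overall, repetition, naming) |
| `lesionmap.univariate` | Per-voxel GLM t-maps, max-statistic FWER and cluster-extent permutation nulls, face-connected cluster extraction, subgroup reruns |
| `lesionmap.multivariate` | Nuisance residualization, dTLVC lesion scaling, epsilon-SVR weight maps with back-projection, permutation p-maps |
| `lesionmap.cohort` | Dice overlap, ROI intersection, 1.5-SD classification rules, 2×2 tables with RR (Katz CI) / OR (Woolf CI), chi-square and rank-sum tests, per-region damage |
| `lesionmap.pipeline` / `lesionmap.cli` | Declarative config, end-to-end orchestration, NIfTI/CSV/JSON I/O, logging |

## CLI

```bash
# generate a synthetic cohort with a planted critical region
lesionmap simulate --out-masks masks/ --out-behavior behavior.csv --n-subjects 60 --seed 1

# add harmonized metric columns
lesionmap harmonize behavior.csv --out harmonized.csv

# univariate and multivariate lesion-symptom mapping
lesionmap vlsm --masks masks/ --behavior behavior.csv --out vlsm/ --permutations 1000 --seed 1
lesionmap mlsm --masks masks/ --behavior behavior.csv --out mlsm/ --permutations 1000 --seed 1

# ROI intersection, classification, and 2x2 effect estimates
lesionmap cohort --vlsm-cluster vlsm/vlsm_cluster.nii.gz --mlsm-cluster mlsm/mlsm_cluster.nii.gz \
    --masks masks/ --behavior behavior.csv --out cohort/

# or the whole chain from one config file
lesionmap run config.json
```

Every stochastic verb takes `--seed`; identical seeds give bit-identical
outputs. World coordinates follow the NIfTI RAS-mm affine convention with
0-based voxel indices; masks are binarized at 0.5 on read.

## Conventions

- Harmonized scores live on a 0–10 scale, 0 most impaired.
- The behavior CSV schema is versioned via a `# lesionmap-behavior-v1`
  header; unknown columns are preserved, missing required columns are fatal.
- Excluded voxels carry NaN in written maps; the inclusion mask is written
  alongside.
- P-values follow the (B+1)-denominator convention for sampled permutations
  and exact counts under exhaustive enumeration (automatic for small n).
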