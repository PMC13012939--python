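# klsnet

Individual structural covariance networks from ROI-level morphometry via
Kullback–Leibler similarity (KLS), with graph-topology profiling across
sparsity thresholds, covariate-adjusted group statistics, and pairwise
MCI-subtype classification — exercisable end-to-end on a calibrated
synthetic cohort.

## What it does

1. **Synthetic cohort** (`klsnet.cohort`) — seeded three-group cohort
   (CN / EMCI / LMCI) with demographics, cognition and CSF/PET biomarkers
   calibrated to published group summaries; amyloid-positivity and
   education-stratified Logical-Memory-II labeling rules; per-subject,
   per-ROI morphometric sample vectors (GMV on the 116-region AAL
   parcellation; CT/SD/FD/GI on the 68-region Desikan–Killiany
   parcellation) with configurable group effects and an atrophy→cognition
   coupling.
2. **KLS networks** (`klsnet.network`, `klsnet.kde`) — per ROI, a
   Gaussian-kernel density on a subject-wide common grid (diffusion /
   Botev automatic bandwidth, Silverman fallback), epsilon-floored and
   renormalized; symmetric KL divergence between every ROI pair; similarity
   `exp(-d)`; one symmetric 116×116 or 68×68 matrix per subject with unit
   diagonal.
3. **Graph topology** (`klsnet.topology`) — sparsity thresholding
   (0.05–0.30 step 0.01; 0.07 start for 68-node networks), global metrics
   (Cp, Lp, Eg, Eloc), degree-preserving null ensembles for gamma / lambda /
   sigma, nodal degree / betweenness / efficiency / local efficiency, and
   AUC summaries across the sparsity range.
4. **Group statistics** (`klsnet.stats`) — ANCOVA (age, sex, education,
   APOE ε4, TIV for volume-derived outcomes) with Type III group F, partial
   η², Bonferroni post-hoc Cohen's d; Benjamini–Hochberg FDR; vectorized
   edgewise ANCOVA over all 6,670 (116-node) or 2,278 (68-node) edges;
   Pearson / partial correlations with cognition and biomarkers; a
   demographics summary table with ANOVA / Kruskal–Wallis / chi-square tests.
5. **Subtype classifier** (`klsnet.classify`) — leak-free nested stratified
   CV (10 outer × 5 inner by default): train-only covariate residualization,
   train-parameter min–max scaling, L1-logistic feature selection, L2 refit
   with inner-CV-tuned penalty; pooled out-of-fold ROC, Youden-optimal
   operating point, and a label-permutation AUC test.
6. **Pipeline + CLI** (`klsnet.pipeline`, `klsnet.cli`) — YAML-configured
   stages with per-stage seed substreams and a JSON manifest (config hash,
   artifact checksums).

## CLI

```bash
klsnet run-all --config examples/config.yaml --seed 1 --out pipeline_out
klsnet simulate --seed 1 --out pipeline_out     # single stages also available:
klsnet networks | topology | stats | classify
```

A minimal config:

```yaml
n_cn: 67
n_emci: 83
n_lmci: 58
metrics: [GMV, CT]
n_nulls: 100        # null networks per threshold (1000 at full scale)
n_permutations: 200 # permutation iterations (5000 at full scale)
seed: 1
```

Unknown keys are rejected. Outputs: `cohort.csv`,
`roi_samples_<metric>.tsv`, per-subject `<subject>_<metric>_<atlas>.klsm.tsv`
matrices, `topology_{global,nodal,auc}.csv`, `ancova_results.csv`,
`posthoc.csv`, `edges_stats.csv`, `correlations.csv`,
`classification_report.json`, `roc_points.csv`, and `manifest.json`.

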