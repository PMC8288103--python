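# intraconn

Within-region ("local") high-resolution structural connectome analysis for
temporal lobe epilepsy (TLE).

Most structural connectome studies compare the connections *between* brain
regions of a coarse parcellation (e.g. the 68 cortical areas of the
Desikan–Killiany atlas). `intraconn` instead analyzes the connectivity
*within* each region: every cortical surface triangle (~3.5 mm² at full
resolution, ~50,000 triangles per brain) is a network node, streamlines from
tractography connect the nearest triangle centers, and each region's
100–1,500 nodes form a small binary subnetwork whose topology can change
with disease even when the between-region network does not. The package is
aimed at researchers studying local connectivity biomarkers of epilepsy
duration and surgical outcome.

## What it computes

Given a labeled triangle mesh and a streamline set per subject:

1. **Connectome construction** — streamline endpoints are assigned to the
   nearest triangle center (Euclidean, ≤ 2 mm), tracts outside 10–300 mm are
   discarded, and counts between distinct centers form a sparse symmetric
   matrix with weights `c_ij / ((A_i + A_j)/2)` (area-normalized). Region
   level counts pass through a per-subject logistic map to give a weighted
   68-node-style network.
2. **Within-region graph metrics** — per region: surface area (SA), mean
   fiber length (FL), connectivity strength (S), edge density (d),
   characteristic path length (L), clustering coefficient (C), global and
   local efficiency (E_glob, E_loc) and small-worldness
   σ = (C/⟨C_null⟩)/(L/⟨L_null⟩), where the nulls are Maslov–Sneppen
   degree-preserving rewirings. L, C, E_glob, E_loc are reported normalized
   by the null means.
3. **Confound control** — age/sex and per-region surface-area effects are
   regressed out with control-only OLS models; metrics confounded by network
   size are screened with Spearman rank correlation.
4. **Group statistics** — two-sided permutation tests, Cohen's d per surgery
   side combined as the sample-size-weighted d = (n₁d₁ + n₂d₂)/(n₁ + n₂),
   Bonferroni correction, control-referenced z-scores, the per-patient
   abnormality distance Σ|z|, duration associations (Pearson/Spearman), and
   changed-region counts at effect-size thresholds.
5. **Outcome prediction** — per-feature and combined summed-|z| predictors
   of good (ILAE 1–2) vs bad (ILAE 3–5) surgical outcome under stratified
   5-fold cross-validation repeated 50 times, across six classifier families
   (tree, discriminant, logistic regression, SVM, k-NN, bagged ensemble).

Because patient MRI of this kind is not publicly shareable, the package
ships a first-class **synthetic cohort generator**: a spherical cortical
mesh partitioned into mirrored regions, noisy geometric within-region
graphs, and planted disease effects (short edges rewired into long ones,
recruiting more regions with longer disease duration, broader/stronger in
bad-outcome patients) whose ground truth is recorded for parameter-recovery
testing.

## Worked example

```python
from intraconn import (CohortConfig, MetricSettings, PipelineConfig,
                       analyze_cohort, generate_cohort)

cfg = PipelineConfig(seed=1, metrics=MetricSettings(n_nulls=50, seed=1),
                     n_perm=500, cv_repeats=20)
subjects, truth = generate_cohort(cfg.cohort, seed=1)   # 36 controls, 33 patients
analysis = analyze_cohort(subjects, truth, cfg)

a = analysis.duration["association"]
print(f"duration r={a.pearson_r:.3f} rho={a.spearman_rho:.3f}")
print(f"patient-control distance d={analysis.duration['patient_control_d']:.2f}")
for name, info in analysis.duration["group_counts"].items():
    print(name, info["n"], info["counts"])
hr = analysis.outcome["highres"]["result"]
lr = analysis.outcome["lowres"]["result"]
print(f"combined AUC: within-region {hr.auc_mean:.3f}, "
      f"between-region {lr.auc_mean:.3f}")
```

prints (seed 1):

```
duration r=0.907 rho=0.921
patient-control distance d=1.99
short 13 {0.5: 6, 1.2: 3}
long 20 {0.5: 10, 1.2: 6}
combined AUC: within-region 1.000, between-region 0.643
```

Reading: the per-patient abnormality distance (summed |z| over the planted
duration-related regions) correlates strongly with disease duration; the
long-duration (> 20 y) patient group shows more changed regions than the
short-duration group at both the medium (|d| > 0.5) and very-large
(|d| > 1.2) effect thresholds; and the combined within-region predictor
separates surgical outcomes far better than the between-region one — the
generator plants effects only inside regions, so the low-resolution network
carries almost no outcome signal by construction.

A command-line interface mirrors the stages
(`intraconn simulate-cohort | build-connectome | compute-metrics |
adjust-metrics | group-stats | predict-outcome | run-all`); see
`intraconn --help`.

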