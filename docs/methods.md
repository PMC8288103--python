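# Methods

This note documents the models, parameter choices and numerical decisions
behind `intraconn`, in the order the pipeline runs.

## Synthetic cohort model

The generator exists because individual patient diffusion MRI cannot be
shared; it emulates the *structure* of a within-region connectome study so
that every analysis stage can be validated against known ground truth. It
does **not** emulate anatomically realistic cortical geometry, diffusion
signal, or tractography failure modes — passing tests demonstrate that the
pipeline recovers effects of the planted kind at realistic effect-to-noise
ratios, not that it would behave identically on real tractography.

**Mesh.** A convex hull over a jittered Fibonacci lattice on the sphere
gives a closed triangulation with an exactly controlled face count
(2·n_points − 4). Vertices are scaled so the mean triangle area matches the
chosen resolution: 3.5 mm² (the "50k" full-resolution regime), 6.3 mm²
("25k") or 12.6 mm² ("12k", the default for desk-scale work). Triangles are
partitioned by farthest-point seeding into contiguous patches, seeds
mirrored across x = 0 so left region *j* pairs with right region *j + k*;
stray components are reassigned to neighbouring regions until every region
is edge-connected. The default cohort uses 16 regions × ~120 triangles.
Region sizes (~60–170 nodes) sit at the lower end of the 100–1,500-node
range of a real 68-region parcellation, which keeps a 69-subject cohort
analysis in the minutes range on one core.

**Healthy connectivity.** Within a region, triangle centers closer than
r = 1.8·√(mean area) are connected (a geometric random graph — locally
clustered, the phenotype the disease model degrades). Subject variability
comes from three sources chosen to give a realistic noise floor:
a per-subject surface-scale factor (SD 3 %), a per-subject radius jitter
(SD 4 %, coupling connection density to surface scale), and a per-(subject,
region) "long-range edge burden": geometric edges are kept with
probability 0.88 and a Poisson number of random long-range intra-region
edges is added at a fraction drawn from N(0.06, 0.05) (clipped ≥ 0) of the
region's edge count. The burden is drawn per region, not per subject, so
healthy variability is regionally independent; the summed abnormality
distance then averages noise across regions the way multi-region composite
scores do in practice. Inter-region streamlines (30 % of the total, i.e.
intra fraction 0.7) connect uniformly random cross-region triangle pairs.

**Streamlines.** Each edge is materialized as a three-point polyline whose
trajectory length is `10.5 + chord·(1 + U(0.05, 0.35))` mm, clipped into
(10, 300): monotone in the inter-center chord (so rewiring short edges into
long ones raises mean fiber length), always inside the tract-length filter,
and exactly realizable by displacing the midpoint perpendicular to the
chord.

**Disease model.** The planted effect rewires a fraction ("rate") of a
region's *shortest* intra-region edges into currently absent far-apart
pairs (above the 75th percentile of the region's pairwise distances),
conserving the intra-region edge count. This reproduces the target
phenotype: fewer short connections, more long connections, lower clustering
and local efficiency, higher mean fiber length.

Duration-related regions (6 ipsilateral by default) are recruited
progressively: region *j* has an onset spread evenly over 0–25 years, and
its rate is `0.005 + 0.005·(duration − onset)` once duration passes the
onset, plus N(0, 0.025) subject noise, clipped to [0, 1]. A purely linear
rate in duration cannot produce the "more regions affected with longer
duration" pattern at n = 33: all planted regions cross the effect-size
thresholds in both duration subgroups. Onset recruitment expresses
progressive regional involvement directly, keeps each region's planted rate
monotone in duration, and grades effect sizes from medium to huge.
Bad-outcome patients (ILAE 3–5) additionally receive a fixed rate of 0.10
in 4 contralateral regions. All planted rates are recorded per subject and
region in `EffectGroundTruth`.

These defaults were fixed by pilot calibration to land in the reported
effect regime of this kind of study — duration correlation r ≈ 0.7–0.9,
patient-vs-control distance Cohen's d ≈ 1.5–2, combined-predictor
AUC ≈ 0.95–1.0, per-region weighted d spanning ~0.5–3 — and then frozen.

**Demographics.** Group sizes, sex counts, surgery sides and outcome counts
are assigned exactly (36 controls 17 M/19 F; 19 left-surgery patients
7 M/12 F with 12 good/7 bad outcomes; 14 right 8 M/6 F with 9/5); ages and
durations are drawn from the published mean/SD (controls 39.06 ± 12.32 y,
patients 38.79 ± 12.79 y, duration 23.45 ± 15.03 y truncated at 1 y).
Outcome labels are assigned stratified over the sorted durations within
each side, matching the reported property that the 20-year duration split
carries balanced outcome and side distributions; independent shuffling
occasionally concentrates bad outcomes in one duration subgroup and
contaminates the duration contrast with outcome effects. Controls receive a
seeded, recorded pseudo-side for ipsi/contra relabeling, balanced L/R.

## Connectome construction

Endpoints map to the nearest triangle center (Euclidean), ties to the
lowest index, unassigned beyond 2 mm (a stand-in for the gray-matter
termination mask). Length bounds (10, 300) mm are strict. Weights divide
counts by the mean of the two endpoint triangle areas — symmetric, and
reducing to 1/area for equal areas. Streamlines whose endpoints map to one
node add no edge (no self-loops) but their lengths count toward the
region's fiber-length list, as do all intra-region streamlines. The
low-resolution weight map is `w(c) = 1/(1 + exp(−(log c − m)/s))` with m, s
the mean/SD of log counts over the subject's nonzero entries (w(0) = 0):
strictly increasing, bounded in [0, 1), per-subject normalized. Within-
region topology is analyzed *binary*; weights feed only the strength S.

## Graph metrics and null models

Definitions (binary, symmetric, zero diagonal): d = 2E/(N(N−1)); L = mean
shortest-path length over *connected* ordered pairs (NaN when none — this
keeps L finite as regions fragment, which efficiency handles natively);
C = mean Watts–Strogatz local clustering, degree < 2 contributing 0;
E_glob = mean of 1/d_ij over all ordered pairs with unreachable pairs
contributing 0; E_loc = mean over nodes of the global efficiency of the
node's neighbourhood subgraph. All five are validated to 1e−12 against
brute-force Floyd–Warshall/exhaustive-triangle oracles.

Nulls are Maslov–Sneppen double-edge swaps (default 10 swap attempts per
edge, 20× retry budget), preserving every degree exactly; rigid graphs
(e.g. complete graphs) return unchanged with a warning. Normalized metric =
observed / null mean; σ = (C/⟨C⟩_null)/(L/⟨L⟩_null). Edge density is
invariant under rewiring and is reported raw. The rewire-and-measure loop
is a single compiled (numba) kernel using a dense boolean adjacency for
membership, which bounds it to ~20k-node graphs — far above any
within-region subnetwork. Null counts are configurable; the package default
is 100 per within-region graph (50 for the low-resolution network), the
test-suite parameter-recovery sweep uses 10 and the acceptance script 30,
with the whole-brain high-resolution row reported raw (its all-pairs BFS
times any null count dominates runtime without informing the within-region
analysis).

Low-resolution nodal metrics are strength S_i = Σw_ij, nodal efficiency
with path costs 1/w, and Onnela geometric-mean weighted clustering with
weights scaled by the matrix maximum. The weighted null rewires the binary
topology and re-assigns the original weights by rank of the endpoint
strength product.

## Confound control

Age/sex models are ordinary least squares fitted on controls only (sex
coded F = 0, M = 1) and applied to everyone as
`corrected = observed − (predicted − control mean)`, preserving the control
grand mean so downstream z-scores stay interpretable. Surface-area
correction runs per region after the age/sex pass, using that region's SA
as covariate. Residualization is idempotent and leaves corrected control
values orthogonal to the covariates (both tested).

Network-size screening computes, per metric, the Spearman rank correlation
between node counts and metric values pooled over (control subject, region)
pairs, Bonferroni-corrected over the metrics screened (α = 0.05). The
pipeline applies the screen to *region-centered* values: the between-region
metric profile legitimately varies with region size (bigger geometric
graphs are relatively more clustered than their rewired nulls), but only
the within-region covariation of a subject's metric with its own network
size can confound the per-region group comparisons. On the pooled variant
every metric in the synthetic cohort correlates with size and the analysis
would be empty; both variants are exposed (`center_regions=`), and the
pooled variant carries the type-I calibration test.

## Group statistics

Permutation tests are two-sided on |mean difference| with the add-one
estimator p = (b + 1)/(n_perm + 1) (never exactly 0); default 1,000
permutations in the pipeline, 5,000 where the headline comparisons are
reported. Cohen's d uses the pooled (n−1) SD; side-specific effects combine
as (n₁d₁ + n₂d₂)/(n₁ + n₂). Effect bins at |d| ≥ 2.0/1.2/0.8/0.5/0.2/0.01
are labelled huge/very large/large/medium/small/very small, else
negligible. The Bonferroni family for region effects is all (region ×
retained metric) cells tested. The 2×2 chi-square is Pearson *without*
Yates continuity correction, which is what reproduces the published
demographics statistics; the side-by-gender cell of that table prints a
statistic inconsistent with its own p-value, and the package reports the
recomputed value (χ² = 1.340, p = 0.247).

Duration analysis splits patients at 20 years; each subgroup is compared
against an age/sex-matched control subset of equal size chosen greedily
(nearest age within sex, deterministic given the seed), so the two control
subsets overlap maximally. A region counts as "changed" at threshold t when
any retained metric has p < 0.05 and |weighted d| > t. The abnormality
distance is the per-subject Σ|z| over the duration-related regions and all
retained metrics, with controls scored against their own group statistics
(no leave-one-out; the resulting slight shrinkage of control distances is
shared by every control).

## Outcome prediction

Features are patient |z| values; the combined predictor sums |z| over the
features whose good/bad outcome groups differ (permutation p < 0.05 and
|d| > 0.5), selected on the full data as in the source protocol — a
deliberately leaky selection; `analyze_outcome` falls back to all features
(chance-level by construction) when nothing passes. Because that selection
leaks outcome information, `crossval_combined_nested` re-selects the
feature set inside every training fold and is exposed on the command line
as `--nested`; `per_feature_predictions` emits the per-feature × family
report with both an AUC and an accuracy ranking, since the best-model
choice depends on which criterion is ranked. Classification is
stratified 5-fold CV repeated 50 times (repetition r seeds with seed + r);
AUC is computed on the pooled out-of-fold scores per repetition, accuracy/
sensitivity/specificity on the pooled out-of-fold class predictions, with
good outcome (ILAE 1–2) as the positive class. Model families map to
scikit-learn defaults: decision tree, linear discriminant, logistic
regression, RBF-kernel SVC (scores via the decision function), 5-NN, and a
30-tree bagged ensemble, each behind a standard scaler. A deterministic
1e−8 relative jitter on the feature keeps zero-within-class-variance
training sets well-posed (LDA's covariance solve otherwise degenerates).
The ROC optimal point maximizes Youden's J with ties broken toward higher
specificity; constant scores are flagged degenerate.

The generator plants outcome effects only *within* regions, so the
low-resolution combined predictor is near chance by construction; the
high-vs-low-resolution contrast in the tests is therefore qualitative
(within-region ≥ between-region), not a calibrated margin.

## Problem sizes and determinism

Default desk-scale conditions: 69 subjects, 16 regions × ~120 triangles at
12.6 mm² ("12k-equivalent" density), ~11,500 streamlines per subject. At
these sizes a full cohort metric table costs roughly a minute at 50 nulls
per region on one core; the 20-seed recovery sweep in the test suite uses
10 nulls and skips the whole-brain rows. All randomness descends from one
master seed via named substreams (`numpy.random.SeedSequence`); reruns with
the same configuration are byte-identical, which the pipeline tests assert.

## Known limitations

* The cortical geometry is a sphere; no sulcal geometry, no subcortex, and
  region adjacency structure is not anatomical.
* All subjects share one base mesh (scaled per subject), so region node
  counts do not vary across subjects; the within-region size screen is
  consequently inert on synthetic data (by design, documented above).
* Streamline trajectories are three-point arcs: adequate for length
  bookkeeping, not for tract-shape analyses.
* The low-resolution network carries no planted disease signal; conclusions
  about relative high/low-resolution predictive power on real data cannot
  be drawn from the synthetic contrast.
* Fixed edge-count conservation in the disease model means planted effects
  never appear in edge density — unlike real patients, where density
  differences are reported.
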