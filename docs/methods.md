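# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `morphconn`, and what the synthetic-data tests do
and do not establish about real data.

## KLS similarity networks

Each region's gray-matter density distribution is estimated by a
Gaussian kernel density estimate with Silverman's bandwidth
((3n/4)^(−1/5) × sample s.d.), evaluated on one shared 256-point grid
per subject spanning the pooled sample range of all regions, extended
by three pooled bandwidths so kernel tails are captured. Densities are
converted to discrete masses (unit sum), floored at ε = 10⁻¹⁰ and
renormalized — KL divergence is undefined at zeros, and the floor also
bounds the largest attainable symmetric KL, keeping every similarity
strictly positive. The edge weight is

KLS(i, j) = exp{−[KL(p̂ᵢ‖p̂ⱼ) + KL(p̂ⱼ‖p̂ᵢ)]},

the *sum* of the two KL directions (a mean-of-directions variant is
selectable via `symmetrization="mean"`). The diagonal is fixed at 1 but
never participates in thresholding or metrics — self-similarity is not
an edge. Using one shared grid per subject rather than a per-pair grid
makes all 4,005 pair similarities one matrix product over the
per-region mass vectors; the per-pair variant remains available through
`estimate_density(samples, grid)` + `kls`.

For two Gaussians the similarity has the closed form
exp(−[ln(σ₂/σ₁) + (σ₁² + Δμ²)/(2σ₂²) − ½ + ln(σ₁/σ₂) +
(σ₂² + Δμ²)/(2σ₁²) − ½]), implemented as `gaussian_kls` and used as the
analytic oracle for the estimator. At 500 samples/region the estimator
tracks this oracle with mean absolute error ≈ 0.02–0.03; individual
pairs in the mid-similarity range (KLS ≈ 0.3–0.8), where the exponential
is steepest in the KL estimate, can deviate by up to ≈ 0.15 from pure
sampling noise. The validation therefore bounds the *mean* absolute
error (< 0.05 at n = 500); per-pair error shrinks with sample count and
is checked to decrease between n = 100 and n = 4000.

## Binary graph topology

Thresholding retains the round-half-up(S·N(N−1)/2) strongest
off-diagonal edges (ties broken by descending weight, then ascending
(row, column) index — fully deterministic). Round-half-up is computed
after rounding the product to 9 decimals so that values such as
0.30 × 4005 = 1201.5, which binary floating point represents just below
the tie, round up as intended. The default scheme is the inclusive
range S = 0.10…0.34 in steps of 0.01 (25 thresholds); every metric
curve is summarized by its trapezoidal AUC over S.

Conventions for the individual measures:

* **C_p** — mean over nodes of 2tᵢ/(kᵢ(kᵢ−1)); nodes of degree < 2
  contribute 0 (they have no neighbor pairs).
* **L_p** — mean shortest-path length over *connected* ordered pairs.
  Disconnected graphs are not given an infinite-distance convention;
  the first occurrence per process is logged as a warning. Note the
  consequence: if a perturbation fragments a graph into compact
  components, connected-pairs L_p can *decrease*; the synthetic
  generator is designed to keep graphs connected across the threshold
  range so that regularization raises L_p, as intended.
* **E_glob** — mean inverse distance over ordered pairs (0 for
  unreachable pairs); **E_loc** — mean over nodes of the global
  efficiency of the neighbor-induced subgraph.
* **Nodal** — degree; nodal efficiency (1/(N−1)) Σⱼ 1/dᵢⱼ; betweenness
  is unnormalized Brandes centrality (networkx); normalization would
  only rescale group comparisons.
* **γ, λ, σ** — ratios against the mean of a degree-preserving null
  ensemble: 100 rewired graphs by default (seeded; ensemble mean and
  s.d. are reported alongside). Rewiring attempts 10× edge-count
  double-edge swaps; rejected proposals count as attempts, and
  connectedness is not enforced. The swap loop is numba-compiled (a
  pure-Python fallback keeps the package importable without a JIT).

All-pairs distances use a level-synchronous BFS over all sources at
once via float32 matrix products — for the dense ~90-node graphs this
pipeline produces, faster than per-source traversal; it is verified
against `scipy.sparse.csgraph` and brute-force Floyd–Warshall in the
tests.

## Statistical inference

* **Permutation tests** on AUC metrics reallocate all values into two
  groups of the original sizes; the two-tailed p is
  (1 + #{|null| ≥ |observed|})/(1 + n_perm) (never exactly zero, valid
  by construction). Default 10,000 permutations. Per-region nodal
  testing shares one set of permutations across regions and
  centralities (`permutation_test_matrix`) — statistically equivalent
  per column and an order of magnitude cheaper. Permutation tests
  compare raw AUC values without covariate adjustment; covariates enter
  the regression models only.
* **Abnormal regions** — flagged when ≥ 2 of the 3 nodal centrality
  p-values fall below 0.05, uncorrected (strict inequality).
* **Mixed models** — `value ~ group × time + age + sex` with a
  subject-level random intercept, REML. The group-by-time interaction
  is a joint Wald test of all interaction terms; F is reported as the
  Wald χ²/df with the χ² p-value (MixedLM does not supply a
  denominator-df F). Rank deficiency of the fixed-effects design raises
  a collinearity error rather than silently fitting.
* **FDR** — Benjamini–Hochberg step-up (statsmodels), validated against
  a brute-force step-up oracle.
* **Responder rule** — (YMRS₀ − YMRS_end)/YMRS₀ ≥ 0.5; scale-invariant.
* **ICC** — two-way mixed, consistency, single measure, ICC(3,1) =
  (MSR − MSE)/(MSR + (k−1)MSE) from the two-way ANOVA mean squares;
  degenerate variance yields an explicit "undefined" category.
  Cicchetti bins: < 0.40 poor, 0.40–0.59 fair, 0.60–0.74 good,
  ≥ 0.75 excellent.

## Response prediction

Linear SVM (C = 1, configurable; a linear kernel is required for the
weight-map interpretation), stratified 10-fold CV with per-fold
standardization fitted on training folds only (scikit-learn Pipeline,
so leakage is structurally impossible — verified by a canary test).
Performance is the mean of per-class recalls (balanced accuracy) per
fold; significance is p = (1 + #{permuted mean accuracy ≥ observed})/
(1 + n_perm) with the full CV re-run per permuted label vector. Edge
importance is the mean |w| across folds; a region's weight is the mean
over its N−1 incident edges; ranking is descending with index-order tie
breaks. The pipeline classifies KLS matrices; externally supplied
correlation matrices can be substituted, as the operations only assume
a symmetric similarity matrix.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
it is a ground-truth device, not a biophysical model of gray matter.

* **Regional densities** — truncated Gaussians on [0, 1] (σ = 0.05,
  per-subject log-normal jitter 0.08): the choice admits the
  closed-form KLS oracle. Clipping to [0, 1] happens after sampling
  (density is a tissue probability); with means in [0.25, 0.75] it
  almost never binds, keeping the oracle valid.
* **Network structure** — region means form a 1-D lattice of
  communities (default 6 communities of 15 regions): core regions
  evenly spaced within a community, adjacent communities separated by a
  gap of 4 within-steps crossed by one mid-gap *bridge* region per
  boundary. Nearest-neighbour similarity keeps thresholded graphs
  connected at S = 0.10 while clustering stays far above the rewired
  null, so control networks are small-world (minimum σ ≈ 1.6 across the
  full range).
* **Patient effect** — all offsets (core and bridge) shrink toward the
  community centre by 5% per unit `patient_effect`. This concentrates
  the fixed edge budget within communities (C_p ↑) and widens the
  boundary hops (L_p ↑) without fragmenting the graph. The default
  magnitude (1.0) induces a large standardized C_p-AUC difference
  (d ≈ 2) and a moderate L_p difference (d ≈ 0.8) at study-scale group
  sizes (100 patients, 63 controls) — the same ordering the case-control
  statistics show (C_p more significant than L_p), with power
  comfortably above 80% per metric.
* **Treatment dynamics** — each patient's eventual normalization
  fraction is higher for responders (0.85 vs 0.45, ±0.15 via a latent
  factor); the perturbation decays with the square root of elapsed
  weeks times `normalization_rate` (0.8), giving partial normalization
  at week 1 and near-complete normalization for responders by week 6.
* **Symptoms** — baseline YMRS = 20 + Poisson(8) (inclusion requires
  ≥ 20); responder status is assigned first (fraction 0.55, both
  classes forced non-empty), and the week-6 percent reduction is drawn
  inside class-consistent bounds ([0.50, 0.95] vs [0.02, 0.49]) so the
  ≥ 50%-reduction rule reproduces the label exactly, including after
  integer rounding of the endpoint score. The reduction shares a latent
  factor with network normalization at strength `coupling` (0.6),
  producing the metric-change/symptom-change correlations (r ≈ 0.4–0.55
  for C_p at moderate n). CDRS-R decays at half the YMRS rate; CGI-S is
  a deterministic function of YMRS.
* **Responder baseline marker** — responders' bilateral insula means
  are shifted by `response_signal` (default 0.02) at baseline only,
  emulating a pretreatment marker that resolves with treatment; a
  planted signal of 0.035 is recovered by the SVM at ≈ 0.86 balanced
  accuracy with the insula ranked first in the weight map.
* **Demographics** — age ~ N(14.7, 2.0) clipped to [10, 17.9], 40%
  male, independent of group (matched design). Arms ("lithium-like",
  "quetiapine-like", split 0.5) have identical dynamics, so
  treatment-by-time contrasts are null by construction.
* **Reliability** — per-subject trait jitter (s.d. 0.003 on region
  means, constant across timepoints) plus smaller per-scan noise
  (0.0015) gives control-group metric ICCs in the fair range (≈ 0.4),
  mirroring the reliability screen the analysis assumes.

What passing tests on this generator do **not** show: robustness to
non-Gaussian density shapes, spatial smoothing artifacts, scanner or
registration effects, dropout, or parcellation choices — none of which
the generator emulates.

## Problem sizes in the validation suite

The test suite scales simulations to what the statistics require:
estimator accuracy at 300–1,000 pairs; brute-force metric equivalence
on 100 graphs of ≤ 8 nodes; the small-world screen on 20 control
subjects with 30 nulls/threshold (100 in `scripts/acceptance.py`);
permutation calibration on 500 null datasets × 1,000 permutations;
effect recovery on 50 replicate cohorts at full study-scale group
sizes; prediction on a 100-patient planted-signal cohort with 150
label permutations.

## Known limitations

* The mixed-model F statistic is a Wald χ²/df, not a
  denominator-df-corrected F; at the cohort sizes involved the
  difference is negligible, but small-sample p-values are approximate.
* Connected-pairs L_p is not comparable across graphs with very
  different fragmentation; the generator avoids the regime, but user
  data at aggressive thresholds may not.
* KLS values near 1 compress differences between strongly similar
  regions; group contrasts rely on threshold-rank changes, not on the
  raw similarity scale.
* The per-pair KLS estimator tolerance at n = 500 is a mean-error
  bound; single mid-range pairs carry ≈ ±0.1 sampling noise.
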