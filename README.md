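# morphconn

Gray-matter **morph**ological similarity **conn**ectomes: build per-subject
Kullback–Leibler-similarity (KLS) brain networks from regional gray-matter
density samples, characterize their topology across sparsity thresholds,
run permutation-based case-control and longitudinal inference, and predict
treatment response from baseline connectomes with a cross-validated linear
SVM.

## Who this is for

Neuroimaging groups studying structural connectome alterations in clinical
cohorts — e.g. youth with bipolar disorder scanned before and during
pharmacotherapy — who start from region-wise gray-matter density samples
(AAL-90 parcellation by default) and need a reproducible pipeline from raw
regional samples to group statistics and individual-level prediction. A
synthetic-cohort generator with known ground truth (community-structured
similarity networks, treatment-linked normalization, responder-linked
baseline signal) makes every stage testable without access to patient data.

## The model

**Edges.** For each subject, the density distribution of region *i* is
estimated by Gaussian-kernel density estimation (Silverman bandwidth) on a
shared grid, and every region pair is scored by the KL-based similarity

&nbsp;&nbsp;&nbsp;&nbsp;KLS(i, j) = exp{−[KL(p̂ᵢ‖p̂ⱼ) + KL(p̂ⱼ‖p̂ᵢ)]} ∈ (0, 1],

with KLS = 1 for identical distributions, giving a symmetric 90 × 90
similarity matrix per subject and timepoint.

**Topology.** Each matrix is binarized by keeping the strongest S-fraction
of edges for sparsity S = 0.10, 0.11, …, 0.34. At every threshold the
pipeline computes the clustering coefficient C_p, characteristic path
length L_p, global and local efficiency E_glob / E_loc, and the normalized
small-world quantities γ = C_p/⟨C_p^rand⟩, λ = L_p/⟨L_p^rand⟩ and
σ = γ/λ against degree-preserving rewired null graphs; σ > 1 indicates
small-world organization. Nodal degree, nodal efficiency and (unnormalized)
betweenness centrality are computed per region. Every metric curve is
summarized by its trapezoidal area under the curve (AUC) over S, a
threshold-free scalar.

**Inference.** Case-control differences in AUC metrics are tested with
label-reallocation permutation tests (two-tailed empirical p with the +1
correction). Regions are flagged as abnormal when at least two of the
three nodal centralities differ at p < 0.05 (uncorrected). Group-by-time
effects use mixed models with subject-level random intercepts and age/sex
covariates; metric-change vs symptom-change associations use Pearson
correlation; multiplicity is controlled by Benjamini–Hochberg FDR.
Treatment response is a ≥ 50 % YMRS reduction from baseline; reliability
is screened with ICC(3,1) under Cicchetti's categories.

**Prediction.** Baseline connectomes are flattened to 4,005 upper-triangle
edge features and classified (responder vs non-responder) by a linear SVM
under stratified 10-fold cross-validation, with training-fold-only
standardization, balanced accuracy scoring, label-permutation significance,
and a per-region weight map (mean |w| over each region's 89 incident
edges) ranking the regions that drive the prediction.

## Worked example

```python
import numpy as np
from morphconn import (CohortConfig, ThresholdScheme, build_similarity_matrix,
                       generate_cohort, global_metric_curves, permutation_test)

cfg = CohortConfig(n_patients=30, n_controls=30, timepoints=("baseline",), seed=7)
profiles = generate_cohort(cfg)

scheme = ThresholdScheme()  # sparsities 0.10 .. 0.34, step 0.01
auc = {"patient": [], "control": []}
for p in profiles:
    matrix = build_similarity_matrix(p)          # 90 x 90 KLS connectome
    curves = global_metric_curves(matrix, scheme, metrics=("cp", "lp"))
    auc[p.group].append((curves["cp"].auc, curves["lp"].auc))

pat, ctl = np.array(auc["patient"]), np.array(auc["control"])
print(f"Cp AUC  patients {pat[:, 0].mean():.4f}  controls {ctl[:, 0].mean():.4f}")
print(f"Lp AUC  patients {pat[:, 1].mean():.4f}  controls {ctl[:, 1].mean():.4f}")
res = permutation_test(pat[:, 0], ctl[:, 0], n_perm=10_000, seed=7)
print(f"Cp AUC group difference: {res.observed:+.4f}, permutation p = {res.p_two_tailed:.4f}")
```

prints

```
Cp AUC  patients 0.1839  controls 0.1824
Lp AUC  patients 0.9096  controls 0.9008
Cp AUC group difference: +0.0015, permutation p = 0.0001
```

The synthetic patients' networks are shifted toward regularization — higher
clustering (C_p) and longer paths (L_p) than controls — and the permutation
test on the C_p AUC detects that shift. Control networks stay in the
small-world regime (minimum σ across all 25 thresholds ≈ 1.6).

## Command line

```bash
morphconn simulate --config cohort.yaml --out cohort_dir/
morphconn build-networks --in cohort_dir/ --out matrices.h5
morphconn metrics --matrices matrices.h5 --clinical cohort_dir/clinical.csv \
    --smin 0.10 --smax 0.34 --step 0.01 --nulls 100 --seed 7 --out metrics/
morphconn compare --metrics metrics/ --clinical cohort_dir/clinical.csv \
    --n-perm 10000 --seed 7 --out stats/
morphconn predict --matrices matrices.h5 --clinical cohort_dir/clinical.csv \
    --folds 10 --n-perm 1000 --seed 7 --out prediction/
morphconn run --config run.yaml          # all stages, one manifest
```

Every stochastic stage receives a seed derived from the single global seed;
all output tables carry the config hash in a header comment, and `run`
writes a manifest with SHA-256 digests, so a run is reproducible
byte-for-byte from its YAML config.

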