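"""Case-control and longitudinal inference on connectome metrics.

Covers the statistical machinery of the analysis: nonparametric
permutation tests on AUC metrics (label reallocation, two-tailed
empirical p with the +1 correction), the 2-of-3 nodal-centrality
abnormality rule, mixed-effects group-by-time interaction models with
age/sex covariates, Pearson correlations between metric change and
symptom change, Benjamini–Hochberg FDR adjustment, the >= 50% YMRS
reduction responder rule, and ICC reliability screening with
Cicchetti's categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "LongitudinalResult",
    "ReliabilityResult",
    "permutation_test",
    "permutation_test_matrix",
    "abnormal_regions",
    "interaction_model",
    "change_correlation",
    "fdr_adjust",
    "classify_responder",
    "icc",
]

NODAL_METRIC_COLUMNS = ("degree", "efficiency", "betweenness")


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_two_tailed: float
    n_perm: int


@dataclass
class LongitudinalResult:
    effect: str
    F: float
    p: float
    adjusted_q: float = float("nan")


@dataclass
class ReliabilityResult:
    icc: float
    category: str  # poor | fair | good | excellent | undefined


def permutation_test(a, b, n_perm: int = 10_000, seed: int | None = 0) -> PermutationResult:
    """Two-tailed permutation test of a group difference in means.

    All values are randomly reallocated into two groups of the original
    sizes ``n_perm`` times; the empirical two-tailed p-value is
    ``(1 + #{|null| >= |observed|}) / (1 + n_perm)`` (never exactly 0).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = float(a.mean() - b.mean())
    # vectorized label reallocation: each row of `order` is a permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = pooled[order]
    null = permuted[:, :na].mean(axis=1) - permuted[:, na:].mean(axis=1)
    p = (1 + int(np.sum(np.abs(null) >= abs(observed) - 1e-12))) / (1 + n_perm)
    return PermutationResult(
        observed=observed, null_distribution=null, p_two_tailed=float(p), n_perm=int(n_perm)
    )


def permutation_test_matrix(
    values: np.ndarray, in_group_a: np.ndarray, n_perm: int = 10_000, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise permutation tests sharing one set of label reallocations.

    ``values`` is (subjects x columns); ``in_group_a`` a boolean mask.
    Returns (observed mean differences, two-tailed p-values), one per
    column. Sharing permutations across columns is what makes per-region,
    per-centrality testing at 10,000 permutations affordable.
    """
    v = np.asarray(values, dtype=float)
    mask = np.asarray(in_group_a, dtype=bool)
    na, nb = int(mask.sum()), int((~mask).sum())
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least two values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = v[mask].mean(axis=0) - v[~mask].mean(axis=0)
    n = v.shape[0]
    exceed = np.zeros(v.shape[1], dtype=int)
    for _ in range(n_perm):
        order = rng.permutation(n)
        null = v[order[:na]].mean(axis=0) - v[order[na:]].mean(axis=0)
        exceed += np.abs(null) >= np.abs(observed) - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    return observed, p


def abnormal_regions(p_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag regions abnormal in >= 2 of the 3 nodal centralities.

    ``p_table`` must carry one row per region and the three p-value
    columns ``degree``, ``efficiency``, ``betweenness`` (uncorrected).
    Returns the table with an added boolean ``abnormal`` column.
    """
    missing = [c for c in NODAL_METRIC_COLUMNS if c not in p_table.columns]
    if missing:
        raise ValueError(f"p_table is missing metric column(s): {missing}")
    out = p_table.copy()
    below = (out[list(NODAL_METRIC_COLUMNS)] < alpha).sum(axis=1)
    out["abnormal"] = below >= 2
    return out


def interaction_model(
    long_table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    time: str = "timepoint",
    subject: str = "subject_id",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> LongitudinalResult:
    """Group-by-time interaction from a mixed-effects model.

    Fits ``value ~ group * time + covariates`` with a subject-level
    random intercept (REML) and returns a joint Wald test of all
    group-by-time interaction terms. The F statistic is the Wald
    chi-square divided by its degrees of freedom.
    """
    df = long_table.dropna(subset=[value]).copy()
    if df[group].nunique() < 2:
        raise ValueError("interaction model needs both groups present")
    if df[time].nunique() < 2:
        raise ValueError("interaction model needs at least two timepoints")
    # keep the stated timepoint order rather than lexical order
    tp_order = list(dict.fromkeys(long_table[time]))
    df[time] = pd.Categorical(df[time], categories=tp_order, ordered=True)

    import statsmodels.formula.api as smf

    cov_terms = []
    for c in covariates:
        if c not in df.columns:
            continue
        cov_terms.append(f"C({c})" if df[c].dtype == object else c)
    formula = f"{value} ~ C({group}) * C({time})"
    if cov_terms:
        formula += " + " + " + ".join(cov_terms)

    model = smf.mixedlm(formula, df, groups=df[subject])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("collinear covariates in the fixed-effects design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)

    inter = [
        name
        for name in res.model.exog_names
        if ":" in name and f"C({group})" in name and f"C({time})" in name
    ]
    if not inter:
        raise RuntimeError("no interaction terms found in the fitted model")
    constraint = ", ".join(f"{name} = 0" for name in inter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test(constraint, scalar=False)
    chi2 = float(np.squeeze(wt.statistic))
    dof = len(inter)
    F = chi2 / dof
    p = float(stats.chi2.sf(chi2, dof))
    return LongitudinalResult(effect=f"{group}:{time}", F=F, p=p)


def change_correlation(delta_metric, delta_symptom) -> tuple[float, float]:
    """Pearson correlation between per-patient metric and symptom change."""
    x = np.asarray(delta_metric, dtype=float).ravel()
    y = np.asarray(delta_symptom, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired changes must have equal length")
    if x.size < 3:
        raise ValueError("need at least three paired changes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, >= p)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_responder(ymrs_baseline: float, ymrs_endpoint: float) -> str:
    """Responder iff YMRS fell by at least 50% from baseline."""
    if ymrs_baseline <= 0:
        raise ValueError("baseline YMRS must be positive")
    reduction = (ymrs_baseline - ymrs_endpoint) / ymrs_baseline
    return "responder" if reduction >= 0.5 else "non-responder"


def _cicchetti(icc_value: float) -> str:
    if not np.isfinite(icc_value):
        return "undefined"
    if icc_value < 0.40:
        return "poor"
    if icc_value < 0.60:
        return "fair"
    if icc_value < 0.75:
        return "good"
    return "excellent"


def icc(measurements) -> ReliabilityResult:
    """ICC(3,1): two-way mixed, consistency, single measurement.

    ``measurements`` is a (subjects x repeats) array. Computed from the
    two-way ANOVA mean squares as ``(MSR - MSE) / (MSR + (k-1) MSE)``.
    Degenerate variance yields an explicit "undefined" result.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D (subjects x repeats) array")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 repeated measurements")
    if np.any(~np.isfinite(x)):
        raise ValueError("measurements contain non-finite values")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if ss_total == 0 or denom <= 0:
        return ReliabilityResult(icc=float("nan"), category="undefined")
    value = (msr - mse) / denom
    return ReliabilityResult(icc=float(value), category=_cicchetti(float(value)))
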