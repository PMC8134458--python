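"""Permutation inference, FDR, responder rule, ICC, mixed models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bruteforce import bf_fdr
from morphconn import (
    abnormal_regions,
    change_correlation,
    classify_responder,
    fdr_adjust,
    icc,
    interaction_model,
    permutation_test,
    permutation_test_matrix,
)

# Printed nodal-centrality p-values (degree, efficiency, betweenness) for
# the baseline case-control comparison; all these regions meet the
# 2-of-3 rule at alpha = 0.05.
BASELINE_TABLE = {
    "Right inferior frontal gyrus (opercular part)": (0.010, 0.151, 0.008),
    "Left supplementary motor area": (0.006, 0.004, 0.341),
    "Right supplementary motor area": (0.046, 0.044, 0.580),
    "Left insula": (0.016, 0.017, 0.631),
    "Right insula": (0.019, 0.045, 0.585),
    "Right parahippocampal gyrus": (0.024, 0.051, 0.033),
    "Right superior parietal gyrus": (0.117, 0.039, 0.048),
    "Left paracentral lobule": (0.019, 0.007, 0.017),
}


class TestPermutationTest:
    def test_identical_groups_null(self):
        a = np.arange(10.0)
        res = permutation_test(a, a.copy(), n_perm=500, seed=0)
        assert res.observed == 0.0
        assert res.p_two_tailed == 1.0

    def test_extreme_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        res = permutation_test(a, b, n_perm=10_000, seed=0)
        assert res.p_two_tailed <= 0.001

    def test_p_never_zero_and_deterministic(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        r1 = permutation_test(a, b, n_perm=999, seed=3)
        r2 = permutation_test(a, b, n_perm=999, seed=3)
        assert r1.p_two_tailed == r2.p_two_tailed > 0
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="two values"):
            permutation_test([1.0], [1.0, 2.0], n_perm=10)

    def test_type_one_error_calibrated(self):
        """Under the null the rejection rate at alpha=0.05 stays within
        3 Monte-Carlo standard errors of 0.05 (reduced-scale check; the
        full calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(4)
        n_data = 200
        rejections = 0
        for i in range(n_data):
            a, b = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
            p = permutation_test(a, b, n_perm=500, seed=i).p_two_tailed
            rejections += p < 0.05
        rate = rejections / n_data
        se = np.sqrt(0.05 * 0.95 / n_data)
        assert rate <= 0.05 + 3 * se

    def test_matrix_variant_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1, (40, 3))
        v[:20, 1] += 1.2
        mask = np.zeros(40, dtype=bool)
        mask[:20] = True
        obs, p = permutation_test_matrix(v, mask, n_perm=4000, seed=6)
        for c in range(3):
            ref = permutation_test(v[mask, c], v[~mask, c], n_perm=4000, seed=7)
            assert obs[c] == pytest.approx(ref.observed)
            se = 3 * np.sqrt(ref.p_two_tailed * (1 - ref.p_two_tailed) / 4000)
            assert abs(p[c] - ref.p_two_tailed) <= se + 0.01


class TestAbnormalRegions:
    def test_reproduces_printed_baseline_flags(self):
        df = pd.DataFrame(
            [
                {"region": name, "degree": d, "efficiency": e, "betweenness": b}
                for name, (d, e, b) in BASELINE_TABLE.items()
            ]
        )
        out = abnormal_regions(df)
        assert out["abnormal"].all()

    def test_single_significant_metric_not_flagged(self):
        df = pd.DataFrame(
            [{"region": "r1", "degree": 0.04, "efficiency": 0.20, "betweenness": 0.70}]
        )
        assert not abnormal_regions(df)["abnormal"].any()

    def test_missing_metric_column_named(self):
        df = pd.DataFrame([{"region": "r1", "degree": 0.01, "efficiency": 0.02}])
        with pytest.raises(ValueError, match="betweenness"):
            abnormal_regions(df)


def _longitudinal_frame(rng, n_per_group=25, effect=0.0):
    rows = []
    for g, group in enumerate(("control", "patient")):
        for i in range(n_per_group):
            sid = f"{group}{i}"
            intercept = rng.normal(0, 1)
            age, sex = rng.uniform(10, 18), rng.choice(["M", "F"])
            for t, tp in enumerate(("baseline", "week1", "week6")):
                val = intercept + 0.1 * t + effect * g * t + rng.normal(0, 0.5)
                rows.append(
                    dict(subject_id=sid, group=group, timepoint=tp, age=age, sex=sex, value=val)
                )
    return pd.DataFrame(rows)


class TestInteractionModel:
    def test_recovers_group_by_time_effect(self):
        df = _longitudinal_frame(np.random.default_rng(0), effect=0.6)
        res = interaction_model(df)
        assert res.p < 0.05
        assert res.F > 0

    def test_null_effect_not_rejected_wildly(self):
        df = _longitudinal_frame(np.random.default_rng(1), effect=0.0)
        res = interaction_model(df)
        assert res.p > 0.001

    def test_single_group_rejected(self):
        df = _longitudinal_frame(np.random.default_rng(2))
        with pytest.raises(ValueError, match="both groups"):
            interaction_model(df[df["group"] == "patient"])

    def test_collinear_covariate_reported(self):
        df = _longitudinal_frame(np.random.default_rng(3))
        df["dupage"] = df["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            interaction_model(df, covariates=("age", "sex", "dupage"))


class TestChangeCorrelation:
    def test_proportional_changes(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = change_correlation(x, 3 * x)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            change_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFdrAdjust:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_matches_brute_force_stepup(self, p):
        got = fdr_adjust(p)
        np.testing.assert_allclose(got, bf_fdr(p), atol=1e-12)
        assert np.all(got >= np.asarray(p) - 1e-15)


class TestClassifyResponder:
    @pytest.mark.parametrize(
        "base, end, expect",
        [(20, 10, "responder"), (20, 11, "non-responder"), (40, 0, "responder")],
    )
    def test_examples(self, base, end, expect):
        assert classify_responder(base, end) == expect

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_responder(0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=0, max_value=60),
        st.floats(min_value=0.1, max_value=100.0, allow_nan=False),
    )
    def test_scale_invariance(self, base, end, k):
        assert classify_responder(base, end) == classify_responder(k * base, k * end)


class TestIcc:
    def test_perfect_reliability(self):
        x = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        res = icc(x)
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_cicchetti_categories(self):
        # construct data with a known ICC via variance components
        rng = np.random.default_rng(0)
        subj = rng.normal(0, 1.0, (200, 1))
        x = subj + rng.normal(0, 1.0, (200, 4))  # ICC = 1/(1+1) = 0.5
        res = icc(x)
        assert res.icc == pytest.approx(0.5, abs=0.08)
        assert res.category == "fair"

    def test_independent_repeats_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [icc(rng.normal(0, 1, (30, 3))).icc for _ in range(50)]
        assert abs(np.mean(vals)) < 0.05

    def test_degenerate_variance_undefined(self):
        res = icc(np.full((5, 3), 2.0))
        assert res.category == "undefined"
        assert np.isnan(res.icc)

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (20, 4)) + rng.normal(0, 1, (20, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 4),
                "rater": np.tile(np.arange(4), 20),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc(x).icc == pytest.approx(icc3, abs=1e-9)
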