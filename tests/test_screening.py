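"""Exclusion rules, depression screening, descriptives, and bias checks."""

import numpy as np
import pandas as pd
import pytest

from modmod import (
    DegenerateVariableError,
    GeneratorConfig,
    GroupingError,
    apply_exclusions,
    gender_t_test,
    generate_cohort,
    harman_single_factor,
    pearson_matrix,
    score_frame,
    screen_positive,
    screening_report,
)
from modmod.scales import all_item_columns


class TestApplyExclusions:
    def test_single_missing_item_excluded_as_incomplete(self, clean_cohort):
        frame = clean_cohort.head(10).copy()
        frame.iloc[3, frame.columns.get_loc("pcq17")] = np.nan
        retained, excluded = apply_exclusions(frame)
        assert len(excluded) == 1
        assert excluded["reason"].iloc[0] == "incomplete"
        assert len(retained) == 9

    def test_clean_records_all_retained(self, clean_cohort):
        retained, excluded = apply_exclusions(clean_cohort)
        assert len(excluded) == 0
        assert len(retained) == len(clean_cohort)

    def test_idempotent(self, screening_fixture_cohort):
        retained1, _ = apply_exclusions(screening_fixture_cohort)
        retained2, excluded2 = apply_exclusions(retained1)
        assert len(excluded2) == 0
        pd.testing.assert_frame_equal(retained1, retained2)

    def test_empty_input_gives_empty_outputs(self, clean_cohort):
        retained, excluded = apply_exclusions(clean_cohort.head(0))
        assert len(retained) == 0 and len(excluded) == 0

    def test_reference_fixture_exclusion_percentage(self, screening_fixture_cohort):
        report, _ = screening_report(screening_fixture_cohort)
        assert report.n_raw == 2359
        assert report.n_excluded == 112
        assert report.exclusion_pct == pytest.approx(4.75, abs=0.005)


class TestScreenPositive:
    def test_threshold_boundary(self, clean_scores):
        screened = screen_positive(clean_scores, threshold=5)
        assert (screened["dep"] >= 5).all()
        kept_ids = set(screened["id"])
        boundary = clean_scores[clean_scores["dep"].isin([4, 5])]
        for _, row in boundary.iterrows():
            assert (row["id"] in kept_ids) == (row["dep"] == 5)

    def test_impossible_threshold_gives_empty_set(self, clean_scores):
        assert len(screen_positive(clean_scores, threshold=28)) == 0

    def test_reference_band_counts_sum_to_positive_screens(
        self, screening_fixture_cohort
    ):
        report, _ = screening_report(screening_fixture_cohort)
        assert report.band_counts == {
            "none": 1553, "mild": 591, "moderate": 70,
            "moderately_severe": 23, "severe": 10,
        }
        assert report.n_positive == 591 + 70 + 23 + 10 == 694
        assert report.prevalence_pct == pytest.approx(30.89, abs=0.005)

    def test_report_invariant_to_row_order(self, screening_fixture_cohort):
        shuffled = screening_fixture_cohort.sample(
            frac=1.0, random_state=5
        ).reset_index(drop=True)
        a, _ = screening_report(screening_fixture_cohort)
        b, _ = screening_report(shuffled)
        assert a.to_dict() == b.to_dict()


class TestPearsonMatrix:
    def test_self_correlation_and_antisymmetry(self):
        x = np.arange(30, dtype=float)
        scores = pd.DataFrame({"dep": x, "is": -x, "psycap": x**2, "fs": x % 7})
        summary = pearson_matrix(scores)
        assert summary.r.loc["dep", "dep"] == pytest.approx(1.0)
        assert summary.r.loc["dep", "is"] == pytest.approx(-1.0)
        assert np.allclose(summary.r, summary.r.T)

    def test_round_trip_recovers_generating_correlation(self, clean_scores):
        summary = pearson_matrix(clean_scores)
        assert summary.r.loc["is", "dep"] == pytest.approx(0.399, abs=0.05)
        assert summary.p.loc["is", "dep"] < 1e-10

    def test_zero_variance_column_rejected(self):
        scores = pd.DataFrame(
            {"dep": [1.0, 2, 3], "is": [1.0, 1, 1],
             "psycap": [1.0, 2, 1], "fs": [0.0, 1, 0]}
        )
        with pytest.raises(DegenerateVariableError):
            pearson_matrix(scores)

    def test_p_values_match_t_transform(self, clean_scores):
        from scipy import stats

        summary = pearson_matrix(clean_scores)
        r = summary.r.loc["psycap", "fs"]
        n = summary.n
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert summary.p.loc["psycap", "fs"] == pytest.approx(
            2 * stats.t.sf(abs(t), n - 2)
        )


class TestGenderTTest:
    def test_identical_groups_give_zero_t(self):
        scores = pd.DataFrame(
            {"gender": ["male"] * 3 + ["female"] * 3, "dep": [1.0, 2, 3, 1, 2, 3]}
        )
        t, df, p = gender_t_test(scores, "dep")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # groups (1,2,3) vs (4,5,6): pooled sd 1, se = sqrt(2/3), t = -3/0.8165
        scores = pd.DataFrame(
            {"gender": ["male"] * 3 + ["female"] * 3,
             "dep": [1.0, 2, 3, 4, 5, 6]}
        )
        t, df, p = gender_t_test(scores, "dep")
        assert t == pytest.approx(-3.674, abs=0.001)
        assert df == 4

    def test_absent_group_rejected(self):
        scores = pd.DataFrame({"gender": ["male"] * 4, "dep": [1.0, 2, 3, 4]})
        with pytest.raises(GroupingError):
            gender_t_test(scores, "dep")

    def test_type_i_rate_under_gender_independence(self, clean_scores):
        # gender is assigned independently of scores, so relabelling genders
        # repeatedly must reject at about the nominal 5% rate
        gen = np.random.default_rng(99)
        sub = clean_scores.head(2000).copy()
        rejections = 0
        reps = 500
        for _ in range(reps):
            sub["gender"] = np.where(
                gen.random(len(sub)) < 0.6, "female", "male"
            )
            _, _, p = gender_t_test(sub, "dep")
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestHarman:
    def test_rank_one_matrix_gives_full_share(self, rng):
        item = rng.standard_normal(200)
        matrix = np.column_stack([item] * 8)
        assert harman_single_factor(matrix) == pytest.approx(100.0)

    def test_independent_items_share_near_uniform(self, rng):
        k = 62
        matrix = rng.standard_normal((10_000, k))
        assert harman_single_factor(matrix) == pytest.approx(100 / k, abs=1.0)

    def test_one_factor_equicorrelation_share(self, rng):
        # loadings 0.7 on every item: corr matrix is equicorrelated at 0.49,
        # largest eigenvalue 1 + (k-1)*0.49, share = 49% + 51%/k
        k, n = 62, 10_000
        factor = rng.standard_normal((n, 1))
        matrix = 0.7 * factor + np.sqrt(1 - 0.49) * rng.standard_normal((n, k))
        expected = 100 * (0.49 + 0.51 / k)
        assert harman_single_factor(matrix) == pytest.approx(expected, abs=2.0)

    def test_constant_item_rejected(self, rng):
        matrix = rng.standard_normal((50, 4))
        matrix[:, 2] = 3.0
        with pytest.raises(DegenerateVariableError):
            harman_single_factor(matrix)

    def test_synthetic_cohort_passes_common_method_bias_check(self, clean_cohort):
        pct = harman_single_factor(
            clean_cohort[all_item_columns()].to_numpy(dtype=float)
        )
        assert 0 < pct < 40
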