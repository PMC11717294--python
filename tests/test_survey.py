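"""Questionnaire statistics: DCDQ, tallies, kappa, KS, multinomial logit."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oracles import fleiss_kappa_direct

from chopgrip.errors import ChopgripError, FitError
from chopgrip.simulate import make_survey_table
from chopgrip.survey import (
    describe_cohort,
    fit_multinomial_logit,
    fleiss_kappa,
    ks_normality,
    model_nagelkerke,
    nagelkerke_r2,
    score_dcdq,
    tally_grip_classes,
)


class TestDcdq:
    def test_all_fives_hit_subscale_maxima(self):
        s = score_dcdq([5] * 15)
        assert (s.control_during_movement, s.fine_motor_handwriting, s.general_coordination) == (
            30,
            20,
            25,
        )
        assert s.total == 75

    def test_all_ones_floor(self):
        assert score_dcdq([1] * 15).total == 15

    def test_total_is_sum_of_subscales(self, rng):
        for _ in range(20):
            items = rng.integers(1, 6, 15).tolist()
            s = score_dcdq(items)
            assert s.total == s.control_during_movement + s.fine_motor_handwriting + s.general_coordination

    def test_missing_item_propagates_to_subscale_and_total(self):
        items = [3] * 15
        items[2] = None  # control subscale item
        s = score_dcdq(items)
        assert math.isnan(s.control_during_movement)
        assert math.isnan(s.total)
        assert s.fine_motor_handwriting == 12

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ChopgripError):
            score_dcdq([3] * 14 + [6])


class TestTally:
    def test_counts_percentages_and_merged_group(self):
        labels = pd.Series(
            ["four_finger"] * 5 + ["three_finger"] * 3 + ["palm"] * 1 + ["other"] * 1
        )
        t = tally_grip_classes(labels)
        assert t.loc["four_finger", "count"] == 5
        assert t.loc["palm_other", "count"] == 2
        assert t.loc["four_finger", "percent"] == pytest.approx(50.0)
        four_classes = ["four_finger", "three_finger", "palm", "other"]
        assert t.loc[four_classes, "percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_table_all_zeros(self):
        t = tally_grip_classes(pd.Series([], dtype=object))
        assert (t["count"] == 0).all()

    def test_synthetic_table_matches_generator_bookkeeping(self):
        df = make_survey_table(n=300, seed=4)
        t = tally_grip_classes(df)
        assert t.loc[["four_finger", "three_finger", "palm", "other"], "count"].sum() == 300


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        m = np.array([["a", "a"], ["b", "b"], ["c", "c"], ["a", "a"]])
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        labels = rng.integers(0, 4, size=(10000, 2))
        assert abs(fleiss_kappa(labels)) < 0.03

    def test_matches_hand_formula_on_exhaustive_small_tables(self):
        """Exhaustive 2-rater tables over 3 categories, n = 2 and 3, plus a
        random sample of larger ones, against the hand-built formula."""
        cats = ["x", "y", "z"]
        for n in (2, 3):
            for table in itertools.product(itertools.product(cats, repeat=2), repeat=n):
                m = np.array(table, dtype=object)
                expected = fleiss_kappa_direct(m)
                if math.isnan(expected):
                    continue  # undefined: all mass in one category
                assert fleiss_kappa(m) == pytest.approx(expected, abs=1e-10)
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 7))
            m = rng.choice(cats, size=(n, 2))
            expected = fleiss_kappa_direct(m)
            if math.isnan(expected):
                continue
            assert fleiss_kappa(m) == pytest.approx(expected, abs=1e-10)

    def test_incomplete_ratings_rejected(self):
        m = np.array([["a", "b"], ["a", None]], dtype=object)
        with pytest.raises(ChopgripError):
            fleiss_kappa(m)

    def test_survey_raters_show_high_agreement(self):
        df = make_survey_table(n=300, seed=6)
        kappa = fleiss_kappa(df[["rater_1", "rater_2"]].to_numpy())
        assert kappa > 0.9


class TestKsNormality:
    def test_normal_sample_not_rejected(self, rng):
        out = ks_normality(rng.normal(50, 10, 200))
        assert out["normal"] and "log_values" not in out

    def test_exponential_sample_rejected_and_log_transformed(self, rng):
        out = ks_normality(rng.exponential(1.0, 500))
        assert not out["normal"]
        assert "log_values" in out and len(out["log_values"]) == 500

    def test_tiny_sample_rejected(self):
        with pytest.raises(ChopgripError):
            ks_normality([1.0, 2.0, 3.0])

    def test_nonpositive_values_cannot_be_log_transformed(self, rng):
        x = np.concatenate([[-1.0], rng.exponential(1.0, 499)])
        with pytest.raises(ChopgripError):
            ks_normality(x)


class TestMultinomialLogit:
    def test_known_cohabitation_effect_recovered(self):
        coefs = {("cohabitation", "three_finger"): math.log(0.15)}
        df = make_survey_table(n=5000, coefficients=coefs, seed=11)
        fit = fit_multinomial_logit(df)
        assert fit.odds_ratio("cohabitation", "three_finger") == pytest.approx(0.15, abs=0.05)

    def test_robust_covariance_keeps_point_estimates(self):
        df = make_survey_table(n=800, seed=2)
        plain = fit_multinomial_logit(df)
        robust = fit_multinomial_logit(df, robust=True)
        np.testing.assert_allclose(plain.table["or"], robust.table["or"], rtol=1e-8)
        assert not np.allclose(plain.table["se"], robust.table["se"])

    def test_listwise_deletion_drops_incomplete_rows(self):
        df = make_survey_table(n=400, missing_rate=0.05, seed=3)
        fit = fit_multinomial_logit(df)
        assert fit.n < 400

    def test_separation_diagnosed_with_predictor_name(self):
        df = make_survey_table(n=200, seed=9)
        df["cohabitation"] = (df["grip_class"] == "three_finger").astype(float)
        with pytest.raises(FitError, match="cohabitation"):
            fit_multinomial_logit(df)

    def test_wald_coverage_of_generating_coefficients(self):
        """The generating log-odds fall inside the Wald 95% CI in most
        replicates (parameter recovery at n = 2000)."""
        beta = math.log(0.3)
        hits = 0
        reps = 30
        for r in range(reps):
            df = make_survey_table(
                n=2000, coefficients={("cohabitation", "palm_other"): beta}, seed=100 + r
            )
            fit = fit_multinomial_logit(df)
            row = fit.table[
                (fit.table.predictor == "cohabitation")
                & (fit.table.contrast == "palm_other")
            ].iloc[0]
            if row["ci_low"] <= math.exp(beta) <= row["ci_high"]:
                hits += 1
        assert hits / reps >= 0.9


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == pytest.approx(0.0)

    def test_swapped_fits_rejected(self):
        with pytest.raises(FitError):
            nagelkerke_r2(-120.0, -100.0, 200)

    def test_huge_effect_approaches_one(self):
        # a strong continuous effect: DCDQ total nearly determines the class
        df = make_survey_table(
            n=3000,
            coefficients={
                ("dcdq_total", "three_finger"): 0.8,
                ("dcdq_total", "palm_other"): -0.8,
            },
            seed=8,
        )
        fit = fit_multinomial_logit(df)
        assert model_nagelkerke(fit) > 0.8

    def test_null_effects_give_small_r2(self):
        df = make_survey_table(n=3000, seed=14)
        fit = fit_multinomial_logit(df)
        assert model_nagelkerke(fit) < 0.05


class TestDescribeCohort:
    def test_cohort_marginals_match_generator_conditions(self):
        df = make_survey_table(n=2000, seed=17)
        out = describe_cohort(df)
        assert out["dcdq_total_mean"] == pytest.approx(51.25, abs=1.0)
        assert out["maternal_age_mean"] == pytest.approx(37.88, abs=0.6)
        assert out["maternal_taught_percent"] == pytest.approx(100 * 136 / 165, abs=4)
        assert set(out["dcdq"].index) == {
            "control_during_movement",
            "fine_motor_handwriting",
            "general_coordination",
            "dcdq_total",
        }

    def test_single_record_reports_missing_sd(self):
        df = make_survey_table(n=10, seed=0).head(1)
        out = describe_cohort(df)
        assert "± -" in out["dcdq"].iloc[-1, 0]

    def test_empty_table_rejected(self):
        with pytest.raises(ChopgripError):
            describe_cohort(pd.DataFrame())
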