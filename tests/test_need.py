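"""Need-rate estimation from survey microdata: strata, mapping, estimator, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import oralforce as of
from oralforce.errors import DataError
from oralforce.need import VISIT_TYPES


class TestStratumAssignment:
    @pytest.mark.parametrize(
        "sex,age,expected",
        [
            ("female", 44, ("female", "15-44")),  # upper edge inclusive
            ("female", 45, ("female", "45-64")),
            ("female", 65, ("female", "65-74")),
            ("male", 74, ("male", "65-74")),
            ("male", 75, ("male", "75+")),
            ("male", 101, ("male", "75+")),
            ("female", 15, ("female", "15-44")),
        ],
    )
    def test_band_edges(self, sex, age, expected):
        assert of.assign_stratum({"sex": sex, "age_years": age}) == expected

    def test_health_status_attached_on_request(self):
        rec = {
            "sex": "female",
            "age_years": 50,
            "natural_teeth_category": "some_missing",
            "food_pain_problem": True,
        }
        assert of.assign_stratum(rec, use_health_status=True) == (
            "female",
            "45-64",
            "some_missing",
            True,
        )

    def test_underage_rejected(self):
        with pytest.raises(ValueError):
            of.age_band(14)


class TestVisitsForRecord:
    mapping = {"once": 1, "twice": 2, "three_or_more": 3.5}

    def test_non_visitor_contributes_zero(self):
        assert of.visits_for_record({"visited_12m": False}, self.mapping) == 0.0

    @pytest.mark.parametrize("cat,expected", [("twice", 2), ("three_or_more", 3.5)])
    def test_mapping_lookup(self, cat, expected):
        rec = {"visited_12m": True, "frequency_category": cat}
        assert of.visits_for_record(rec, self.mapping) == expected

    def test_unknown_category_named_in_error(self):
        rec = {"visited_12m": True, "frequency_category": "weekly"}
        with pytest.raises(DataError, match="weekly"):
            of.visits_for_record(rec, self.mapping)


class TestEstimateNeedRates:
    def test_hand_counted_toy_stratum(self, toy_survey):
        # female 15-44: one visitor (twice, check-up) + one non-visitor -> 1.0/capita
        rates = of.estimate_need_rates(toy_survey)
        assert rates.rate("female", "15-44") == pytest.approx(1.0)
        assert rates.rate("female", "15-44", "checkup_exam_cleaning") == pytest.approx(1.0)
        assert rates.rate("female", "15-44", "routine_treatment") == 0.0
        # male 45-64: one visitor (once, emergency) + one non-visitor -> 0.5
        assert rates.rate("male", "45-64") == pytest.approx(0.5)
        assert rates.rate("male", "45-64", "emergency_treatment") == pytest.approx(0.5)

    def test_all_non_visitors_zero_rates(self):
        df = pd.DataFrame(
            {
                "sex": ["female"] * 3,
                "age_years": [20, 30, 40],
                "visited_12m": [False] * 3,
                "frequency_category": [None] * 3,
                "last_visit_type": [None] * 3,
            }
        )
        rates = of.estimate_need_rates(df)
        assert rates.rate("female", "15-44") == 0.0

    def test_type_split_sums_to_total(self, rates_5k):
        table = rates_5k.table[rates_5k.table["defined"]]
        np.testing.assert_allclose(
            table[list(VISIT_TYPES)].sum(axis=1), table["total"], atol=1e-9
        )

    def test_empty_strata_flagged_not_zeroed(self, toy_survey):
        rates = of.estimate_need_rates(toy_survey)
        assert ("female", "75+") in rates.undefined_strata
        assert np.isnan(rates.rate("female", "75+"))
        filled = rates.zero_filled()
        assert filled.rate("female", "75+") == 0.0

    def test_underage_filtered_with_count(self, toy_survey):
        extra = toy_survey.copy()
        extra.loc[len(extra)] = ["female", 10, "all_natural", False, False, None, None]
        rates = of.estimate_need_rates(extra)
        assert rates.n_dropped_underage == 1
        assert rates.rate("female", "15-44") == pytest.approx(1.0)

    def test_order_invariance(self, survey_5k):
        shuffled = survey_5k.sample(frac=1, random_state=3).reset_index(drop=True)
        a = of.estimate_need_rates(survey_5k).table
        b = of.estimate_need_rates(shuffled).table
        pd.testing.assert_frame_equal(a, b)

    def test_weight_scale_invariance(self, survey_5k):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.5, 2.0, len(survey_5k))
        a = of.estimate_need_rates(survey_5k.assign(weight=w), use_weights=True)
        b = of.estimate_need_rates(survey_5k.assign(weight=17.0 * w), use_weights=True)
        pd.testing.assert_frame_equal(
            a.table[list(VISIT_TYPES) + ["total"]], b.table[list(VISIT_TYPES) + ["total"]]
        )

    def test_recovery_within_monte_carlo_error(self, truth):
        survey = of.gen_survey(truth, 50_000, seed=5)
        est = of.estimate_need_rates(survey)
        expected = truth.expected_need_rates()
        for key, s in truth.strata.items():
            n_s = est.table.loc[key, "n_respondents"]
            # per-respondent visits: 0 w.p. 1-p, mapped count w.p. p x freq dist
            cats = list(of.DEFAULT_FREQUENCY_MAPPING)
            vals = np.array([of.DEFAULT_FREQUENCY_MAPPING[c] for c in cats])
            probs = s.participation * np.array([s.frequency_dist[c] for c in cats])
            ev = float((vals * probs).sum())
            var = float((vals**2 * probs).sum()) - ev**2
            se = np.sqrt(var / n_s)
            assert abs(est.table.loc[key, "total"] - expected.table.loc[key, "total"]) < 3 * se

    def test_consistency_error_shrinks_with_n(self, truth):
        expected = truth.expected_need_rates().table["total"]
        rmse = {}
        for n in (500, 50_000):
            est = of.estimate_need_rates(of.gen_survey(truth, n, seed=21)).table["total"]
            rmse[n] = float(np.sqrt(((est - expected) ** 2).mean()))
        # 100x the sample should shrink the error roughly 10x; demand at least 3x
        assert rmse[50_000] < rmse[500] / 3

    def test_health_status_stratification(self, survey_5k):
        rates = of.estimate_need_rates(survey_5k, use_health_status=True)
        assert rates.table.index.nlevels == 4
        table = rates.table
        np.testing.assert_allclose(
            table[list(VISIT_TYPES)].sum(axis=1), table["total"], atol=1e-9
        )


class TestBootstrap:
    def test_degenerate_single_resample(self, toy_survey):
        iv = of.bootstrap_need_rates(toy_survey, B=1, seed=9)
        pd.testing.assert_frame_equal(iv.lo, iv.hi)

    def test_deterministic_for_fixed_seed(self, survey_5k):
        a = of.bootstrap_need_rates(survey_5k, B=50, seed=13)
        b = of.bootstrap_need_rates(survey_5k, B=50, seed=13)
        pd.testing.assert_frame_equal(a.lo, b.lo)
        pd.testing.assert_frame_equal(a.hi, b.hi)

    def test_interval_brackets_point_estimate(self, survey_5k, rates_5k):
        iv = of.bootstrap_need_rates(survey_5k, B=200, seed=13)
        est = rates_5k.table.loc[iv.lo.index, "total"]
        assert (iv.lo["total"] <= est + 1e-12).all()
        assert (est <= iv.hi["total"] + 1e-12).all()

    def test_invalid_b_rejected(self, toy_survey):
        with pytest.raises(ValueError, match="B"):
            of.bootstrap_need_rates(toy_survey, B=0)

    def test_coverage_on_synthetic_data(self, truth):
        """Nominal 95% intervals cover the true stratum rates >= 90% of the
        time across 100 synthetic replicates at n=2000, B=500."""
        expected = truth.expected_need_rates().table
        covered = total = 0
        for rep in range(100):
            survey = of.gen_survey(truth, 2000, seed=1000 + rep)
            iv = of.bootstrap_need_rates(survey, B=500, seed=rep)
            hits = iv.covers(expected)
            covered += int(hits.sum())
            total += len(hits)
        assert covered / total >= 0.90
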