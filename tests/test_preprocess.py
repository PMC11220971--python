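"""Cohort construction: adjustment, composites, filters, scores, progression."""

import numpy as np
import pandas as pd
import pytest

from crtraj.preprocess import (
    activity_scores,
    adi_tertiles,
    adjust_hippocampal_volume,
    apply_inclusion_criteria,
    compute_pacc5,
    cr_residual,
    occupational_complexity,
    progression_events,
    threshold_flags,
)


class TestHippocampalAdjustment:
    def test_collinear_toy_exact_ols(self):
        adj, b, me = adjust_hippocampal_volume([7000, 7500, 8000], [1.4e6, 1.5e6, 1.6e6])
        assert b == pytest.approx(0.005)
        np.testing.assert_allclose(adj, [7500, 7500, 7500])

    def test_subject_at_mean_etiv_unchanged(self):
        rng = np.random.default_rng(0)
        etiv = rng.normal(1.5e6, 1e5, 50)
        raw = 7000 + 0.004 * (etiv - 1.5e6) + rng.normal(0, 300, 50)
        etiv[0] = etiv.mean() * 50 / 50  # will re-center below
        adj, b, me = adjust_hippocampal_volume(raw, etiv)
        # apply the formula at exactly the mean eTIV
        adj2, _, _ = adjust_hippocampal_volume(np.array([raw[0]]), np.array([me]),
                                               b=b, mean_etiv=me)
        assert adj2[0] == pytest.approx(raw[0])

    def test_constant_raw_volume_gives_zero_slope(self):
        adj, b, _ = adjust_hippocampal_volume([7000.0] * 5, [1.4e6, 1.5e6, 1.6e6, 1.45e6, 1.55e6])
        assert b == 0.0
        np.testing.assert_allclose(adj, 7000.0)

    def test_zero_etiv_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            adjust_hippocampal_volume([7000, 7100, 7200], [1.5e6] * 3)

    def test_adjusted_uncorrelated_with_etiv(self):
        rng = np.random.default_rng(1)
        etiv = rng.normal(1.5e6, 1.2e5, 200)
        raw = 7400 + 0.003 * (etiv - 1.5e6) + rng.normal(0, 500, 200)
        adj, _, _ = adjust_hippocampal_volume(raw, etiv)
        assert abs(np.corrcoef(adj, etiv)[0, 1]) < 1e-8


class TestPacc5:
    cols = ["mmse", "lmdr", "dsst", "fcsrt", "fluency"]

    def _frame(self, vals):
        return pd.DataFrame([vals], columns=self.cols)

    def test_all_at_reference_mean_is_zero(self):
        ref_m = dict(zip(self.cols, [27, 10, 40, 90, 20]))
        ref_s = dict(zip(self.cols, [2, 3, 8, 5, 4]))
        comp = compute_pacc5(self._frame([27, 10, 40, 90, 20]), ref_m, ref_s)
        assert comp.iloc[0] == pytest.approx(0.0)

    def test_one_component_one_sd_up(self):
        ref_m = dict(zip(self.cols, [0] * 5))
        ref_s = dict(zip(self.cols, [1] * 5))
        comp = compute_pacc5(self._frame([1, 0, 0, 0, 0]), ref_m, ref_s)
        assert comp.iloc[0] == pytest.approx(0.2)

    def test_lower_is_better_sign_flip(self):
        ref_m = dict(zip(self.cols, [0] * 5))
        ref_s = dict(zip(self.cols, [1] * 5))
        comp = compute_pacc5(self._frame([1, 0, 0, 0, 0]), ref_m, ref_s,
                             lower_is_better=("mmse",))
        assert comp.iloc[0] == pytest.approx(-0.2)

    def test_reference_cohort_mean_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (40, 5)), columns=self.cols)
        comp = compute_pacc5(df)
        assert comp.mean() == pytest.approx(0.0, abs=1e-10)

    def test_zero_reference_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            compute_pacc5(self._frame([1, 0, 0, 0, 0]),
                          dict.fromkeys(self.cols, 0), dict.fromkeys(self.cols, 0))


def _inclusion_tables():
    visits = pd.DataFrame([
        # s1: baseline 17 weeks before scan -> retained (3 visits)
        ("s1", "2015-01-01", 0.1), ("s1", "2016-01-05", 0.0), ("s1", "2017-01-02", -0.2),
        # s2: only one cognitive visit -> excluded
        ("s2", "2015-06-01", 0.3),
        # s3: all visits > 52 weeks from scan -> excluded
        ("s3", "2012-01-01", 0.2), ("s3", "2013-01-01", 0.1),
        # s4: retained, first visit same day as scan
        ("s4", "2015-03-01", 0.5), ("s4", "2016-03-10", 0.4),
        # s5: early retrospective visit dropped, still 2 in-window visits
        ("s5", "2010-01-01", 0.9), ("s5", "2015-02-01", 0.6), ("s5", "2016-02-20", 0.5),
    ], columns=["subject_id", "visit_date", "outcome"])
    base = pd.DataFrame({
        "subject_id": ["s1", "s2", "s3", "s4", "s5"],
        "scan_date": ["2015-04-29", "2015-06-01", "2015-06-01", "2015-03-01", "2015-01-15"],
        "baseline_age": [70, 71, 72, 73, 74.0],
        "sex": [1, 0, 1, 0, 1.0],
        "abeta": [1.1, 1.2, 1.3, 1.0, 1.4],
        "tau_ec": [1.2, 1.3, 1.4, 1.1, 1.5],
        "adj_hv": [7500, 7400, 7300, 7600, 7200.0],
    })
    return visits, base


class TestInclusion:
    def test_toy_table_three_survive(self):
        visits, base = _inclusion_tables()
        cohort, log = apply_inclusion_criteria(visits, base)
        assert set(cohort.subject_ids) == {"s1", "s4", "s5"}
        reasons = dict(zip(log["subject_id"], log["reason"]))
        assert reasons["s2"] == "insufficient timepoints"
        assert "window" in reasons["s3"]

    def test_retrospective_visits_dropped_and_time_origin(self):
        visits, base = _inclusion_tables()
        cohort, _ = apply_inclusion_criteria(visits, base)
        s5 = cohort.subject_table("s5")
        assert len(s5) == 2  # 2010 visit dropped
        assert s5["time"].iloc[0] == 0.0
        assert s5["time"].iloc[1] == pytest.approx((384) / 365.25, abs=1e-9)

    def test_idempotent(self):
        visits, base = _inclusion_tables()
        cohort, _ = apply_inclusion_criteria(visits, base)
        # re-express the retained cohort as date tables anchored at baseline
        again = cohort.visits.copy()
        again["visit_date"] = [
            (pd.Timestamp("2020-01-01") + pd.Timedelta(days=round(t * 365.25))).date().isoformat()
            for t in again["time"]]
        base2 = base[base["subject_id"].isin(cohort.subject_ids)].copy()
        base2["scan_date"] = "2020-01-01"
        cohort2, _ = apply_inclusion_criteria(again.drop(columns=["time"]), base2)
        assert cohort2.n_subjects == cohort.n_subjects
        assert len(cohort2.visits) == len(cohort.visits)


class TestCrResidual:
    def _table(self, n=10, seed=3):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "baseline_age": rng.normal(72, 8, n),
            "sex": (rng.random(n) < 0.5).astype(float),
            "abeta": rng.normal(1.2, 0.2, n),
            "tau_ec": rng.normal(1.3, 0.3, n),
            "adj_hv": rng.normal(7400, 800, n),
        })
        df["pacc5"] = (0.5 - 0.01 * df["baseline_age"] + 0.2 * df["sex"]
                       - 0.4 * df["abeta"] + rng.normal(0, 0.5, n))
        return df

    def test_matches_normal_equations_oracle(self):
        df = self._table()
        got = cr_residual(df)
        X = np.column_stack([np.ones(len(df)),
                             df[["baseline_age", "sex", "abeta", "tau_ec", "adj_hv"]]])
        y = df["pacc5"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s = np.sqrt(resid @ resid / (len(df) - 6))
        np.testing.assert_allclose(got.to_numpy(), resid / s, atol=1e-10)

    def test_mean_zero_and_unit_sd(self):
        df = self._table(n=100, seed=4)
        got = cr_residual(df)
        assert got.mean() == pytest.approx(0.0, abs=1e-10)
        n, p1 = len(df), 6
        # standardization uses residual SD on n - p - 1 df
        assert np.sqrt(got @ got / (n - p1)) == pytest.approx(1.0, abs=1e-8)

    def test_exact_linear_outcome_degenerate(self):
        df = self._table()
        df["pacc5"] = 1.0 + 0.01 * df["baseline_age"] - 0.2 * df["abeta"]
        with pytest.raises(ValueError, match="degenerate"):
            cr_residual(df)


class TestThresholds:
    def test_boundaries_are_negative(self):
        pos, atro = threshold_flags([1.185], [6723.0])
        assert not pos[0] and not atro[0]

    def test_just_below_atrophy_threshold_positive(self):
        _, atro = threshold_flags([1.0], [6722.9])
        assert atro[0]

    def test_table2_like_values(self):
        pos, atro = threshold_flags([1.27], [7141.0])
        assert pos[0] and not atro[0]


class TestActivityAndOccupation:
    def test_constant_items(self):
        df = pd.DataFrame({f"past_act_{i + 1}": [3] for i in range(25)} |
                          {f"curr_act_{i + 1}": [2] for i in range(11)})
        past, curr = activity_scores(df)
        assert past.iloc[0] == 3.0 and curr.iloc[0] == 2.0

    def test_alternating_items_arithmetic(self):
        vals = [1 if i % 2 == 0 else 5 for i in range(25)]  # 13 ones, 12 fives
        df = pd.DataFrame({f"past_act_{i + 1}": [v] for i, v in enumerate(vals)} |
                          {f"curr_act_{i + 1}": [3] for i in range(11)})
        past, _ = activity_scores(df)
        assert past.iloc[0] == pytest.approx(73 / 25)  # 2.92

    def test_missing_item_policy(self):
        df = pd.DataFrame({f"past_act_{i + 1}": [3.0] for i in range(25)} |
                          {f"curr_act_{i + 1}": [np.nan if i < 6 else 3.0] for i in range(11)})
        _, curr = activity_scores(df)
        assert np.isnan(curr.iloc[0])

    def test_occupational_complexity_range_and_arithmetic(self):
        assert occupational_complexity([0], [0], [0])[0] == 21.0
        assert occupational_complexity([6], [8], [7])[0] == 0.0
        assert occupational_complexity([3], [4], [3])[0] == 11.0

    def test_occupational_out_of_range(self):
        with pytest.raises(ValueError):
            occupational_complexity([7], [0], [0])


class TestAdiTertiles:
    def test_uniform_reference_cuts(self):
        ref = np.arange(1, 100)
        cats = adi_tertiles([10, 40, 80], ref)
        assert list(cats) == ["Lowest", "Intermediate", "Highest"]

    def test_value_below_first_cut(self):
        cats = adi_tertiles([1], np.arange(1, 100))
        assert cats[0] == "Lowest"

    def test_degenerate_reference_warns(self):
        with pytest.warns(UserWarning):
            cats = adi_tertiles([5, 5], [5, 5, 5])
        assert list(cats) == ["Lowest", "Lowest"]


class TestProgression:
    def _events(self, scores, times):
        df = pd.DataFrame({"subject_id": "x", "time": times, "cdr_global": scores})
        return progression_events(df).loc["x"]

    def test_two_consecutive_nonzero_event_at_first(self):
        ev = self._events([0, 0.5, 0.5], [0, 2, 3])
        assert ev["event"] and ev["time_to_event"] == 2

    def test_isolated_nonzero_censored(self):
        ev = self._events([0, 0.5, 0], [0, 2, 3])
        assert not ev["event"] and ev["time_to_event"] == 3

    def test_final_nonzero_is_event(self):
        ev = self._events([0, 0, 0.5], [0, 1, 2])
        assert ev["event"] and ev["time_to_event"] == 2

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError, match="CDR"):
            self._events([0, 3.0], [0, 1])
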