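"""PCM primitives against independent closed-form oracles; conditional
calibration recovery; equating-table properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import raschtraj as rt
from raschtraj.rasch_engine import (
    CategoryUseError,
    Item,
    ItemBank,
    equate_forms,
    pcm_category_probs,
    pcm_expected_score,
    pcm_score_variance,
    tcc,
    invert_tcc,
)
from raschtraj.synthetic_cohort import FormPlan

sorted_taus = st.lists(
    st.floats(-3, 3), min_size=1, max_size=8
).map(lambda v: np.sort(np.round(v, 6)))


class TestCategoryProbs:
    def test_dichotomous_at_threshold_is_half(self):
        p = pcm_category_probs(0.7, [0.7])
        assert np.allclose(p, [0.5, 0.5])

    def test_low_ability_limit_category_zero(self):
        p = pcm_category_probs(-30.0, [-1.0, 0.0, 1.0])
        assert p[0] > 1 - 1e-9

    def test_matches_direct_summation_oracle(self, probs_oracle):
        cases = [
            (0.0, [-1.0, 1.0]),
            (1.3, [-0.5, 0.2, 0.9]),
            (-2.0, [0.0]),
            (0.4, [-2.0, -1.0, 0.5, 2.5]),
        ]
        for theta, taus in cases:
            got = pcm_category_probs(theta, taus)
            want = probs_oracle(theta, taus)
            assert np.allclose(got, want, atol=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(theta=st.floats(-10, 10), taus=sorted_taus)
    def test_probabilities_form_a_distribution(self, theta, taus):
        p = pcm_category_probs(theta, taus)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-10


class TestExpectedScore:
    def test_dichotomous_at_threshold(self):
        assert pcm_expected_score(0.2, [0.2]) == pytest.approx(0.5)

    def test_high_ability_limit_is_max(self):
        assert pcm_expected_score(40.0, [-1, 0, 1]) == pytest.approx(3.0)

    def test_matches_log_partition_derivative(self):
        """E[X] is the derivative of the log partition function; check
        against a central finite difference of an independent oracle."""

        def log_partition(theta, taus):
            import math
            return math.log(
                sum(
                    math.exp(sum(theta - t for t in taus[:k]))
                    for k in range(len(taus) + 1)
                )
            )

        h = 1e-6
        for theta, taus in [(0.3, [-1.0, 0.4, 2.0]), (-1.1, [0.0]), (2.2, [-2, -1, 0, 1, 2])]:
            num = (log_partition(theta + h, taus) - log_partition(theta - h, taus)) / (2 * h)
            assert pcm_expected_score(theta, taus) == pytest.approx(num, abs=1e-6)

    @settings(max_examples=40, derandomize=True)
    @given(taus=sorted_taus)
    def test_strictly_increasing_in_theta(self, taus):
        grid = np.linspace(-6, 6, 25)
        vals = pcm_expected_score(grid, taus)
        assert np.all(np.diff(vals) > 0)


class TestTCC:
    def test_inversion_roundtrip(self, bank):
        ths = bank.thresholds_list()
        targets = np.array([1.0, 8.0, 12.0, 20.0, 23.5])
        theta = invert_tcc(targets, ths)
        assert np.allclose(tcc(theta, ths), targets, atol=1e-8)

    def test_rejects_out_of_range_targets(self, bank):
        with pytest.raises(ValueError):
            invert_tcc([0.0], bank.thresholds_list())


class TestCalibrate:
    def test_threshold_recovery(self, null_cohort, null_calibration, bank):
        """Calibration on simulated data recovers the generating bank."""
        errs = np.concatenate(
            [null_calibration.thresholds[i] - bank[i].thresholds
             for i in null_calibration.item_ids]
        )
        assert np.sqrt(np.mean(errs**2)) < 0.25  # n = 400 cohort fixture

    def test_loglik_nondecreasing(self, null_calibration):
        trace = np.asarray(null_calibration.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_theta_monotone_in_raw_total_within_form(self, null_calibration):
        persons = null_calibration.persons
        for _, sub in persons.groupby("session"):
            sub = sub.sort_values("raw_total")
            assert np.all(np.diff(sub["theta"]) >= -1e-9)

    def test_extreme_persons_flagged_and_finite(self, bank, no_dif_plan):
        spec = rt.default_cohort_spec(n_persons=150, dropout_rate=0.0, seed=2)
        resp, _ = rt.simulate_cohort(spec, plan=no_dif_plan)
        # force one person to the ceiling at session 1
        at = resp["session"] == 1
        pid = resp.loc[at, "person_id"].iloc[0]
        sel = (resp["person_id"] == pid) & at
        resp.loc[sel, "response"] = [
            bank[i].max_score for i in resp.loc[sel, "item_id"]
        ]
        calib = rt.calibrate(resp)
        row = calib.persons.query("person_id == @pid and session == 1").iloc[0]
        assert row["extreme"]
        assert np.isfinite(row["theta"]) and np.isfinite(row["se"])

    def test_identical_items_get_identical_thresholds(self):
        rng = np.random.default_rng(4)
        taus = np.array([-0.8, 0.3, 1.1])
        theta = rng.normal(0, 1.5, 500)
        rows = []
        for name in ("copy_a", "copy_b", "anchor"):
            p = pcm_category_probs(theta, taus)
            u = rng.random(theta.size)
            resp = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
            for j, r in enumerate(resp):
                rows.append(
                    {"person_id": f"p{j}", "session": 1, "item_id": name,
                     "response": int(r)}
                )
        calib = rt.calibrate(pd.DataFrame(rows))
        assert np.allclose(
            calib.thresholds["copy_a"], calib.thresholds["copy_b"], atol=0.35
        )

    def test_single_category_item_raises_collapse_error(self):
        rows = []
        for j in range(30):
            rows.append({"person_id": f"p{j}", "session": 1,
                         "item_id": "dead", "response": 0})
            rows.append({"person_id": f"p{j}", "session": 1,
                         "item_id": "live", "response": j % 3})
        with pytest.raises(CategoryUseError):
            rt.calibrate(pd.DataFrame(rows))

    def test_unused_middle_category_raises(self):
        rng = np.random.default_rng(0)
        rows = []
        for j in range(60):
            rows.append({"person_id": f"p{j}", "session": 1,
                         "item_id": "skip", "response": int(rng.choice([0, 2]))})
            rows.append({"person_id": f"p{j}", "session": 1,
                         "item_id": "ok", "response": int(rng.choice([0, 1, 2]))})
        with pytest.raises(CategoryUseError, match="category 1"):
            rt.calibrate(pd.DataFrame(rows))

    def test_item_locations_centred(self, null_calibration):
        assert abs(null_calibration.item_locations.mean()) < 1e-9

    def test_residuals_finite_where_observed(self, null_calibration):
        z = null_calibration.residuals.to_numpy()
        obs = ~np.isnan(null_calibration.observed.to_numpy())
        assert np.all(np.isfinite(z[obs]))


class TestEquateForms:
    def _bank(self, shift_b=0.0, shift_c=0.0):
        base = rt.make_default_item_bank()
        plan = FormPlan(
            dif_items=("fluency",),
            dif_shifts={("fluency", "A"): 0.0, ("fluency", "B"): shift_b,
                        ("fluency", "C"): shift_c},
        )
        return plan.bank_with_variants(base)

    def test_zero_shifts_tables_identical(self):
        tables = equate_forms(self._bank())
        by_form = {f: t.reset_index(drop=True) for f, t in tables.groupby("form")}
        for f in ("B", "C"):
            assert np.allclose(
                by_form["A"]["ref_score"], by_form[f]["ref_score"], atol=1e-9
            )

    def test_boundaries_map_to_themselves(self):
        tables = equate_forms(self._bank(shift_b=-0.8))
        for _, t in tables.groupby("form"):
            t = t.sort_values("raw")
            assert t["ref_score"].iloc[0] == 0.0
            assert t["ref_score"].iloc[-1] == 24.0

    def test_easier_form_equates_below_raw_at_midrange(self):
        """On a form with an easier fluency list, a mid-range raw total
        over-states ability, so its reference-form equivalent is lower."""
        tables = equate_forms(self._bank(shift_b=-0.8))
        b = tables.query("form == 'B' and raw == 12").iloc[0]
        assert b["ref_score"] < 12.0

    def test_tables_monotone(self):
        tables = equate_forms(self._bank(shift_b=-0.8, shift_c=0.5))
        for _, t in tables.groupby("form"):
            t = t.sort_values("raw")
            assert np.all(np.diff(t["theta"]) >= 0)
            assert np.all(np.diff(t["ref_score"]) >= 0)

    def test_unknown_reference_form_rejected(self):
        with pytest.raises(KeyError):
            equate_forms(self._bank(), ref_form="Z")
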