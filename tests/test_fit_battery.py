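"""Class intervals, fit residuals, unidimensionality, dependency,
targeting and person separation, with constructed misfit cases."""

import numpy as np
import pandas as pd
import pytest

import raschtraj as rt
from raschtraj.fit_battery import (
    assign_class_intervals,
    item_fit,
    person_fit,
    person_separation_index,
    response_dependency,
    targeting_summary,
    unidimensionality_test,
    full_fit_report,
)
from raschtraj.rasch_engine import pcm_category_probs


def _simulate_items(theta, banks, rng):
    """Sample long-format responses for arbitrary per-item ability vectors."""
    rows = []
    for item_id, (taus, th) in banks.items():
        p = pcm_category_probs(th, taus)
        u = rng.random(th.size)
        resp = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
        for j, r in enumerate(resp):
            rows.append({"person_id": f"p{j:04d}", "session": 1,
                         "item_id": item_id, "response": int(r)})
    return pd.DataFrame(rows)


class TestClassIntervals:
    def test_even_split(self):
        labels = assign_class_intervals(np.arange(10, dtype=float), 2)
        assert np.bincount(labels).tolist() == [5, 5]

    def test_extra_member_goes_to_lower_interval(self):
        labels = assign_class_intervals(np.arange(11, dtype=float), 2)
        assert np.bincount(labels).tolist() == [6, 5]

    def test_interval_means_increase(self, null_calibration):
        theta = null_calibration.persons["theta"].to_numpy()
        labels = assign_class_intervals(theta, 5)
        means = [theta[labels == g].mean() for g in range(5)]
        assert np.all(np.diff(means) > 0)

    def test_too_few_persons_suggests_fewer_intervals(self):
        with pytest.raises(ValueError, match="fewer intervals"):
            assign_class_intervals(np.array([0.0, 1.0]), 5)


class TestItemFit:
    def test_well_fitting_data_unflagged(self, null_calibration):
        fit = item_fit(null_calibration)
        assert int(fit["misfit"].sum() + fit["overfit"].sum()) <= 1
        assert (fit["df"] == 4).all()

    def test_noise_item_misfits(self):
        """An item answered at random ignores the latent trait and must
        show a large positive fit residual."""
        rng = np.random.default_rng(8)
        n = 800
        theta = rng.normal(0, 1.5, n)
        banks = {
            f"item{i}": (np.array([-1.0, 0.0, 1.0]) + loc, theta)
            for i, loc in enumerate((-0.5, 0.0, 0.5, -0.2, 0.2))
        }
        table = _simulate_items(theta, banks, rng)
        noise = pd.DataFrame(
            {"person_id": [f"p{j:04d}" for j in range(n)], "session": 1,
             "item_id": "noise", "response": rng.integers(0, 4, n)}
        )
        calib = rt.calibrate(pd.concat([table, noise], ignore_index=True))
        fit = item_fit(calib).set_index("item_id")
        assert fit.loc["noise", "fit_residual"] > 2.5

    def test_duplicated_item_overfits(self):
        """A verbatim duplicate adds no independent information; its
        residuals are too small and the fit residual goes negative."""
        rng = np.random.default_rng(9)
        n = 800
        theta = rng.normal(0, 1.5, n)
        banks = {
            f"item{i}": (np.array([-1.0, 0.0, 1.0]) + loc, theta)
            for i, loc in enumerate((-0.5, 0.0, 0.5))
        }
        table = _simulate_items(theta, banks, rng)
        dup = table.query("item_id == 'item0'").assign(item_id="item0_copy")
        calib = rt.calibrate(pd.concat([table, dup], ignore_index=True))
        fit = item_fit(calib).set_index("item_id")
        assert min(fit.loc["item0", "fit_residual"],
                   fit.loc["item0_copy", "fit_residual"]) < -2.5


class TestUnidimensionality:
    def test_unidimensional_data_passes(self, null_calibration):
        res = unidimensionality_test(null_calibration)
        assert res.verdict == "unidimensional"

    def test_two_factor_data_violates(self):
        """Items driven by two independent latents must fail the subset
        t-test comparison."""
        rng = np.random.default_rng(10)
        n = 700
        th_a = rng.normal(0, 1.5, n)
        th_b = rng.normal(0, 1.5, n)
        banks = {}
        for i in range(3):
            banks[f"a{i}"] = (np.array([-1.0, 0.0, 1.0]), th_a)
            banks[f"b{i}"] = (np.array([-1.0, 0.0, 1.0]), th_b)
        table = _simulate_items(None, banks, rng)
        calib = rt.calibrate(table)
        res = unidimensionality_test(calib)
        assert res.verdict == "violated"
        assert res.proportion > 0.05

    def test_zero_proportion_is_unidimensional(self, null_calibration):
        res = unidimensionality_test(null_calibration)
        if res.n_outside == 0:
            assert res.verdict == "unidimensional"


class TestResponseDependency:
    def test_independent_items_unflagged(self, null_calibration):
        dep = response_dependency(null_calibration)
        assert not dep["flagged"].any()

    def test_duplicate_item_pair_flagged(self):
        rng = np.random.default_rng(12)
        n = 500
        theta = rng.normal(0, 1.5, n)
        banks = {
            f"item{i}": (np.array([-1.0, 0.0, 1.0]) + loc, theta)
            for i, loc in enumerate((-0.5, 0.0, 0.5))
        }
        table = _simulate_items(theta, banks, rng)
        dup = table.query("item_id == 'item0'").assign(item_id="item0_copy")
        calib = rt.calibrate(pd.concat([table, dup], ignore_index=True))
        dep = response_dependency(calib)
        pair = dep.query(
            "item_a == 'item0' and item_b == 'item0_copy'"
        ).iloc[0]
        assert pair["flagged"] and pair["r"] > 0.3

    def test_threshold_one_never_flags(self, null_calibration):
        dep = response_dependency(null_calibration, threshold=1.0)
        assert not dep["flagged"].any()


class TestTargeting:
    def test_matched_cohort_covered_and_centred(self, no_dif_plan):
        """A cohort centred where the bank is centred (expected total at
        theta 0) yields person estimates near 0 and full coverage."""
        bank = rt.make_default_item_bank()
        centre = float(rt.tcc([0.0], bank.thresholds_list())[0])
        spec = rt.default_cohort_spec(
            n_persons=400, group_weights=(1.0,), group_intercepts=(centre,),
            group_slopes=(0.0,), residual_sd=3.5, dropout_rate=0.0, seed=21,
        )
        responses, _ = rt.simulate_cohort(spec, plan=no_dif_plan)
        calib = rt.calibrate(responses)
        t = targeting_summary(calib)
        assert abs(t.person_mean) < 0.25
        assert t.covered

    def test_mistargeted_persons_not_covered(self, null_cohort):
        _, responses, _ = null_cohort
        calib = rt.calibrate(responses)
        # shift all person estimates far above every threshold
        calib.persons["theta"] = calib.persons["theta"] + 50.0
        t = targeting_summary(calib)
        assert not t.covered


class TestPSI:
    def test_zero_se_gives_one(self):
        persons = pd.DataFrame(
            {"theta": [-1.0, 0.0, 1.0, 2.0], "se": 0.0, "extreme": False}
        )
        psi, _ = person_separation_index(persons)
        assert psi == pytest.approx(1.0)

    def test_floor_at_zero_when_noise_dominates(self):
        persons = pd.DataFrame(
            {"theta": [0.0, 0.1, -0.1, 0.05], "se": 5.0, "extreme": False}
        )
        psi, _ = person_separation_index(persons)
        assert psi == 0.0

    def test_zero_variance_errors(self):
        persons = pd.DataFrame(
            {"theta": [1.0, 1.0, 1.0], "se": 0.5, "extreme": False}
        )
        with pytest.raises(ValueError):
            person_separation_index(persons)

    def test_matches_variance_decomposition_oracle(self, null_calibration):
        psi, _ = person_separation_index(null_calibration.persons)
        sub = null_calibration.persons.query("~extreme")
        # independent recomputation: reliability = true variance share
        obs_var = float(np.var(sub["theta"], ddof=1))
        err_var = float(np.mean(np.square(sub["se"])))
        want = max(0.0, (obs_var - err_var) / obs_var)
        assert psi == pytest.approx(want, abs=0.05)


def test_full_report_renders(null_calibration):
    report = full_fit_report(null_calibration)
    text = report.to_text()
    for fragment in ("Threshold order", "Unidimensionality",
                     "Response dependency", "Targeting", "Person separation"):
        assert fragment in text
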