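"""Half-SD criterion arithmetic, Bland-Altman agreement, adjudication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import raschtraj as rt
from raschtraj.gbta import fit_gbta
from raschtraj.practice_effect import (
    adjudicate,
    bland_altman,
    change_over_period,
    criterion_from_sd,
    half_sd_criterion,
    overall_first_last_test,
)


class TestChangeOverPeriod:
    @pytest.mark.parametrize(
        "slope,se,months,change,change_se",
        [
            (0.36, 0.12, 6.0, 2.16, 0.72),
            (0.24, 0.11, 6.0, 1.44, 0.66),
            (0.47, 0.21, 6.0, 2.82, 1.26),
            (0.0, 0.5, 6.0, 0.0, 3.0),
        ],
    )
    def test_slope_times_months(self, slope, se, months, change, change_se):
        got = change_over_period(slope, se, months)
        assert got[0] == pytest.approx(change, abs=1e-12)
        assert got[1] == pytest.approx(change_se, abs=1e-12)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            change_over_period(0.3, 0.1, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(slope=st.floats(-2, 2), se=st.floats(0, 2), months=st.floats(0.1, 24))
    def test_exact_scaling_identity(self, slope, se, months):
        change, change_se = change_over_period(slope, se, months)
        assert change == slope * months
        assert change_se == se * months


class TestHalfSDCriterion:
    def test_baseline_sd_4_4_gives_2_2(self):
        assert criterion_from_sd(4.4) == pytest.approx(2.2, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            half_sd_criterion([10.0, 10.0])

    def test_sample_sd_uses_n_minus_1(self):
        x = [10.0, 12.0, 14.0]
        assert half_sd_criterion(x) == pytest.approx(0.5 * np.std(x, ddof=1))

    def test_synthetic_baseline_recovers_criterion(self):
        """A generator tuned to baseline SD 4.4 yields a criterion near
        2.2 at n = 1000 (sampling-error bound)."""
        rng = np.random.default_rng(0)
        scores = 14.4 + 4.4 * rng.standard_normal(1000)
        assert half_sd_criterion(scores) == pytest.approx(2.2, abs=0.15)


class TestBlandAltman:
    def test_identical_sessions_degenerate(self):
        x = np.array([10.0, 12.0, 14.0, 16.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0
        assert ba.loa_low == ba.loa_high == 0.0
        assert ba.n_outside == 0

    def test_constant_shift(self):
        x = np.array([10.0, 12.0, 14.0])
        ba = bland_altman(x, x + 2.0)
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.loa_low == ba.loa_high == pytest.approx(2.0)
        assert ba.n_outside == 0

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_gaussian_coverage_near_five_percent(self):
        """With Gaussian differences the fraction outside mean +/- 1.96 SD
        must sit inside the binomial 95% CI of 5% at n = 1000."""
        rng = np.random.default_rng(123)
        n = 1000
        first = rng.normal(14, 4, n)
        last = first + rng.normal(0.5, 1.5, n)
        ba = bland_altman(first, last)
        p = ba.n_outside / n
        half = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= p <= 0.05 + half

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(5)
        first = rng.normal(14, 4, 50)
        last = first + rng.normal(0, 2, 50)
        ba = bland_altman(first, last)
        assert (ba.loa_high - ba.mean_diff) == pytest.approx(
            ba.mean_diff - ba.loa_low
        )


class TestOverallTest:
    def test_no_change_gives_half(self):
        x = np.array([10.0, 12.0, 15.0])
        stat, p = overall_first_last_test(x, x)
        assert stat == 0.0 and p == 0.5

    def test_large_uniform_improvement_significant(self):
        rng = np.random.default_rng(1)
        first = rng.normal(12, 3, 60)
        last = first + 3.0 + rng.normal(0, 0.5, 60)
        _, p = overall_first_last_test(first, last)
        assert p < 0.001

    def test_type_one_error_near_nominal(self):
        """Null simulation: one-tailed rejections at 5% stay within the
        binomial 95% CI over 500 replicates."""
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 500
        for _ in range(reps):
            first = rng.normal(14, 4, 40)
            last = first + rng.normal(0, 2, 40)
            _, p = overall_first_last_test(first, last)
            rejections += p < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rejections / reps <= 0.05 + half


def _model_with(slopes, slope_ses, intercepts, n_per_group=10, seed=0):
    """Build a fitted-looking trajectory model via a real fit on separated
    data, then overwrite the coefficient table with the quantities under
    adjudication."""
    rng = np.random.default_rng(seed)
    rows = []
    k = len(slopes)
    pid = 0
    for g in range(k):
        for _ in range(n_per_group):
            for m in (0.0, 3.0, 6.0):
                rows.append(
                    {"person_id": f"p{pid:03d}", "month": m,
                     "score": intercepts[g] + rng.normal(0, 0.3)}
                )
            pid += 1
    model = fit_gbta(pd.DataFrame(rows), K=k, n_starts=3, seed=seed)
    model.beta[:, 0] = np.asarray(intercepts, dtype=float)
    model.beta[:, 1] = np.asarray(slopes, dtype=float)
    model.beta_se[:, 1] = np.asarray(slope_ses, dtype=float)
    return model


class TestAdjudicate:
    def test_only_highest_group_exceeds_printed_criterion(self):
        """Changes 2.16/1.44/2.82 against criterion 2.2: only the
        highest-intercept group exceeds."""
        model = _model_with(
            slopes=(0.36, 0.24, 0.47), slope_ses=(0.12, 0.11, 0.21),
            intercepts=(9.2, 14.9, 18.7),
        )
        x = np.linspace(8, 20, 30)
        ba = bland_altman(x, x + 0.5)
        report = adjudicate(model, criterion=2.2, ba=ba, period_months=6.0)
        exceeds = [g.exceeds_criterion for g in report.groups]
        assert exceeds == [False, False, True]

    def test_zero_slopes_no_practice_effect(self):
        model = _model_with(
            slopes=(0.0, 0.0, 0.0), slope_ses=(0.1, 0.1, 0.1),
            intercepts=(9.0, 15.0, 19.0),
        )
        x = np.linspace(8, 20, 30)
        ba = bland_altman(x, x + 0.1)
        report = adjudicate(model, criterion=2.2, ba=ba)
        assert all(g.verdict == "no practice effect" for g in report.groups)

    def test_exceeding_group_without_outliers_is_within_error(self):
        model = _model_with(
            slopes=(0.36, 0.24, 0.47), slope_ses=(0.12, 0.11, 0.21),
            intercepts=(9.2, 14.9, 18.7),
        )
        x = np.linspace(8, 20, 30)
        ba = bland_altman(x, x + 0.5)  # constant-ish shift, no outliers
        report = adjudicate(model, criterion=2.2, ba=ba)
        assert report.groups[2].verdict == "change within measurement error"

    def test_change_identity_holds_exactly(self):
        model = _model_with(
            slopes=(0.36, 0.24, 0.47), slope_ses=(0.12, 0.11, 0.21),
            intercepts=(9.2, 14.9, 18.7),
        )
        x = np.linspace(8, 20, 30)
        ba = bland_altman(x, x + 0.5)
        report = adjudicate(model, criterion=2.2, ba=ba, period_months=6.0)
        for g, slope, se in zip(report.groups, (0.36, 0.24, 0.47), (0.12, 0.11, 0.21)):
            assert g.change == slope * 6.0
            assert g.change_se == se * 6.0

    def test_markdown_report_renders(self):
        model = _model_with(
            slopes=(0.36, 0.24, 0.47), slope_ses=(0.12, 0.11, 0.21),
            intercepts=(9.2, 14.9, 18.7),
        )
        x = np.linspace(8, 20, 30)
        ba = bland_altman(x, x + 0.5)
        report = adjudicate(model, criterion=2.2, ba=ba,
                            overall=(1.6, 0.06))
        text = report.to_markdown()
        assert "Criterion value: 2.2" in text
        assert "Bland-Altman" in text
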