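"""Agreement statistics against hand arithmetic and numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from dbstdm.agreement import (
    AgreementError,
    bland_altman,
    deming_regression,
    ema_within_20,
    evaluate_model,
    predictive_errors,
)
from dbstdm.conversion import fit_linear, hct_model
from dbstdm.synth import SimulationConfig, generate_paired_dataset

positive_floats = st.floats(0.5, 200.0, allow_nan=False)


class TestDeming:
    def test_identity_line(self):
        x = np.array([1.0, 4.0, 7.0, 9.0])
        res = deming_regression(x, x)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_affine(self):
        x = np.array([2.0, 3.0, 5.0, 11.0])
        for lam in (0.5, 1.0, 4.0):
            res = deming_regression(x, 2 * x + 1, lambda_ratio=lam)
            assert res.slope == pytest.approx(2.0, rel=1e-12)
            assert res.intercept == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("lam", [1.0, 2.5])
    def test_matches_orthogonal_distance_oracle(self, rng, lam):
        """Closed-form slope equals a 2-D numerical minimiser of the
        lambda-scaled orthogonal squared distances."""
        x = rng.uniform(2, 50, size=6)
        y = 1.1 * x - 0.5 + rng.normal(0, 2.0, size=6)

        def objective(p):
            a, b = p
            return np.sum((y - a - b * x) ** 2 / (lam + b * b))

        num = minimize(objective, [0.0, 1.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        res = deming_regression(x, y, lambda_ratio=lam)
        assert res.slope == pytest.approx(num.x[1], rel=1e-6)
        assert res.intercept == pytest.approx(num.x[0], rel=1e-5, abs=1e-6)

    def test_swap_inverts_slope(self, rng):
        """slope(x,y) * slope(y,x) >= 1, with equality on noiseless data."""
        x = rng.uniform(1, 30, size=10)
        y_clean = 1.7 * x + 0.3
        s1 = deming_regression(x, y_clean).slope
        s2 = deming_regression(y_clean, x).slope
        assert s1 * s2 == pytest.approx(1.0, rel=1e-10)
        y = y_clean + rng.normal(0, 1.5, size=10)
        assert deming_regression(x, y).slope * deming_regression(y, x).slope >= 1.0 - 1e-12

    def test_ci_covers_point_estimate(self, rng):
        x = rng.uniform(1, 30, size=12)
        y = x + rng.normal(0, 1, size=12)
        res = deming_regression(x, y)
        assert res.slope_ci[0] < res.slope < res.slope_ci[1]
        assert res.intercept_ci[0] < res.intercept < res.intercept_ci[1]

    def test_degenerate_inputs(self):
        with pytest.raises(AgreementError):
            deming_regression([1, 2], [1, 2])
        with pytest.raises(AgreementError):
            deming_regression([3, 3, 3], [1, 2, 3])
        with pytest.raises(AgreementError):  # S_xy = 0
            deming_regression([1, 2, 1, 2], [1, 1, 2, 2])


class TestBlandAltman:
    def test_equal_series(self):
        a = np.array([2.0, 5.0, 9.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0 and res.loa == (0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([2.0, 5.0, 9.0])
        res = bland_altman(a + 1, a)
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert res.loa[0] == pytest.approx(1.0) and res.loa[1] == pytest.approx(1.0)

    def test_monte_carlo_matches_closed_form(self):
        """LoA of simulated Normal(0.5, 1) differences land at 0.5 +/- 1.96."""
        rng = np.random.default_rng(42)
        b = rng.uniform(5, 50, size=10_000)
        a = b + rng.normal(0.5, 1.0, size=10_000)
        res = bland_altman(a, b)
        assert res.loa[0] == pytest.approx(0.5 - 1.96, abs=0.05)
        assert res.loa[1] == pytest.approx(0.5 + 1.96, abs=0.05)

    def test_antisymmetry_and_width(self, rng):
        a = rng.uniform(1, 20, 15)
        b = rng.uniform(1, 20, 15)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.bias == pytest.approx(-r2.bias)
        width = r1.loa[1] - r1.loa[0]
        assert width == pytest.approx(r2.loa[1] - r2.loa[0])
        assert width == pytest.approx(2 * 1.96 * r1.sd_diff)
        assert r1.loa[0] <= r1.bias <= r1.loa[1]

    def test_too_few_pairs(self):
        with pytest.raises(AgreementError):
            bland_altman([1.0], [2.0])


class TestEmaCriterion:
    def test_all_equal_passes(self):
        a = np.array([3.0, 8.0, 12.0])
        frac, ok = ema_within_20(a, a)
        assert frac == 1.0 and ok

    @pytest.mark.parametrize(
        "pair, within",
        [((10.0, 13.0), False), ((10.0, 12.0), True)],  # 3 > 2.3 vs 2 <= 2.2
    )
    def test_hand_worked_pairs(self, pair, within):
        frac, ok = ema_within_20([pair[0]], [pair[1]])
        assert frac == (1.0 if within else 0.0)
        assert ok is within

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        a=st.lists(positive_floats, min_size=2, max_size=12),
        scale=st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, a, scale):
        a = np.asarray(a)
        b = a[::-1].copy()
        assert ema_within_20(a, b)[0] == ema_within_20(scale * a, scale * b)[0]

    def test_nonpositive_pairs_excluded(self):
        frac, _ = ema_within_20([10.0, 0.0], [10.0, 0.0])
        assert frac == 1.0  # the zero-mean pair is excluded, not counted


class TestPredictiveErrors:
    @pytest.mark.parametrize(
        "pred, obs, expected",
        [
            ([5.0, 9.0], [5.0, 9.0], (0.0, 0.0)),
            ([11.0], [10.0], (10.0, 10.0)),
            ([9.0, 13.0], [10.0, 10.0], (10.0, 20.0)),  # pe = {-10, +30}
        ],
    )
    def test_mean_centered_examples(self, pred, obs, expected):
        assert predictive_errors(pred, obs) == pytest.approx(expected)

    def test_median_center(self):
        mppe, mape = predictive_errors([9.0, 13.0, 10.5], [10.0, 10.0, 10.0], center="median")
        assert (mppe, mape) == pytest.approx((5.0, 10.0))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        pred=st.lists(positive_floats, min_size=1, max_size=15),
        obs=st.lists(positive_floats, min_size=1, max_size=15),
    )
    def test_mape_bounds_mppe(self, pred, obs):
        n = min(len(pred), len(obs))
        mppe, mape = predictive_errors(pred[:n], obs[:n])
        assert mape >= abs(mppe) - 1e-9

    def test_zero_observed_rejected(self):
        with pytest.raises(AgreementError):
            predictive_errors([1.0], [0.0])


class TestEvaluateModel:
    def test_self_consistency_on_noiseless_linear_data(self):
        dbs = np.linspace(4, 80, 12)
        serum = dbs / 1.17 + 1.04
        fit = fit_linear(dbs, serum)
        rep = evaluate_model(serum, dbs, fit)
        assert rep.deming_slope == pytest.approx(1.0, abs=1e-9)
        assert rep.deming_intercept == pytest.approx(0.0, abs=1e-8)
        assert rep.ba_bias == pytest.approx(0.0, abs=1e-10)
        assert rep.ema_fraction == 1.0 and rep.ema_pass
        assert rep.mppe_pct == pytest.approx(0.0, abs=1e-10)
        assert rep.mape_pct == pytest.approx(0.0, abs=1e-10)

    def test_hct_model_biased_on_structureless_data(self, default_dataset):
        """Dividing by (1-HCT) overcorrects data generated without any HCT
        dependence, so the parameter-free model shows a larger bias than
        the fitted linear model."""
        df = default_dataset
        fit = fit_linear(df["dbsv_mgL"], df["serum_mgL"])
        rep_lin = evaluate_model(df["serum_mgL"], df["dbsv_mgL"], fit)
        rep_hct = evaluate_model(df["serum_mgL"], df["dbsv_mgL"], hct_model(), hct=df["hct"])
        assert abs(rep_hct.ba_bias) > abs(rep_lin.ba_bias)
        assert rep_hct.deming_slope > 1.5  # systematic overprediction

    def test_report_internal_consistency(self, default_dataset):
        df = default_dataset
        fit = fit_linear(df["dbsv_mgL"], df["serum_mgL"])
        rep = evaluate_model(df["serum_mgL"], df["dbsv_mgL"], fit)
        assert rep.ba_loa[0] <= rep.ba_bias <= rep.ba_loa[1]
        assert 0.0 <= rep.ema_fraction <= 1.0
        assert rep.mape_pct >= abs(rep.mppe_pct)
        assert rep.direction == "predicted - measured"
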