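"""Assay-validation metrics against hand arithmetic and a permutation ANOVA."""

import numpy as np
import pytest

from dbstdm.validation import (
    QCRun,
    ValidationError,
    accuracy_pct,
    dilution_integrity,
    fit_calibration,
    hct_effect,
    precision_rsd,
    recovery_pct,
    selectivity_anova,
    stability_deviation,
    validation_report,
)


class TestCalibration:
    def test_exact_line(self):
        nominal = np.array([3.0, 4.0, 6.0, 9.0, 12.0])
        cal = fit_calibration(nominal, 0.1 * nominal + 0.2)
        assert cal.slope == pytest.approx(0.1)
        assert cal.intercept == pytest.approx(0.2)
        assert cal.r2 == pytest.approx(1.0)
        assert all(abs(d) < 1e-9 for d in cal.back_calc_devs_pct.values())
        assert all(cal.dev_flags.values())

    def test_lloq_deviation_fails_20pct_bound(self):
        # a calibrator back-calculating 3 -> 3.7 deviates +23.3% and fails
        dev = 100 * (3.7 - 3.0) / 3.0
        assert dev == pytest.approx(23.3, abs=0.05)
        nominal = np.array([3.0, 6.0, 9.0, 12.0])
        # residuals orthogonal to (1, nominal): OLS stays slope 0.1, intercept 0,
        # and the LLOQ calibrator back-calculates to exactly 0.37/0.1 = 3.7
        residual = np.array([0.07, -0.105, 0.0, 0.035])
        cal = fit_calibration(nominal, 0.1 * nominal + residual)
        assert cal.slope == pytest.approx(0.1, rel=1e-10)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.back_calc_devs_pct[3.0] == pytest.approx(23.3, abs=0.05)
        assert not cal.dev_flags[3.0]

    def test_two_levels_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([3.0, 3.0, 12.0], [0.3, 0.31, 1.2])


class TestAccuracyPrecision:
    @pytest.mark.parametrize(
        "measured, nominal, expected",
        [(5.3, 5.0, 106.0), (11.1, 10.0, 111.0), (7.7, 7.7, 100.0)],
    )
    def test_accuracy_examples(self, measured, nominal, expected):
        assert accuracy_pct(measured, nominal) == pytest.approx(expected)

    def test_accuracy_scale_invariant(self):
        assert accuracy_pct(5.3, 5.0) == pytest.approx(accuracy_pct(53.0, 50.0))

    def test_rsd_examples(self):
        assert precision_rsd([7.0, 7.0, 7.0]) == 0.0
        assert precision_rsd([4.0, 5.0, 6.0]) == pytest.approx(20.0)
        assert precision_rsd([4.0, 5.0, 6.0]) == pytest.approx(precision_rsd([8.0, 10.0, 12.0]))

    def test_rsd_needs_replicates(self):
        with pytest.raises(ValidationError):
            precision_rsd([5.0])


class TestRecovery:
    def test_identical_sets(self):
        pct, sd = recovery_pct([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert pct == pytest.approx(100.0)

    def test_ratio_of_means(self):
        pct, sd = recovery_pct([0.88, 0.90, 0.92], [0.98, 1.00, 1.02])
        assert pct == pytest.approx(90.0)
        assert sd > 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            recovery_pct([], [1.0])


class TestHctEffect:
    def test_reference_level_is_100(self):
        out = hct_effect({0.25: [5.8], 0.4: [5.1], 0.55: [5.5]})
        assert out[0.4][0] == pytest.approx(100.0)
        assert out[0.4][1]

    def test_ratio_and_flags(self):
        out = hct_effect({0.25: [5.8], 0.4: [5.1]})
        assert out[0.25][0] == pytest.approx(100 * 5.8 / 5.1, rel=1e-12)  # 113.7%
        assert out[0.25][1]
        out = hct_effect({0.25: [6.0], 0.4: [5.0]})
        assert out[0.25] == (pytest.approx(120.0), False)

    def test_missing_reference(self):
        with pytest.raises(ValidationError):
            hct_effect({0.25: [5.8]})


class TestStabilityAndDilution:
    def test_stability_examples(self):
        assert stability_deviation([10.0], [10.0]) == (0.0, True)
        dev, ok = stability_deviation([7.49], [10.0])
        assert dev == pytest.approx(-25.1) and not ok
        dev, ok = stability_deviation([8.6], [10.0])
        assert dev == pytest.approx(-14.0) and ok

    def test_dilution_examples(self):
        acc, rsd, ok = dilution_integrity(120.0, [12.0, 12.0, 12.0], 10)
        assert acc == pytest.approx(100.0) and ok
        acc, _, ok = dilution_integrity(120.0, [11.34], 10)
        assert acc == pytest.approx(94.5) and ok
        acc, _, ok = dilution_integrity(30.0, [5.0], 5)
        assert acc == pytest.approx(83.3, abs=0.05) and not ok


class TestSelectivityAnova:
    def test_identical_groups(self):
        f, p, pairwise = selectivity_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert f == 0.0 and p == 1.0
        assert pairwise[("a", "b")] == 1.0

    def test_matches_hand_anova_table(self):
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [1.0, 2.0, 3.0], "g3": [4.0, 5.0, 6.0]}
        f, p, _ = selectivity_anova(groups)
        # hand decomposition: grand mean 3, SSB = 3*(1+1+4)... recompute directly
        allv = np.concatenate([np.asarray(v, float) for v in groups.values()])
        gm = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - gm) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_hand = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_hand, rel=1e-12)

    def test_agrees_with_permutation(self, rng):
        """Closed-form ANOVA p agrees with a permutation approximation."""
        from scipy import stats

        groups = {
            0.2: rng.normal(1.0, 0.1, 5),
            0.4: rng.normal(1.05, 0.1, 5),
            0.6: rng.normal(1.2, 0.1, 5),
        }
        f_obs, p, _ = selectivity_anova(groups)
        allv = np.concatenate(list(groups.values()))
        sizes = [len(v) for v in groups.values()]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(allv)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            count += stats.f_oneway(*parts)[0] >= f_obs
        assert p == pytest.approx(count / n_perm, abs=0.02)


class TestValidationReport:
    def test_simulated_runs_all_pass(self, rng):
        """5 days x 5 replicates at CV 6% stays within the 15%/20% limits."""
        runs = []
        for level, nominal in [("LLOQ", 3.0), ("QC_L", 5.0), ("QC_M", 8.0), ("QC_H", 10.0)]:
            for day in range(1, 6):
                vals = nominal * rng.lognormal(0, 0.06, size=5)
                runs.append(QCRun(level, nominal, vals.tolist(), day=day))
        rep = validation_report(runs)
        for level in ("LLOQ", "QC_L", "QC_M", "QC_H"):
            inter = rep["levels"][level]["inter_day"]
            assert inter["n"] == 25
            assert inter["rsd_pct"] < 15
            assert inter["pass"]

    def test_missing_level_reported_not_raised(self):
        runs = [QCRun("QC_L", 5.0, [5.1, 5.2], day=1)]
        rep = validation_report(runs)
        assert rep["levels"]["QC_H"] == "missing"

    def test_deterministic_for_fixed_input(self):
        runs = [
            QCRun("QC_L", 5.0, [5.1, 4.9], day=2),
            QCRun("QC_L", 5.0, [5.3, 5.0], day=1),
        ]
        assert validation_report(runs) == validation_report(runs)
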