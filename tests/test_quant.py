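"""Calibration curves, standard addition, ratios, and stoichiometry."""

import numpy as np
import pytest
from scipy import stats

from perilipid.quant import (
    StandardSeries,
    class_composition,
    conversion_factor,
    fit_external_curve,
    lipids_per_smalp,
    quantify_by_curve,
    sphingolipid_ratio_report,
    standard_addition,
    two_sample_ttest,
)
from perilipid.simulate import simulate_standard_series


def external(concs, areas):
    return StandardSeries("PI 34:1", tuple(concs), tuple(areas), "external")


def addition(concs, areas):
    return StandardSeries("PI 34:1", tuple(concs), tuple(areas), "addition")


class TestExternalCurve:
    def test_exact_line(self):
        fit = fit_external_curve(external((0, 1, 2), (0, 200, 400)))
        assert fit.slope == pytest.approx(200.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.flags

    def test_noisy_slope_recovery(self):
        s = simulate_standard_series("external", 0.0, 200.0, 0.01, 3, intercept=50.0)
        fit = fit_external_curve(s)
        assert fit.slope == pytest.approx(200.0, rel=0.02)

    def test_flat_series_flagged(self):
        fit = fit_external_curve(external((0, 1, 2), (100, 100, 100)))
        assert "nonpositive_slope" in fit.flags

    def test_poor_linearity_flagged(self):
        fit = fit_external_curve(external((0, 1, 2, 3), (0, 300, 320, 900)))
        assert "poor_linearity" in fit.flags

    def test_series_validation(self):
        with pytest.raises(ValueError):
            external((0, 1), (0, 1))  # too few points
        with pytest.raises(ValueError):
            external((0.5, 1, 2), (1, 2, 3))  # missing blank
        with pytest.raises(ValueError):
            external((0, 2, 1), (1, 2, 3))  # not increasing


class TestQuantifyByCurve:
    def test_linear_inversion(self):
        fit = fit_external_curve(external((0, 1, 2), (0, 200, 400)))
        assert quantify_by_curve(300.0, fit) == pytest.approx(1.5)

    def test_floor_at_zero_with_warning(self):
        fit = fit_external_curve(external((0, 1, 2), (100, 300, 500)))
        with pytest.warns(UserWarning):
            assert quantify_by_curve(50.0, fit) == 0.0
        assert quantify_by_curve(100.0, fit) == 0.0


class TestStandardAddition:
    def test_x_intercept(self):
        est, se = standard_addition(
            addition((0, 0.5, 1.0, 1.5, 2.0), (300, 400, 500, 600, 700))
        )
        assert est == pytest.approx(1.5)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_no_endogenous_signal(self):
        est, _ = standard_addition(
            addition((0, 0.5, 1.0, 1.5, 2.0), (0, 100, 200, 300, 400))
        )
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        areas = (300, 400, 500, 600, 700)
        est1, _ = standard_addition(addition((0, 0.5, 1.0, 1.5, 2.0), areas))
        est2, _ = standard_addition(
            addition((0, 0.5, 1.0, 1.5, 2.0), tuple(37.2 * a for a in areas))
        )
        assert est1 == pytest.approx(est2)

    def test_monte_carlo_bias(self):
        """At 1% noise the estimator is essentially unbiased."""
        estimates = [
            standard_addition(
                simulate_standard_series("addition", 1.5, 200.0, 0.01, seed)
            )[0]
            for seed in range(1000)
        ]
        assert np.mean(estimates) == pytest.approx(1.5, rel=0.02)

    def test_noiseless_generator_recovery_exact(self):
        for endo in (0.3, 0.8, 1.5, 2.2):
            s = simulate_standard_series("addition", endo, 150.0, 0.0, 0)
            est, _ = standard_addition(s)
            assert est == pytest.approx(endo, rel=1e-9)


def test_conversion_factor_corrects_matrix_effect():
    # matrix suppresses response: standard addition sees the true amount,
    # the external curve (slope from pure standards) underestimates it
    ext_fit = fit_external_curve(external((0, 1, 2), (0, 200, 400)))
    supp_slope = 140.0  # suppressed in-matrix response
    s = simulate_standard_series("addition", 1.5, supp_slope, 0.0, 0)
    factor = conversion_factor(ext_fit, s)
    external_est = quantify_by_curve(s.areas[0], ext_fit)
    assert factor * external_est == pytest.approx(1.5)


class TestComposition:
    def test_reference_composition(self):
        pmol = {"PC": 40, "PI": 20, "PE": 18, "PS": 16, "ERG": 4, "PA": 1, "PG": 0.5, "CL": 0.5}
        mol = class_composition(pmol)
        assert mol["PC"] == pytest.approx(40.0)
        assert sum(mol.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_class(self):
        assert class_composition({"PC": 5.0}) == {"PC": 100.0}

    def test_relative_only_excluded(self):
        mol = class_composition({"PC": 50, "IPC": 50}, relative_only=("IPC",))
        assert mol == {"PC": 100.0}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            class_composition({"PC": 0.0})


class TestTTest:
    def test_identical_groups(self):
        t, df, p = two_sample_ttest((1, 2, 3), (1, 2, 3))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        t, df, p = two_sample_ttest((1, 2, 3), (5, 6, 7))
        assert t == pytest.approx(-4.899, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0081, abs=2e-4)

    def test_matches_scipy_student(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        t, df, p = two_sample_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest((1.0,), (2.0, 3.0))


class TestRatioReport:
    def mk(self, ipc, erg=1.0):
        return {"IPC": ipc, "ERG": erg}

    def test_fourfold_decrease(self):
        rep = sphingolipid_ratio_report(
            [self.mk(0.8)] * 3, [self.mk(0.2)] * 3, analyte="IPC"
        )
        assert rep.fold_change == pytest.approx(4.0)

    def test_identical_groups(self):
        rep = sphingolipid_ratio_report([self.mk(0.5)] * 3, [self.mk(0.5)] * 3)
        assert rep.fold_change == pytest.approx(1.0)
        assert rep.p_value == pytest.approx(1.0)
        assert rep.label == "ns"

    def test_significant_separation_labelled(self):
        rep = sphingolipid_ratio_report(
            [self.mk(0.7), self.mk(0.8), self.mk(0.9)],
            [self.mk(0.15), self.mk(0.2), self.mk(0.25)],
        )
        # pooled-variance t by hand: means 0.8 vs 0.2, s_p = sqrt(0.0075)/...
        t, df, p = two_sample_ttest((0.7, 0.8, 0.9), (0.15, 0.2, 0.25))
        assert rep.t_statistic == pytest.approx(t)
        assert rep.p_value < 0.005
        assert rep.label == "**"

    def test_zero_ergosterol_rejected(self):
        with pytest.raises(ValueError):
            sphingolipid_ratio_report([self.mk(0.5, erg=0.0)] * 3, [self.mk(0.5)] * 3)

    def test_fold_change_recovery_across_seeds(self):
        """Planted IPC/ergosterol fold changes are recovered within 15%."""
        from perilipid.simulate import SimConfig, _lognormal_factors

        for fold in (2.0, 4.0, 8.0):
            estimates = []
            for seed in range(50):
                rng = np.random.default_rng((seed, int(fold)))
                mcc_ratio = 0.2
                mcp = [
                    self.mk(mcc_ratio * fold * f)
                    for f in _lognormal_factors(rng, 0.10, 3)
                ]
                mcc = [
                    self.mk(mcc_ratio * f) for f in _lognormal_factors(rng, 0.10, 3)
                ]
                estimates.append(sphingolipid_ratio_report(mcp, mcc).fold_change)
            assert np.median(estimates) == pytest.approx(fold, rel=0.15)


class TestLipidsPerSmalp:
    def test_molar_ratio(self):
        assert lipids_per_smalp(870.0, 10.0) == 87

    def test_zero_lipid(self):
        assert lipids_per_smalp(0.0, 10.0) == 0

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError):
            lipids_per_smalp(100.0, 0.0)
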