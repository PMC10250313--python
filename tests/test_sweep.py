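"""Sweep orchestration, dependence-law fits, phase boundaries and the
non-dimensional collapse."""

import numpy as np
import pytest

import tubelaw as tl
from tubelaw.errors import DomainError
from tubelaw.sweep import SweepResult


@pytest.fixture(scope="module")
def d_sweep_result():
    curves = tl.generate_sweep_dataset("d", base_seed=11)
    return tl.analyze_sweep(curves)


@pytest.fixture(scope="module")
def gamma_sweep_result():
    curves = tl.generate_sweep_dataset("gamma", base_seed=12)
    return tl.analyze_sweep(curves)


class TestAnalyzeSweep:
    def test_d_sweep_magnitudes_decrease(self, d_sweep_result):
        res = d_sweep_result
        assert len(res.fits) == 7
        assert res.n_converged == 7
        assert np.all(np.diff(-res.p_crit) < 0)

    def test_gamma_sweep_magnitudes_increase(self, gamma_sweep_result):
        res = gamma_sweep_result
        assert len(res.fits) == 5
        assert np.all(np.diff(-res.p_crit) > 0)

    def test_recovers_generating_knees(self, d_sweep_result):
        truth = np.array([gt["p_crit_true"] for gt in d_sweep_result.ground_truth])
        np.testing.assert_allclose(d_sweep_result.p_crit, truth, rtol=0.02)

    def test_single_curve_rejected(self):
        curve = tl.generate_tubelaw(tl.default_generator_config(seed=0))
        with pytest.raises(DomainError):
            tl.analyze_sweep([curve])

    def test_param_inferred_from_geometry(self, d_sweep_result):
        assert d_sweep_result.param == "d"
        np.testing.assert_allclose(d_sweep_result.values, tl.DEFAULT_SWEEPS["d"])


class TestFitDependence:
    def test_d_law_round_trip_is_exact(self):
        ds = np.array(tl.DEFAULT_SWEEPS["d"])
        sweep = SweepResult.from_points("d", ds, tl.predict_pcrit_d(ds))
        fit = tl.fit_dependence(sweep, 11)
        assert fit.params["B"] == pytest.approx(-2.20, rel=1e-6)
        assert fit.params["A"] == pytest.approx(2.25e4, rel=1e-6)
        assert fit.params["C"] == pytest.approx(4.37e2, rel=1e-6)
        assert not fit.degenerate

    def test_gamma_law_round_trip_is_exact(self):
        gs = np.array(tl.DEFAULT_SWEEPS["gamma"])
        sweep = SweepResult.from_points("gamma", gs, tl.predict_pcrit_gamma(gs))
        fit = tl.fit_dependence(sweep, 12)
        assert fit.params["A"] == pytest.approx(2.53e6, rel=1e-6)
        assert fit.params["B"] == pytest.approx(3.14e4, rel=1e-6)
        assert "C" not in fit.params  # odd-cubic law has no offset

    def test_l_law_round_trip_well_conditioned(self):
        """The saturating l-law round-trips exactly for parameters whose
        plateau A + C is not lost to cancellation."""
        truth = tl.DependenceParams(A=2000.0, B=2.0, C=500.0)
        ls = np.array(tl.DEFAULT_SWEEPS["l"])
        p = np.array([tl.predict_pcrit_l(v, truth) for v in ls])
        sweep = SweepResult.from_points("l", ls, p)
        fit = tl.fit_dependence(sweep, 13)
        assert fit.params["A"] == pytest.approx(2000.0, rel=1e-5)
        assert fit.params["B"] == pytest.approx(2.0, rel=1e-5)
        assert fit.params["C"] == pytest.approx(500.0, rel=1e-4)
        assert "corr_AC" in fit.diagnostics

    def test_noisy_d_sweep_near_published(self, d_sweep_result):
        fit = tl.fit_dependence(d_sweep_result, 11)
        assert fit.params["B"] == pytest.approx(-2.20, abs=0.14)

    def test_all_equal_pressures_degenerate(self):
        ds = np.array(tl.DEFAULT_SWEEPS["d"])
        sweep = SweepResult.from_points("d", ds, np.full(7, -1000.0))
        fit = tl.fit_dependence(sweep, 11)
        assert fit.degenerate

    def test_mismatched_equation_rejected(self, d_sweep_result):
        with pytest.raises(DomainError):
            tl.fit_dependence(d_sweep_result, 12)


class TestPhaseBoundary:
    def test_d_boundary_endpoint_values(self):
        ds = np.array(tl.DEFAULT_SWEEPS["d"])
        sweep = SweepResult.from_points("d", ds, tl.predict_pcrit_d(ds))
        fit = tl.fit_dependence(sweep, 11)
        table = tl.phase_boundary(fit, [3.0, 6.0])
        np.testing.assert_allclose(
            table["neg_p_crit_pa"], [2443.85, 873.77], rtol=1e-3
        )
        assert np.all(table["p_crit_pa"] < 0)

    def test_gamma_boundary_value(self):
        gs = np.array(tl.DEFAULT_SWEEPS["gamma"])
        sweep = SweepResult.from_points("gamma", gs, tl.predict_pcrit_gamma(gs))
        fit = tl.fit_dependence(sweep, 12)
        table = tl.phase_boundary(fit, [0.05])
        assert table["neg_p_crit_pa"].iloc[0] == pytest.approx(1886.25, rel=1e-3)

    def test_empty_grid(self):
        ds = np.array(tl.DEFAULT_SWEEPS["d"])
        sweep = SweepResult.from_points("d", ds, tl.predict_pcrit_d(ds))
        fit = tl.fit_dependence(sweep, 11)
        assert len(tl.phase_boundary(fit, [])) == 0


class TestNondimensionalCollapse:
    def test_single_point_reference_value(self, reference_material):
        sweep = SweepResult.from_points("d", [3.0], [-2444.0], a_crit=[0.924])
        summary = tl.nondimensional_collapse(
            [sweep], reference_material, include_nonconverged=True
        )
        assert summary.p_hat_mean == pytest.approx(-0.0767, rel=2e-3)
        assert summary.a_hat_mean == pytest.approx(0.924, rel=1e-9)

    def test_constructed_areas_have_zero_spread(self, reference_material):
        sweep = SweepResult.from_points(
            "d", [3.0, 4.0, 5.0], [-2444.0, -1250.0, -1090.0],
            a_crit=[0.924, 0.924, 0.924],
        )
        summary = tl.nondimensional_collapse(
            [sweep], reference_material, include_nonconverged=True
        )
        assert summary.a_hat_mean == pytest.approx(0.924)
        assert summary.a_hat_std == pytest.approx(0.0, abs=1e-12)

    def test_collapse_flattens_d_spread(self, reference_material):
        """Raw critical pressures vary ~2.8x over d in [3, 6]; after the
        rescaling the non-dimensional values stay within +/-25% of their
        mean."""
        ds = np.array(tl.DEFAULT_SWEEPS["d"])
        sweep = SweepResult.from_points(
            "d", ds, tl.predict_pcrit_d(ds), a_crit=np.full(7, 0.924)
        )
        raw = -sweep.p_crit
        assert raw.max() / raw.min() > 2.5
        summary = tl.nondimensional_collapse(
            [sweep], reference_material, include_nonconverged=True
        )
        dev = np.abs(summary.p_hat - summary.p_hat_mean) / abs(summary.p_hat_mean)
        assert dev.max() < 0.25

    def test_shared_triplet_consistency(
        self, d_sweep_result, gamma_sweep_result
    ):
        """The d- and gamma-sweeps share the tube (3, 0.06, 1.1); their
        fitted dependence laws agree there within 1%."""
        fd = tl.fit_dependence(d_sweep_result, 11)
        fg = tl.fit_dependence(gamma_sweep_result, 12)
        at_d = fd.predict_neg_pcrit(3.0)
        at_g = fg.predict_neg_pcrit(0.06)
        assert abs(at_d - at_g) / at_g < 0.01

    def test_population_sd_default_and_ddof_option(self, reference_material):
        sweep = SweepResult.from_points(
            "d", [3.0, 4.0], [-2000.0, -1000.0], a_crit=[0.9, 0.95]
        )
        s0 = tl.nondimensional_collapse(
            [sweep], reference_material, include_nonconverged=True
        )
        s1 = tl.nondimensional_collapse(
            [sweep], reference_material, ddof=1, include_nonconverged=True
        )
        assert s1.a_hat_std > s0.a_hat_std
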