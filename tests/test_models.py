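"""Analytic models: elastic coefficients, thin-shell buckling, mean-field
order parameter, dependence laws, non-dimensional transforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tubelaw as tl
from tubelaw.errors import DomainError, IllConditionedParametersWarning


class TestNeoHookean:
    @pytest.mark.parametrize(
        "E, nu, chi, lam",
        [
            (1e6, 0.49, 1.6779e5, 1.6443e7),  # nearly incompressible wall
            (1e6, 0.0, 2.5e5, 0.0),  # nu=0 zeroes the volumetric term
            (0.0, 0.3, 0.0, 0.0),  # linear in E
        ],
    )
    def test_coefficients(self, E, nu, chi, lam):
        got = tl.neo_hookean_coefficients(tl.Material(E=E, nu=nu))
        assert got.chi == pytest.approx(chi, rel=1e-4)
        assert got.lam == pytest.approx(lam, rel=1e-4, abs=1e-9)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(DomainError):
            tl.Material(E=1e6, nu=0.5)


class TestVonMises:
    def test_reference_value(self, reference_material, reference_geometry):
        p = tl.von_mises_critical_pressure(reference_material, reference_geometry)
        assert p == pytest.approx(-3.214e3, rel=2e-3)
        assert p < 0  # signed intramural pressure

    def test_large_d_ring_limit(self, reference_material):
        """For long tubes the end-support term vanishes as (4d/pi)^-2 and
        the formula approaches the elastic-ring pressure
        2 E gamma^3/(1-nu^2); agreement reaches 1% around d ~ 70."""
        ring = tl.ring_buckling_pressure(reference_material, 0.06)
        assert ring == pytest.approx(-568.5, rel=1e-3)
        errs = []
        for d in (40.0, 70.0, 140.0):
            p = tl.von_mises_critical_pressure(
                reference_material, tl.TubeGeometry(d=d, gamma=0.06)
            )
            errs.append(abs((p - ring) / ring))
        assert errs[1] < 0.01
        # the end-support correction decays quadratically in d
        assert errs[0] / errs[1] == pytest.approx((70 / 40) ** 2, rel=0.05)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.05)

    def test_monotone_in_gamma_and_d(self, reference_material):
        gammas = np.linspace(0.005, 0.1, 20)
        mags_g = [
            -tl.von_mises_critical_pressure(
                reference_material, tl.TubeGeometry(d=3.0, gamma=g)
            )
            for g in gammas
        ]
        assert np.all(np.diff(mags_g) > 0)
        ds = np.linspace(3.0, 6.0, 13)
        mags_d = [
            -tl.von_mises_critical_pressure(
                reference_material, tl.TubeGeometry(d=d, gamma=0.06)
            )
            for d in ds
        ]
        assert np.all(np.diff(mags_d) < 0)

    def test_overestimates_observed_boundaries(self, reference_material):
        """The thin-shell formula exceeds the fitted dependence laws in
        magnitude over the studied geometric ranges."""
        for d in np.linspace(3.0, 6.0, 13):
            vm = tl.von_mises_critical_pressure(
                reference_material, tl.TubeGeometry(d=d, gamma=0.06, l=1.1)
            )
            assert -vm > -tl.predict_pcrit_d(d)
        for g in np.linspace(0.05, 0.09, 9):
            vm = tl.von_mises_critical_pressure(
                reference_material, tl.TubeGeometry(d=3.0, gamma=g, l=1.1)
            )
            assert -vm > -tl.predict_pcrit_gamma(g)


class TestOrderParameter:
    def test_transition_point_and_beyond(self):
        params = tl.LandauModelParams(c1=2.0, c2=1.0, xi_crit=1.0)
        assert tl.order_parameter_mean_field(1.0, params) == 0.0
        assert tl.order_parameter_mean_field(5.0, params) == 0.0

    def test_ratio_cancels(self):
        params = tl.LandauModelParams(c1=3.7, c2=3.7, xi_crit=1.0)
        assert tl.order_parameter_mean_field(0.0, params) == pytest.approx(1.0)

    def test_square_linear_in_distance(self):
        params = tl.LandauModelParams(c1=2.0, c2=0.5, xi_crit=1.0)
        xi = np.linspace(-3.0, 1.0, 50)
        alpha = tl.order_parameter_mean_field(xi, params)
        slope = np.polyfit(params.xi_crit - xi, alpha**2, 1)[0]
        assert slope == pytest.approx(params.c1 / params.c2, rel=1e-12)

    def test_continuity_at_transition(self):
        params = tl.LandauModelParams(c1=1.0, c2=1.0, xi_crit=0.0)
        eps = 1e-12
        assert tl.order_parameter_mean_field(-eps, params) < 1e-5


class TestDependenceLaws:
    @pytest.mark.parametrize(
        "d, expected",
        [(3.0, -2.444e3), (6.0, -8.74e2)],
    )
    def test_d_law_published_defaults(self, d, expected):
        assert tl.predict_pcrit_d(d) == pytest.approx(expected, rel=2e-3)

    def test_d_law_zero_params(self):
        params = tl.DependenceParams(A=0.0, B=-2.0, C=0.0)
        assert tl.predict_pcrit_d(5.0, params) == 0.0

    def test_d_law_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            tl.predict_pcrit_d(-1.0)

    @pytest.mark.parametrize(
        "gamma, expected",
        [(0.06, -2.431e3), (0.05, -1.886e3), (0.0, 0.0)],
    )
    def test_gamma_law_published_defaults(self, gamma, expected):
        assert tl.predict_pcrit_gamma(gamma) == pytest.approx(
            expected, rel=2e-3, abs=1e-9
        )

    def test_l_law_defaults_warn_and_are_unphysical(self):
        """The printed tanh-law A and C cancel to rounding: the prediction
        carries the wrong sign and must arrive flagged."""
        with pytest.warns(IllConditionedParametersWarning):
            p = tl.predict_pcrit_l(1.1)
        assert p == pytest.approx(1.10e3, rel=2e-3)  # unphysical positive

    def test_l_law_well_conditioned_params_no_warning(self, recwarn):
        params = tl.DependenceParams(A=2000.0, B=2.0, C=500.0)
        p = tl.predict_pcrit_l(1.5, params)
        assert p == pytest.approx(-(2000.0 * np.tanh(3.0) + 500.0))
        assert not any(
            isinstance(w.message, IllConditionedParametersWarning)
            for w in recwarn.list
        )

    def test_l_law_constant_when_amplitude_zero(self):
        params = tl.DependenceParams(A=0.0, B=1.0, C=-1000.0)
        for l in (1.0, 1.5, 2.0):
            assert tl.predict_pcrit_l(l, params) == pytest.approx(1000.0)

    def test_cross_consistency_at_shared_triplet(self):
        """The d-law at d=3 and the gamma-law at gamma=0.06 describe the same
        tube (3, 0.06, 1.1) and agree within 1%."""
        pd_ = tl.predict_pcrit_d(3.0)
        pg = tl.predict_pcrit_gamma(0.06)
        assert abs(pd_ - pg) / abs(pg) < 0.01


class TestNondimensional:
    def test_reference_pressure(self, reference_material, reference_geometry):
        p_hat, _ = tl.nondimensionalize(
            -2444.0, 1e-5, reference_material, reference_geometry
        )
        assert p_hat == pytest.approx(-0.0767, rel=2e-3)

    def test_area_definition_inverts(self, reference_material, reference_geometry):
        g = reference_geometry
        area = 0.924 * np.pi * g.r**2 / g.l
        _, a_hat = tl.nondimensionalize(0.0, area, reference_material, g)
        assert a_hat == pytest.approx(0.924, rel=1e-12)

    @given(
        p=st.floats(-1e4, 0.0),
        a_hat=st.floats(0.1, 1.2),
        d=st.floats(1.0, 10.0),
        gamma=st.floats(0.01, 0.2),
        l=st.floats(1.0, 2.0),
        r=st.floats(1e-3, 0.05),
    )
    def test_round_trip_identity(self, p, a_hat, d, gamma, l, r):
        mat = tl.Material()
        geom = tl.TubeGeometry(d=d, gamma=gamma, l=l, r=r)
        area = a_hat * np.pi * r**2 / l
        ph, ah = tl.nondimensionalize(p, area, mat, geom)
        p2, a2 = tl.dimensionalize(ph, ah, mat, geom)
        assert p2 == pytest.approx(p, rel=1e-12, abs=1e-9)
        assert a2 == pytest.approx(area, rel=1e-12, abs=1e-15)
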