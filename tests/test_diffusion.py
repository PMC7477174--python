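"""Forward-model physics: closed forms vs independent oracles and limits."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import j0

from ovifnirs.diffusion import (cw_reflectance_homog, cw_reflectance_two_layer,
                                delta_od_forward, dpf, fit_dtof,
                                tr_reflectance_homog)
from ovifnirs.media import C_LIGHT, LayeredMedium, OpticalProperties, \
    boundary_coefficient


def hankel_oracle_homog(rho, props, n_tissue=1.0, n_external=1.0):
    """Independent spatial-frequency-domain evaluation of the semi-infinite
    boundary-value problem: the q-space surface flux integrated piecewise
    between Bessel oscillation periods (never uses the dipole closed form)."""
    d = 1.0 / (3.0 * props.musp)
    z0 = 1.0 / props.musp
    zb = 2.0 * boundary_coefficient(n_tissue, n_external) * d

    def jq(q):
        a = np.sqrt(q * q + props.mua / d)
        return 0.5 * (np.exp(-a * z0) + np.exp(-a * (z0 + 2 * zb)))

    period = 2.0 * np.pi / rho
    edges = np.arange(0.0, 60.0 + period, period)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda q: jq(q) * j0(q * rho) * q, a, b,
                      limit=200, epsabs=1e-16, epsrel=1e-12)
        total += val
    return total / (2.0 * np.pi)


class TestHomogeneousCW:
    def test_matches_independent_hankel_oracle(self, matched_props):
        for rho in (10.0, 30.0):
            closed = cw_reflectance_homog(rho, matched_props, 1.0, 1.0)
            oracle = hankel_oracle_homog(rho, matched_props)
            assert closed == pytest.approx(oracle, rel=1e-6)

    def test_mismatched_boundary_against_oracle(self, matched_props):
        closed = cw_reflectance_homog(30.0, matched_props, 1.4, 1.0)
        oracle = hankel_oracle_homog(30.0, matched_props, 1.4, 1.0)
        assert closed == pytest.approx(oracle, rel=1e-6)

    def test_decays_with_distance_and_absorption(self, matched_props):
        assert cw_reflectance_homog(30.0, matched_props, 1.4) < \
            cw_reflectance_homog(10.0, matched_props, 1.4)
        more_absorbing = OpticalProperties(0.02, 1.0)
        assert cw_reflectance_homog(30.0, more_absorbing, 1.4) < \
            cw_reflectance_homog(30.0, matched_props, 1.4)

    def test_rejects_bad_inputs(self, matched_props):
        with pytest.raises(ValueError):
            cw_reflectance_homog(-1.0, matched_props)
        with pytest.raises(ValueError):
            OpticalProperties(-0.01, 1.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.01, 0.0)

    def test_positive_finite_over_property_grid(self):
        for rho in (5.0, 20.0, 40.0):
            for mua in (0.002, 0.01, 0.05):
                for musp in (0.5, 1.0, 2.0):
                    r = cw_reflectance_homog(rho, OpticalProperties(mua, musp), 1.4)
                    assert np.isfinite(r) and r > 0


class TestTwoLayerCW:
    def test_homogeneous_limit_random_tuples(self):
        """Identical layers must reproduce the closed-form semi-infinite
        reflectance; 20 random property tuples, rel. error < 1e-3."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            props = OpticalProperties(rng.uniform(0.002, 0.05),
                                      rng.uniform(0.5, 2.0))
            med = LayeredMedium(rng.uniform(5.0, 15.0), props, props, 1.4, 1.0)
            rho = rng.uniform(8.0, 35.0)
            assert cw_reflectance_two_layer(rho, med) == pytest.approx(
                cw_reflectance_homog(rho, props, 1.4, 1.0), rel=1e-3)

    def test_thick_slab_limit(self):
        up = OpticalProperties(0.012, 1.2)
        lo = OpticalProperties(0.03, 0.8)
        med = LayeredMedium(100.0, up, lo, 1.4, 1.0)
        assert cw_reflectance_two_layer(30.0, med) == pytest.approx(
            cw_reflectance_homog(30.0, up, 1.4, 1.0), rel=1e-3)

    def test_lower_absorption_monotonicity(self):
        up = OpticalProperties(0.01, 1.0)
        r = [cw_reflectance_two_layer(
                30.0, LayeredMedium(10.0, up, OpticalProperties(mua, 1.0), 1.4, 1.0))
             for mua in (0.01, 0.02, 0.03)]
        assert r[0] > r[1] > r[2]

    def test_positive_over_grid(self):
        for mua in (0.002, 0.05):
            for musp in (0.5, 2.0):
                up = OpticalProperties(0.015, 1.0)
                lo = OpticalProperties(mua, musp)
                med = LayeredMedium(10.0, up, lo, 1.4, 1.0)
                for rho in (5.0, 40.0):
                    r = cw_reflectance_two_layer(rho, med)
                    assert np.isfinite(r) and r > 0


class TestDeltaODForward:
    def test_zero_perturbation_is_zero(self, baseline_medium):
        assert delta_od_forward(10.0, "homogeneous", baseline_medium, 0.0,
                                wavelength=751.0) == 0.0
        assert delta_od_forward(30.0, "two_layer", baseline_medium, 0.0, 0.0,
                                wavelength=751.0) == 0.0

    def test_mbll_first_order_consistency(self, baseline_medium):
        """Small perturbations obey DeltaOD ~ DPF*rho*Dmua/ln10 within 2%."""
        up, _ = baseline_medium.props(751.0)
        for dmua in (1e-5, 1e-4):
            dod = delta_od_forward(10.0, "homogeneous", baseline_medium, dmua,
                                   wavelength=751.0)
            mbll = dpf(10.0, up, 1.4) * 10.0 * dmua / np.log(10.0)
            assert dod == pytest.approx(mbll, rel=0.02)

    def test_partial_volume_bound(self, baseline_medium):
        """A cortical-only perturbation produces less DeltaOD than the same
        perturbation applied to the whole medium (brute-force comparison)."""
        dod_deep = delta_od_forward(30.0, "two_layer", baseline_medium,
                                    0.0, 1e-3, wavelength=751.0)
        dod_all = delta_od_forward(30.0, "homogeneous", baseline_medium,
                                   1e-3, wavelength=751.0)
        assert 0.0 < dod_deep < dod_all

    def test_sign_reciprocity(self, baseline_medium):
        for model, args in (("homogeneous", (5e-4,)), ("two_layer", (5e-4, 5e-4))):
            pos = delta_od_forward(30.0, model, baseline_medium, *args,
                                   wavelength=751.0)
            neg_args = tuple(-a for a in args)
            neg = delta_od_forward(30.0, model, baseline_medium, *neg_args,
                                   wavelength=751.0)
            assert pos > 0.0 > neg

    def test_driving_mua_negative_raises(self, baseline_medium):
        with pytest.raises(ValueError):
            delta_od_forward(10.0, "homogeneous", baseline_medium, -0.02,
                             wavelength=751.0)


class TestTimeResolved:
    grid = [(mua, musp) for mua in (0.005, 0.01, 0.02)
            for musp in (0.5, 1.0, 2.0)]

    def test_time_integral_equals_cw(self, matched_props):
        from ovifnirs.diffusion import _tr_moments
        area, _ = _tr_moments(30.0, matched_props, 1.4, 1.0)
        cw = cw_reflectance_homog(30.0, matched_props, 1.4, 1.0)
        assert area == pytest.approx(cw, rel=1e-3)

    def test_absorption_factorization(self):
        """exp(+mua v t) removes all mua dependence from the TR curve."""
        t = np.linspace(0.05, 3.0, 40)
        v = C_LIGHT / 1.4
        curves = []
        for mua in (0.005, 0.03):
            r = tr_reflectance_homog(30.0, t, OpticalProperties(mua, 1.0), 1.4)
            curves.append(r * np.exp(mua * v * t))
        np.testing.assert_allclose(curves[0], curves[1], rtol=1e-12)

    def test_mean_tof_matches_cw_derivative(self, matched_props):
        from ovifnirs.diffusion import _tr_moments
        _, t_mean = _tr_moments(30.0, matched_props, 1.4, 1.0)
        h = 1e-7
        r = [cw_reflectance_homog(30.0, OpticalProperties(0.01 + s * h, 1.0),
                                  1.4, 1.0) for s in (-1, 1)]
        v = C_LIGHT / 1.4
        t_deriv = (np.log(r[0]) - np.log(r[1])) / (2 * h) / v
        assert t_mean == pytest.approx(t_deriv, rel=0.01)

    def test_t_nonpositive_raises(self, matched_props):
        with pytest.raises(ValueError):
            tr_reflectance_homog(30.0, 0.0, matched_props)


class TestDPF:
    def test_exceeds_one_and_grows_with_scattering(self):
        vals = {}
        for mua in (0.005, 0.02):
            for musp in (0.5, 1.0):
                vals[(mua, musp)] = dpf(30.0, OpticalProperties(mua, musp), 1.4)
                assert vals[(mua, musp)] > 1.0
        assert vals[(0.005, 1.0)] > vals[(0.005, 0.5)]

    @pytest.mark.parametrize("mua,musp", [(0.005, 0.5), (0.01, 1.0), (0.02, 2.0)])
    def test_matches_cw_log_derivative(self, mua, musp):
        props = OpticalProperties(mua, musp)
        val = dpf(30.0, props, 1.4)
        h = mua * 1e-4
        r = [cw_reflectance_homog(30.0, OpticalProperties(mua + s * h, musp),
                                  1.4, 1.0) for s in (-1, 1)]
        oracle = (np.log(r[0]) - np.log(r[1])) / (2 * h) / 30.0
        assert val == pytest.approx(oracle, rel=0.01)


class TestFitDTOF:
    t = np.linspace(0.01, 6.0, 400)

    def _histogram(self, props, n_counts=None, seed=0):
        curve = tr_reflectance_homog(30.0, self.t, props, 1.4, 1.0)
        if n_counts is None:
            return curve
        rng = np.random.default_rng(seed)
        scale = n_counts / curve.sum()
        return rng.poisson(curve * scale).astype(float)

    def test_noiseless_self_fit(self, matched_props):
        fit = fit_dtof(self._histogram(matched_props), self.t, 30.0, 1.4)
        assert fit.mua == pytest.approx(0.01, rel=1e-4)
        assert fit.musp == pytest.approx(1.0, rel=1e-4)

    def test_poisson_round_trip(self, matched_props):
        """1e6 counts: both coefficients recovered within 5%."""
        dtof = self._histogram(matched_props, n_counts=1_000_000, seed=4)
        fit = fit_dtof(dtof, self.t, 30.0, 1.4)
        assert fit.mua == pytest.approx(0.01, rel=0.05)
        assert fit.musp == pytest.approx(1.0, rel=0.05)

    def test_tail_slope_carries_mua(self, matched_props):
        """Restricting the fit window to the tail leaves mua within 3%."""
        full = fit_dtof(self._histogram(matched_props), self.t, 30.0, 1.4)
        tail = fit_dtof(self._histogram(matched_props), self.t, 30.0, 1.4,
                        fit_window=(0.999, 0.001))
        assert tail.mua == pytest.approx(full.mua, rel=0.03)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError):
            fit_dtof(np.zeros(400), self.t, 30.0)
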