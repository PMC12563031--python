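"""Contact-mechanics forward models: closed forms, limits, and the
hereditary integral against an independent quadrature oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffoldkit.mechanics import (
    DepthProtocol,
    ProbeSpec,
    SampleGeometry,
    SLSParams,
    bec_correction,
    hertz_force,
    lee_radok_force,
    sls_relaxation_modulus,
)
from conftest import lee_radok_quadrature_oracle


class TestHertz:
    def test_zero_depth_gives_zero_force(self, probe, half_space):
        assert hertz_force(0.0, 10e3, probe, half_space) == 0.0

    def test_reference_value_half_space(self, probe, half_space):
        # E = 10 kPa, R = 500 um, nu = 0.5, delta = 100 um
        f = hertz_force(100e-6, 10e3, probe, half_space)
        assert f == pytest.approx(3.9752e-4, rel=1e-3)

    def test_three_halves_power_law(self, probe, half_space):
        f1 = hertz_force(50e-6, 8e3, probe, half_space)
        f2 = hertz_force(100e-6, 8e3, probe, half_space)
        assert f2 / f1 == pytest.approx(2**1.5, rel=1e-12)

    @given(
        d=st.floats(1e-7, 5e-4),
        e=st.floats(1e2, 1e6),
        scale=st.floats(1.01, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_depth_and_modulus(self, d, e, scale):
        probe = ProbeSpec(500e-6)
        geom = SampleGeometry(thickness=1e-3)
        assert hertz_force(d * scale, e, probe, geom) > hertz_force(d, e, probe, geom)
        assert hertz_force(d, e * scale, probe, geom) > hertz_force(d, e, probe, geom)

    def test_domain_errors(self, probe, half_space):
        with pytest.raises(ValueError):
            hertz_force(-1e-6, 10e3, probe, half_space)
        with pytest.raises(ValueError):
            hertz_force(1e-6, 0.0, probe, half_space)


class TestBottomEffectCorrection:
    def test_semi_infinite_is_unity(self, probe, half_space):
        assert bec_correction(300e-6, probe, half_space) == 1.0

    def test_zero_depth_is_unity(self, probe, thin_layer):
        assert bec_correction(0.0, probe, thin_layer) == 1.0

    def test_bonded_polynomial_reference_value(self, probe, thin_layer):
        # chi = sqrt(R*delta)/h ~ 0.387 for R=500um, delta=300um, h=1mm
        assert bec_correction(300e-6, probe, thin_layer) == pytest.approx(1.6781, rel=1e-4)

    def test_free_variant_softer_than_bonded(self, probe):
        bonded = SampleGeometry(thickness=1e-3, bonded=True)
        free = SampleGeometry(thickness=1e-3, bonded=False)
        assert 1.0 < bec_correction(300e-6, probe, free) < bec_correction(300e-6, probe, bonded)

    @given(
        d=st.floats(1e-6, 4e-4),
        h1=st.floats(5e-4, 5e-3),
        shrink=st.floats(0.2, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_as_thickness_decreases(self, d, h1, shrink):
        probe = ProbeSpec(500e-6)
        thick = bec_correction(d, probe, SampleGeometry(thickness=h1))
        thin = bec_correction(d, probe, SampleGeometry(thickness=h1 * shrink))
        assert 1.0 <= thick <= thin

    def test_invalid_thickness_rejected(self):
        with pytest.raises(ValueError):
            SampleGeometry(thickness=0.0)


class TestSLSRelaxation:
    def test_limits(self, sls_truth):
        assert sls_relaxation_modulus(0.0, sls_truth) == pytest.approx(30e3)
        assert sls_relaxation_modulus(1e6, sls_truth) == pytest.approx(10e3)

    def test_value_at_one_tau(self, sls_truth):
        # E(tau) = Einf + (E0-Einf)/e = 10 + 20/e kPa
        assert sls_relaxation_modulus(5.0, sls_truth) == pytest.approx(17.3576e3, rel=1e-4)

    def test_monotone_nonincreasing_and_bounded(self, sls_truth):
        t = np.linspace(0, 60, 500)
        e = sls_relaxation_modulus(t, sls_truth)
        assert np.all(np.diff(e) <= 0)
        assert np.all((e >= sls_truth.einf) & (e <= sls_truth.e0))

    def test_negative_time_rejected(self, sls_truth):
        with pytest.raises(ValueError):
            sls_relaxation_modulus(-0.1, sls_truth)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SLSParams(e0=5e3, einf=10e3, tau=1.0)
        with pytest.raises(ValueError):
            SLSParams(e0=10e3, einf=10e3, tau=0.0)


def _protocols(rate=50.0):
    return {
        "ramp": DepthProtocol.ramp_hold(30e-6, 300e-6, 1e-3, rate),
        "step": DepthProtocol.step_hold(200e-6, 10.0, rate),
        "ramp_hold": DepthProtocol.ramp_hold(30e-6, 300e-6, 20.0, rate),
    }


class TestLeeRadok:
    def test_elastic_degenerate_matches_hertz_pointwise(self, probe, half_space):
        params = SLSParams(e0=12e3, einf=12e3, tau=3.0)
        for prot in _protocols().values():
            f = lee_radok_force(prot, params, probe, half_space)
            ref = hertz_force(prot.depth, 12e3, probe, half_space)
            assert np.allclose(f, ref, rtol=1e-6, atol=1e-12)

    def test_elastic_degenerate_finite_thickness_with_derivative_grouping(self, probe, thin_layer):
        # with the BEC folded into the differentiated response, the elastic
        # limit reproduces the corrected Hertz force also on a thin layer
        params = SLSParams(e0=12e3, einf=12e3, tau=3.0)
        prot = DepthProtocol.ramp_hold(30e-6, 300e-6, 5.0, 100.0)
        f = lee_radok_force(prot, params, probe, thin_layer, bec_with_derivative=True)
        ref = hertz_force(prot.depth, 12e3, probe, thin_layer)
        assert np.allclose(f, ref, rtol=1e-6, atol=1e-12)

    def test_step_hold_relaxes_as_relaxation_modulus(self, probe, half_space, sls_truth):
        # step to delta0 then hold: F(t) = pref * delta0^(3/2) * E(t)
        prot = DepthProtocol.step_hold(200e-6, 10.0, 1000.0)
        f = lee_radok_force(prot, sls_truth, probe, half_space)
        pref = 4 * np.sqrt(probe.tip_radius) / (3 * 0.75)
        expected = pref * (200e-6) ** 1.5 * sls_relaxation_modulus(prot.time, sls_truth)
        assert np.allclose(f[1:], expected[1:], rtol=2e-3)

    def test_ramp_hold_relaxes_to_long_term_hertz(self, probe, half_space, sls_truth):
        # 30 um/s to 300 um, long hold -> Hertz force with Einf ~ 2.066 mN
        prot = DepthProtocol.ramp_hold(30e-6, 300e-6, 60.0, 100.0)
        f = lee_radok_force(prot, sls_truth, probe, half_space)
        assert f[-1] == pytest.approx(2.0656e-3, rel=1e-3)

    @pytest.mark.parametrize("name", ["ramp", "step", "ramp_hold"])
    def test_matches_independent_quadrature_oracle(self, name, probe, half_space, sls_truth):
        prot = _protocols(rate=50.0)[name]
        f = lee_radok_force(prot, sls_truth, probe, half_space)
        ref = lee_radok_quadrature_oracle(prot, sls_truth, probe, half_space, refine=10)
        scale = np.abs(ref).max()
        assert np.abs(f - ref).max() / scale < 1e-3

    def test_oracle_agreement_on_thin_layer(self, probe, thin_layer, sls_truth):
        prot = DepthProtocol.ramp_hold(30e-6, 300e-6, 10.0, 50.0)
        f = lee_radok_force(prot, sls_truth, probe, thin_layer)
        ref = lee_radok_quadrature_oracle(prot, sls_truth, probe, thin_layer, refine=10)
        assert np.abs(f - ref).max() / np.abs(ref).max() < 1e-3

    def test_grid_refinement_converges_at_first_order_or_better(self, probe, half_space, sls_truth):
        def force_at(rate):
            prot = DepthProtocol.ramp_hold(30e-6, 300e-6, 10.0, rate)
            return lee_radok_force(prot, sls_truth, probe, half_space)[-1]

        ref = force_at(800.0)
        e_coarse = abs(force_at(25.0) - ref)
        e_fine = abs(force_at(50.0) - ref)
        assert e_fine <= 0.6 * e_coarse  # observed order >= 1

    def test_hold_force_nonincreasing_and_bounded_by_long_term_hertz(
        self, probe, half_space, sls_truth
    ):
        prot = DepthProtocol.ramp_hold(30e-6, 300e-6, 30.0, 100.0)
        f = lee_radok_force(prot, sls_truth, probe, half_space)
        hold = prot.depth >= prot.depth.max()
        fh = f[hold]
        assert np.all(np.diff(fh) <= 1e-15)
        floor = hertz_force(prot.depth.max(), sls_truth.einf, probe, half_space)
        assert np.all(fh >= floor - 1e-12)

    def test_finite_thickness_stiffens_response(self, probe, half_space, thin_layer, sls_truth):
        prot = DepthProtocol.ramp_hold(30e-6, 300e-6, 10.0, 100.0)
        f_inf = lee_radok_force(prot, sls_truth, probe, half_space)
        f_thin = lee_radok_force(prot, sls_truth, probe, thin_layer)
        assert np.all(f_thin >= f_inf)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            DepthProtocol(np.array([0.0, 1.0, 1.0]), np.array([0.0, 1e-5, 1e-5]))
        with pytest.raises(ValueError):
            DepthProtocol(np.array([0.0, 1.0]), np.array([1e-5, 2e-5]))
        with pytest.raises(ValueError):
            DepthProtocol(np.array([0.0, 1.0]), np.array([0.0, -1e-5]))
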