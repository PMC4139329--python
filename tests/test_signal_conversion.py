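"""Tests for MR signal conversion and AIF preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renalpk as rk
from renalpk.kinetics_core import Curve
from renalpk.signal_conversion import RelaxationParams, spgr_signal


class TestGdFromRelaxation:
    def test_no_enhancement_gives_zero(self):
        assert rk.gd_from_relaxation(1.2, 1.2) == 0.0

    def test_hand_arithmetic(self):
        # (1/0.5 - 1/1.0) / 4.1 mmol/L
        assert rk.gd_from_relaxation(1.0, 0.5, r1=4.1) == pytest.approx((2.0 - 1.0) / 4.1)

    def test_linear_in_relaxation_rate_change(self):
        c1 = rk.gd_from_relaxation(1.0, 0.8)
        # doubling delta-R1: 1/t1_post - 1/t1_pre twice as large
        t1_post2 = 1.0 / (1.0 + 2 * (1.0 / 0.8 - 1.0))
        c2 = rk.gd_from_relaxation(1.0, t1_post2)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_negative_concentration_flagged_not_clipped(self, caplog):
        with caplog.at_level("WARNING", logger="renalpk"):
            val = rk.gd_from_relaxation(0.5, 1.0)
        assert val < 0
        assert any("negative" in r.message for r in caplog.records)


class TestVfaT1Fit:
    def test_forward_inverse_round_trip(self):
        t1, tr = 1.2, 6.2e-3
        flips = np.array([4.0, 15.0, 25.0])
        signals = spgr_signal(100.0, t1, tr, flips)
        t1_hat, m0_hat = rk.vfa_t1_fit(signals, flips, tr)
        assert t1_hat == pytest.approx(t1, rel=1e-6)
        assert m0_hat == pytest.approx(100.0, rel=1e-6)

    def test_three_angle_fit_equals_two_angle_closed_form(self):
        t1, tr = 0.9, 6.2e-3
        flips = np.array([5.0, 20.0])
        signals = spgr_signal(50.0, t1, tr, flips)
        # two-point closed form: slope through the two (S/tan, S/sin) points
        y = signals / np.sin(np.deg2rad(flips))
        x = signals / np.tan(np.deg2rad(flips))
        e1 = (y[1] - y[0]) / (x[1] - x[0])
        expected = -tr / np.log(e1)
        t1_hat, _ = rk.vfa_t1_fit(signals, flips, tr)
        assert t1_hat == pytest.approx(expected, rel=1e-9)

    def test_degenerate_design_rejected(self):
        signals = np.array([10.0, 10.0])
        with pytest.raises(ValueError):
            rk.vfa_t1_fit(signals, np.array([15.0, 15.0]), 6.2e-3)


class TestDynamicToConcentration:
    def _params(self, t1=1.2):
        return RelaxationParams(t1_pre=t1)

    def test_baseline_signal_maps_to_zero(self):
        t = np.arange(20) * 3.0
        signal = Curve(t, np.full(20, 40.0))
        conc, flags = rk.dynamic_to_concentration(signal, self._params())
        assert not flags.any()
        np.testing.assert_allclose(conc.v, 0.0, atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(t1=st.floats(0.1, 3.0), peak=st.floats(0.1, 4.0))
    def test_concentration_signal_round_trip(self, t1, peak):
        params = self._params(t1)
        t = np.arange(30) * 3.0
        true_conc = np.concatenate([np.zeros(5), peak * np.exp(-0.01 * t[5:])])
        # synthesise the SPGR signal the scanner would produce
        r1_post = 1.0 / t1 + params.r1 * true_conc
        signal = spgr_signal(75.0, 1.0 / r1_post, params.tr, params.flip_deg)
        conc, flags = rk.dynamic_to_concentration(Curve(t, signal), params)
        assert not flags.any()
        np.testing.assert_allclose(conc.v, true_conc, rtol=1e-6, atol=1e-9)

    def test_default_baseline_is_five_frames(self):
        import inspect

        sig = inspect.signature(rk.dynamic_to_concentration)
        assert sig.parameters["n_baseline"].default == 5

    def test_non_physical_enhancement_flagged(self):
        t = np.arange(10) * 3.0
        v = np.full(10, 40.0)
        v[7] = 4000.0  # signal above the SPGR ceiling for this M0
        conc, flags = rk.dynamic_to_concentration(Curve(t, v), self._params())
        assert flags[7]
        assert np.isnan(conc.v[7])


class TestAifTail:
    def _noisy_biexp_aif(self):
        t = np.arange(100) * 3.0
        first_pass = 3.0 * np.exp(-0.5 * ((t - 24.0) / 6.0) ** 2)
        tail = 1.2 * np.exp(-0.01 * t) + 0.5 * np.exp(-0.002 * t)
        return Curve(t, first_pass + tail)

    def test_known_biexponential_recovered(self):
        t = np.arange(100) * 3.0
        a1, b1, a2, b2 = 1.5, 0.02, 0.7, 0.003
        v = a1 * np.exp(-b1 * t) + a2 * np.exp(-b2 * t)
        fit, smoothed = rk.fit_aif_tail(Curve(t, v), tail_start=0.0)
        assert fit.converged
        np.testing.assert_allclose(smoothed.v, v, atol=1e-4)

    def test_monoexponential_tail_accepted_as_nested_case(self):
        t = np.arange(100) * 3.0
        v = 2.0 * np.exp(-0.01 * t)
        fit, smoothed = rk.fit_aif_tail(Curve(t, v), tail_start=0.0)
        assert fit.converged
        np.testing.assert_allclose(smoothed.v, v, atol=1e-6)

    def test_samples_before_tail_start_untouched(self):
        aif = self._noisy_biexp_aif()
        tail_start = 90.0
        _, smoothed = rk.fit_aif_tail(aif, tail_start=tail_start)
        keep = aif.t < tail_start
        np.testing.assert_array_equal(smoothed.v[keep], aif.v[keep])

    def test_fitted_tail_monotone_non_increasing(self):
        aif = self._noisy_biexp_aif()
        fit, smoothed = rk.fit_aif_tail(aif, tail_start=90.0)
        assert fit.converged
        tail = smoothed.v[smoothed.t >= 90.0]
        assert np.all(tail >= 0)
        assert np.all(np.diff(tail) <= 1e-12)

    def test_short_tail_rejected(self):
        aif = self._noisy_biexp_aif()
        with pytest.raises(ValueError):
            rk.fit_aif_tail(aif, tail_start=aif.t[-3])


class TestToPlasma:
    def test_identity_at_zero_hematocrit(self, blood_aif):
        out = rk.to_plasma(blood_aif, hct=0.0)
        np.testing.assert_array_equal(out.v, blood_aif.v)

    def test_rabbit_hematocrit_scale(self):
        aif = Curve(np.arange(5) * 3.0, np.ones(5))
        out = rk.to_plasma(aif)  # default Hct = 0.45
        np.testing.assert_allclose(out.v, 1.0 / 0.55, rtol=1e-12)

    def test_preserves_shape(self, blood_aif):
        out = rk.to_plasma(blood_aif, hct=0.3)
        ratio = out.v[blood_aif.v > 0] / blood_aif.v[blood_aif.v > 0]
        np.testing.assert_allclose(ratio, ratio[0])

    def test_invalid_hematocrit_rejected(self, blood_aif):
        with pytest.raises(ValueError):
            rk.to_plasma(blood_aif, hct=1.0)
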