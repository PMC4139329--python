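"""Unit and property tests for the 2C-IRF forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renalpk as rk
from renalpk.kinetics_core import Curve

from conftest import convolve_oracle


class TestIRF:
    @pytest.mark.parametrize(
        "tau, m, t, expected",
        [
            (3.2, 0.2, 0.0, 1.0),          # plateau before the minimal transit time
            (3.2, 0.2, 3.2, 1.0),          # continuity at the breakpoint
            (3.2, 0.2, 8.2, np.exp(-1.0)), # one washout time constant past tau
            (0.0, 0.1, 0.0, 1.0),
        ],
    )
    def test_values(self, tau, m, t, expected):
        assert rk.irf_evaluate(rk.IRFParams(tau=tau, m=m), t) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rk.irf_evaluate(rk.IRFParams(tau=1.0, m=0.1), -0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            rk.IRFParams(tau=-1.0, m=0.1)
        with pytest.raises(ValueError):
            rk.IRFParams(tau=1.0, m=0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        tau=st.floats(0.0, 20.0),
        m=st.floats(1e-3, 2.0),
        t=st.floats(0.0, 200.0),  # keeps m*(t - tau) clear of exp underflow
    )
    def test_bounded_in_unit_interval(self, tau, m, t):
        val = rk.irf_evaluate(rk.IRFParams(tau=tau, m=m), t)
        assert 0.0 < val <= 1.0


class TestOutflowDensity:
    def test_unit_mass(self):
        p = rk.IRFParams(tau=3.2, m=0.2)
        t = np.arange(0.0, 20.0 / p.m + p.tau, 5e-4)
        mass = np.trapezoid(rk.outflow_density(p, t), t)
        assert mass == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize(
        "tau, m, t, expected",
        [
            (0.0, 0.1, 0.0, 0.1),   # m * exp(0) at onset
            (3.2, 0.2, 1.0, 0.0),   # nothing leaves before the minimal transit time
        ],
    )
    def test_values(self, tau, m, t, expected):
        out = rk.outflow_density(rk.IRFParams(tau=tau, m=m), np.array([t]))
        assert out[0] == pytest.approx(expected, abs=1e-12)


class TestConvolutionEngine:
    @pytest.mark.parametrize("n", [3, 17, 100, 200])
    def test_matches_double_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        f = rng.normal(size=n)
        g = rng.normal(size=n)
        fast = rk.causal_convolve(f, g, dt=0.7)
        slow = convolve_oracle(f, g, dt=0.7)
        scale = np.max(np.abs(slow)) or 1.0
        assert np.max(np.abs(fast - slow)) / scale < 1e-10

    def test_rejects_mismatched_grids(self):
        with pytest.raises(ValueError):
            rk.causal_convolve(np.ones(5), np.ones(6), dt=1.0)


class TestRetentionCurves:
    def test_vascular_retention_is_irf(self, preset_2cirf):
        t = np.arange(100) * 3.0
        ret = rk.retention_curves(preset_2cirf, t)
        assert ret.r_a[0] == 1.0
        assert np.all(np.diff(ret.r_a) <= 0)
        np.testing.assert_allclose(ret.r_a, rk.irf_evaluate(preset_2cirf.irf_a, t))

    def test_tubular_retention_starts_at_zero(self, preset_2cirf):
        t = np.arange(100) * 3.0
        ret = rk.retention_curves(preset_2cirf, t)
        assert ret.r_t[0] == 0.0
        assert np.all(ret.r_t >= 0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        m_a=st.floats(0.02, 0.5),
        tau_a=st.floats(0.0, 10.0),
        m_t=st.floats(0.01, 0.3),
    )
    def test_tubular_retention_bounded_by_one(self, m_a, tau_a, m_t):
        p = rk.TwoCIRFParams(
            gfr=3.0, rpf=3.0,
            irf_a=rk.IRFParams(tau=tau_a, m=m_a),
            irf_t=rk.IRFParams(tau=0.0, m=m_t),
        )
        ret = rk.retention_curves(p, np.arange(100) * 3.0)
        assert np.max(ret.r_t) <= 1.0 + 1e-12

    def test_cascade_matches_closed_form(self):
        # tau_A = tau_T = 0: r_t is the classical two-exponential cascade
        m_a, m_t = 0.2, 0.1
        p = rk.TwoCIRFParams(
            gfr=3.0, rpf=3.0,
            irf_a=rk.IRFParams(tau=0.0, m=m_a),
            irf_t=rk.IRFParams(tau=0.0, m=m_t),
        )
        t = np.arange(0.0, 60.0, 0.01)
        ret = rk.retention_curves(p, t, upsample=1)
        analytic = (m_a / (m_a - m_t)) * (np.exp(-m_t * t) - np.exp(-m_a * t))
        idx = np.linspace(10, len(t) - 1, 10, dtype=int)
        np.testing.assert_allclose(ret.r_t[idx], analytic[idx], atol=5e-6)

    def test_cortical_retention_is_flow_weighted_sum(self, preset_2cirf):
        t = np.arange(100) * 3.0
        ret = rk.retention_curves(preset_2cirf, t)
        expected = (3.0 / 60.0) * ret.r_a + (3.0 / 60.0) * ret.r_t
        np.testing.assert_allclose(ret.r_cortex, expected, rtol=1e-12)


class TestPredictCortex:
    def test_zero_aif_gives_zero_output(self, preset_2cirf):
        aif = Curve(np.arange(50) * 3.0, np.zeros(50))
        out = rk.predict_cortex(preset_2cirf, aif)
        assert np.all(out.v == 0)

    def test_linear_in_aif(self, preset_2cirf, plasma_aif):
        one = rk.predict_cortex(preset_2cirf, plasma_aif)
        double = rk.predict_cortex(preset_2cirf, plasma_aif.with_values(2 * plasma_aif.v))
        np.testing.assert_allclose(double.v, 2 * one.v, rtol=1e-12)

    def test_time_shift_equivariant(self, preset_2cirf, plasma_aif):
        # shifting the input by two frames shifts the output by two frames
        shift = 2
        shifted = np.concatenate([np.zeros(shift), plasma_aif.v[:-shift]])
        out_ref = rk.predict_cortex(preset_2cirf, plasma_aif).v
        out_shift = rk.predict_cortex(preset_2cirf, plasma_aif.with_values(shifted)).v
        np.testing.assert_allclose(out_shift[shift:], out_ref[:-shift], atol=1e-12)

    def test_impulse_response_matches_oracle(self, preset_2cirf):
        # a single-sample impulse exposes the discrete kernel: the output must
        # equal the brute-force convolution of the impulse with r_cortex
        t = np.arange(80) * 3.0
        impulse = np.zeros(80)
        impulse[4] = 1.0 / 3.0  # area 1 mM*s
        aif = Curve(t, impulse)
        out = rk.predict_cortex(preset_2cirf, aif)
        ret = rk.retention_curves(preset_2cirf, t, upsample=1)
        oracle = convolve_oracle(impulse, ret.r_cortex, 3.0)
        np.testing.assert_allclose(out.v, oracle, rtol=1e-10, atol=1e-15)

    def test_empty_aif_rejected(self, preset_2cirf):
        with pytest.raises(ValueError):
            Curve(np.array([]), np.array([]))


class TestMeanTransitTime:
    @pytest.mark.parametrize(
        "tau, m, expected",
        [(3.2, 0.2, 8.2), (0.0, 0.1, 10.0), (5.0, 0.05, 25.0)],
    )
    def test_irf_area_equals_tau_plus_inverse_rate(self, tau, m, expected):
        p = rk.IRFParams(tau=tau, m=m)
        t = np.arange(0.0, tau + 20.0 / m, 0.01)
        est = rk.mean_transit_time(t, rk.irf_evaluate(p, t))
        assert not est.truncated
        assert est.value == pytest.approx(expected, rel=5e-3)

    def test_tubular_area_preserved_under_convolution(self):
        # convolving a unit-mass density with IRF_T preserves its area, so
        # the numerical MTT of r_t equals tau_T + 1/m_T for any vascular IRF
        p = rk.TwoCIRFParams(
            gfr=3.0, rpf=3.0,
            irf_a=rk.IRFParams(tau=3.2, m=0.2),
            irf_t=rk.IRFParams(tau=0.0, m=0.1),
        )
        t = np.arange(0.0, 250.0, 0.05)
        ret = rk.retention_curves(p, t, upsample=1)
        est = rk.mean_transit_time(t, ret.r_t)
        assert est.value == pytest.approx(p.irf_t.mtt, rel=5e-3)

    def test_truncation_flagged(self):
        p = rk.IRFParams(tau=0.0, m=0.01)
        t = np.arange(0.0, 50.0, 0.5)  # far from decayed
        est = rk.mean_transit_time(t, rk.irf_evaluate(p, t))
        assert est.truncated


class TestMTTSummary:
    def test_additive(self, preset_2cirf):
        mtt_a, mtt_t, mtt_k = rk.mtt_summary(preset_2cirf)
        assert mtt_a == pytest.approx(8.2)
        assert mtt_t == pytest.approx(10.0)
        assert mtt_k == pytest.approx(mtt_a + mtt_t)

    def test_vanishing_vascular_compartment(self):
        p = rk.TwoCIRFParams(
            gfr=3.0, rpf=3.0,
            irf_a=rk.IRFParams(tau=0.0, m=1e6),
            irf_t=rk.IRFParams(tau=0.0, m=0.1),
        )
        _, mtt_t, mtt_k = rk.mtt_summary(p)
        assert mtt_k == pytest.approx(mtt_t, rel=1e-4)


class TestCurve:
    def test_round_trips_through_csv(self, tmp_path, plasma_aif):
        path = tmp_path / "curve.csv"
        plasma_aif.to_csv(path)
        back = Curve.from_csv(path)
        np.testing.assert_allclose(back.t, plasma_aif.t)
        np.testing.assert_allclose(back.v, plasma_aif.v)

    @pytest.mark.parametrize(
        "t, v",
        [
            ([0.0, 1.0, 3.0], [0.0, 0.0, 0.0]),   # non-uniform
            ([0.0, 1.0], [0.0]),                   # length mismatch
            ([1.0, 0.0], [0.0, 0.0]),              # decreasing
            ([0.0], [0.0]),                        # too short
        ],
    )
    def test_invalid_grids_rejected(self, t, v):
        with pytest.raises(ValueError):
            Curve(np.array(t), np.array(v))

    def test_params_round_trip_through_dict(self, preset_2cirf):
        d = preset_2cirf.to_dict()
        assert d == {"gfr": 3.0, "rpf": 3.0, "m_a": 0.2, "tau_a": 3.2, "m_t": 0.1, "tau_t": 0.0}
        assert rk.TwoCIRFParams.from_dict(d) == preset_2cirf
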