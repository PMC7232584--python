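import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hysteresim import (
    PDParams,
    PlasmaCurve,
    ParameterError,
    RangeError,
    effect_site,
    effect_site_ode_oracle,
    hill_effect,
    interp_plasma,
    ke_from_t_half,
    predict_time_effect,
    t_half_e,
)
from hysteresim.pkpd_core import _knot_effect_site

from conftest import random_plasma_curve

LN2 = np.log(2.0)


class TestPlasmaCurve:
    def test_valid(self):
        c = PlasmaCurve([0.0, 10.0], [0.0, 1000.0])
        assert c.span == (0.0, 10.0)

    @pytest.mark.parametrize(
        "times,concs",
        [
            ([0.0], [1.0]),                      # too few knots
            ([0.0, 0.0], [1.0, 2.0]),            # not strictly increasing
            ([10.0, 0.0], [1.0, 2.0]),           # decreasing
            ([0.0, 1.0], [1.0, -2.0]),           # negative concentration
            ([0.0, 1.0], [1.0, np.nan]),         # non-finite
            ([0.0, 1.0, 2.0], [1.0, 2.0]),       # length mismatch
        ],
    )
    def test_invalid(self, times, concs):
        with pytest.raises(ParameterError):
            PlasmaCurve(times, concs)


class TestInterpPlasma:
    def test_midpoint_of_linear_segment(self):
        curve = PlasmaCurve([0.0, 10.0], [0.0, 1000.0])
        assert interp_plasma(curve, 5.0) == pytest.approx(500.0)

    def test_constant_segment(self):
        curve = PlasmaCurve([0.0, 150.0], [600.0, 600.0])
        assert interp_plasma(curve, 77.0) == pytest.approx(600.0)

    def test_second_segment(self):
        # hand linear interpolation on the second segment
        curve = PlasmaCurve([0.0, 10.0, 20.0], [0.0, 2000.0, 600.0])
        assert interp_plasma(curve, 15.0) == pytest.approx(1300.0)

    def test_exact_at_knots(self):
        curve = PlasmaCurve([0.0, 10.0, 20.0], [0.0, 2000.0, 600.0])
        assert interp_plasma(curve, 10.0) == pytest.approx(2000.0)

    def test_no_extrapolation(self):
        curve = PlasmaCurve([0.0, 10.0], [0.0, 1000.0])
        with pytest.raises(RangeError):
            interp_plasma(curve, 10.5)
        with pytest.raises(RangeError):
            interp_plasma(curve, -0.1)


class TestEffectSite:
    def test_steady_state_fixed_point(self):
        curve = PlasmaCurve([0.0, 50.0, 150.0], [600.0, 600.0, 600.0])
        for ke in (0.003, 0.05, 0.7):
            ce = effect_site(curve, ke, 600.0, np.linspace(0, 150, 40))
            np.testing.assert_allclose(ce.concentrations, 600.0, rtol=1e-12)

    def test_constant_plasma_closed_form(self):
        c, ke = 800.0, 0.04
        curve = PlasmaCurve([0.0, 300.0], [c, c])
        t = np.array([0.0, t_half_e(ke), 100.0])
        ce = effect_site(curve, ke, 0.0, t)
        expected = c * (1.0 - np.exp(-ke * t))
        np.testing.assert_allclose(ce.concentrations, expected, rtol=1e-12)
        assert ce.concentrations[1] == pytest.approx(c / 2.0)

    def test_ramp_matches_ode_oracle(self):
        curve = PlasmaCurve([0.0, 10.0], [0.0, 1000.0])
        ke = LN2 / 5.0
        got = effect_site(curve, ke, 0.0, [10.0]).concentrations[0]
        want = effect_site_ode_oracle(curve, ke, 0.0, [10.0], step=0.001).concentrations[0]
        assert got == pytest.approx(want, rel=1e-6)

    def test_continuity_across_knots(self):
        rng = np.random.default_rng(11)
        curve = random_plasma_curve(rng)
        ke = 0.02
        ce_knots = _knot_effect_site(curve, ke, curve.concentrations[0])
        # closed-form evaluation at knot times must reproduce the
        # propagated knot values exactly
        ce = effect_site(curve, ke, curve.concentrations[0], curve.times)
        np.testing.assert_allclose(ce.concentrations, ce_knots, rtol=1e-9)

    def test_equilibration_limit(self):
        curve = PlasmaCurve([0.0, 60.0], [0.0, 1200.0])
        t = np.linspace(0.1, 60.0, 200)
        cp = interp_plasma(curve, t)
        gap = {}
        for ke in (10.0, 100.0):
            ce = effect_site(curve, ke, 0.0, t)
            gap[ke] = np.max(np.abs(ce.concentrations - cp))
        assert gap[100.0] < gap[10.0]
        assert gap[100.0] < 2.0  # Ce -> Cp pointwise for fast equilibration

    def test_parameter_errors(self):
        curve = PlasmaCurve([0.0, 10.0], [0.0, 1000.0])
        with pytest.raises(ParameterError):
            effect_site(curve, -1.0, 0.0, [5.0])
        with pytest.raises(RangeError):
            effect_site(curve, 0.1, 0.0, [11.0])

    def test_nonnegative_for_nonnegative_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            curve = random_plasma_curve(rng)
            ce = effect_site(curve, 0.05, 0.0, np.linspace(0, 180, 100))
            assert np.all(ce.concentrations >= -1e-9)
            assert np.all(np.isfinite(ce.concentrations))


class TestOdeOracle:
    def test_constant_steady_state(self):
        curve = PlasmaCurve([0.0, 150.0], [600.0, 600.0])
        ce = effect_site_ode_oracle(curve, 0.05, 600.0, [0.0, 75.0, 150.0], step=0.01)
        np.testing.assert_allclose(ce.concentrations, 600.0, rtol=1e-9)

    def test_oracle_vs_closed_form_random_curves(self):
        rng = np.random.default_rng(202)
        for _ in range(15):
            curve = random_plasma_curve(rng)
            ke = float(np.exp(rng.uniform(np.log(LN2 / 277), np.log(LN2 / 5))))
            t = np.linspace(0.0, 180.0, 37)
            a = effect_site(curve, ke, curve.concentrations[0], t).concentrations
            b = effect_site_ode_oracle(curve, ke, curve.concentrations[0], t, 0.001).concentrations
            rel = np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12))
            assert rel < 1e-5

    def test_step_convergence(self):
        curve = PlasmaCurve([0.0, 10.0, 40.0], [0.0, 2000.0, 500.0])
        t = [5.0, 20.0, 40.0]
        coarse = effect_site_ode_oracle(curve, 0.1, 0.0, t, step=0.002).concentrations
        fine = effect_site_ode_oracle(curve, 0.1, 0.0, t, step=0.001).concentrations
        assert np.max(np.abs(coarse - fine) / np.abs(fine)) < 1e-8

    def test_bad_step(self):
        curve = PlasmaCurve([0.0, 10.0], [0.0, 1000.0])
        with pytest.raises(ParameterError):
            effect_site_ode_oracle(curve, 0.1, 0.0, [5.0], step=0.0)


class TestHillEffect:
    PARAMS = PDParams(e0=50.0, emax=35.0, ec50=600.0, n=3.0, ke=0.05)

    def test_zero_concentration_gives_baseline(self):
        assert hill_effect(0.0, self.PARAMS) == pytest.approx(50.0)

    def test_asymptote(self):
        assert hill_effect(1e12, self.PARAMS) == pytest.approx(85.0, abs=1e-6)

    def test_half_maximal_at_ec50(self):
        assert hill_effect(600.0, self.PARAMS) == pytest.approx(67.5)

    @given(
        n=st.floats(0.5, 15.0),
        ec50=st.floats(50.0, 5000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_midpoint_for_every_n(self, n, ec50):
        p = PDParams(e0=50.0, emax=35.0, ec50=ec50, n=n, ke=0.05)
        assert hill_effect(ec50, p) == pytest.approx(50.0 + 17.5)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, data):
        n = data.draw(st.floats(0.5, 8.0))
        p = PDParams(e0=50.0, emax=35.0, ec50=600.0, n=n, ke=0.05)
        ce = np.sort(
            np.array(
                data.draw(
                    st.lists(st.integers(0, 2000), min_size=2, max_size=20, unique=True)
                ),
                dtype=float,
            )
        )
        vals = hill_effect(ce, p)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals >= p.e0)
        assert np.all(vals < p.e0 + p.emax + 1e-9)

    def test_negative_ce_rejected(self):
        with pytest.raises(ParameterError):
            hill_effect(-1.0, self.PARAMS)


class TestHalfLife:
    def test_ln2_per_min(self):
        assert t_half_e(LN2) == pytest.approx(1.0)

    def test_paper_extremes(self):
        assert ke_from_t_half(5.0) == pytest.approx(LN2 / 5.0)
        assert ke_from_t_half(5.0) == pytest.approx(0.1386, abs=1e-4)
        assert ke_from_t_half(277.0) == pytest.approx(0.002502, abs=1e-6)

    @given(st.floats(1e-4, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, ke):
        assert ke_from_t_half(t_half_e(ke)) == pytest.approx(ke, rel=1e-14)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            t_half_e(0.0)
        with pytest.raises(ParameterError):
            ke_from_t_half(-3.0)


class TestPredictTimeEffect:
    def test_zero_plasma_flat_baseline(self):
        curve = PlasmaCurve([0.0, 150.0], [0.0, 0.0])
        p = PDParams(e0=50.0, emax=35.0, ec50=600.0, n=3.0, ke=0.05)
        series = predict_time_effect(curve, p, np.linspace(0, 150, 20))
        np.testing.assert_allclose(series.values, 50.0, rtol=1e-12)
        assert not series.noisy

    def test_constant_at_ec50_flat_half_maximal(self):
        curve = PlasmaCurve([0.0, 150.0], [600.0, 600.0])
        p = PDParams(e0=50.0, emax=35.0, ec50=600.0, n=3.0, ke=0.05)
        series = predict_time_effect(curve, p, np.linspace(0, 150, 20))
        np.testing.assert_allclose(series.values, 67.5, rtol=1e-12)

    def test_severe_peaks_before_mild(self, mean_plasma, frames, presets):
        severe = predict_time_effect(mean_plasma, presets[-1].params, frames)
        mild = predict_time_effect(mean_plasma, presets[0].params, frames)
        t_peak_severe = frames[np.argmax(severe.values)]
        t_peak_mild = frames[np.argmax(mild.values)]
        assert t_peak_severe < t_peak_mild
        # severe preset rises and falls; mild is still near its maximum at the end
        assert severe.values[-1] < severe.values.max() - 1.0
        assert mild.values[-1] > mild.values.max() - 0.5
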