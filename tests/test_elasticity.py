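"""WLC fitting, effective spring constant, loading-rate assignment."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from forcekinetics import (
    RuptureEvent,
    SimulationConfig,
    effective_spring_constant,
    fit_wlc,
    loading_rate,
    simulate_force_curve,
    wlc_force,
)
from forcekinetics.curve_io import ForceCurve
from forcekinetics.elasticity import annotate_loading_rates, wlc_stiffness
from forcekinetics.events import detect_events


def _wlc_stretch_curve(lc=50.0, lp=0.38, kc=1e6, n=300, f_max=40.0):
    """Noiseless retract trace following an exact WLC law (rigid cantilever)."""
    x = np.linspace(0.0, 0.97 * lc, n)
    f = wlc_force(x, lc, lp)
    keep = f <= f_max
    x, f = x[keep], f[keep]
    seg = np.array(["retract"] * x.size, dtype=object)
    return ForceCurve(z=x, force=f, segment=seg, kc=kc, velocity=3000.0,
                      sampling_rate=1000.0, curve_id="wlc")


class TestWlcFit:
    def test_noiseless_recovery_of_known_chain(self):
        curve = _wlc_stretch_curve(lc=50.0, lp=0.38)
        event = RuptureEvent(force=float(curve.force[-1]), position=float(curve.z[-1]),
                             noise_sd=1.0)
        fit = fit_wlc(curve, event)
        assert fit.contour_length == pytest.approx(50.0, rel=0.02)
        assert fit.persistence_length == pytest.approx(0.38, rel=0.05)
        assert fit.kl == pytest.approx(
            float(wlc_stiffness(curve.z[-1], 50.0, 0.38)), rel=0.05)

    def test_stiffness_monotone_in_rupture_force(self):
        curve = _wlc_stretch_curve()
        kls = []
        for frac in (0.4, 0.7, 1.0):
            event = RuptureEvent(force=float(frac * curve.force[-1]),
                                 position=float(curve.z[-1]), noise_sd=1.0)
            kls.append(fit_wlc(curve, event).kl)
        assert kls[0] < kls[1] < kls[2]

    def test_bound_trace_is_convex_upward(self):
        """Simulated bound retractions stretch in the nonlinear, parabolic-
        like fashion of a compliant tether: stiffness grows along the pull."""
        cfg = SimulationConfig(bind_sat_A=1.0, tau_on=1e-6, double_sat_frac=0.0,
                               noise_sd=0.0)
        curve = simulate_force_curve(cfg, 0.1, seed=11)
        sl = curve.segment_slice("retract")
        z, f = curve.z[sl], curve.force[sl]
        stretch = (z > 5) & (f > 1) & (z < curve.truth["rupture_positions"][0] - 5)
        slope = np.gradient(f[stretch], z[stretch])
        assert slope[-1] > slope[0] > 0

    def test_too_few_samples_raises(self):
        from forcekinetics import FitFailure
        curve = _wlc_stretch_curve(n=12)
        event = RuptureEvent(force=5.0, position=float(curve.z[3]), noise_sd=1.0)
        with pytest.raises(FitFailure):
            fit_wlc(curve, event)


class TestSprings:
    def test_equal_springs_halve(self):
        assert effective_spring_constant(10.0, 10.0) == pytest.approx(5.0)

    def test_rigid_linker_limit(self):
        assert effective_spring_constant(10.0, 1e9) == pytest.approx(10.0, rel=1e-6)

    def test_nominal_cantilever_with_soft_tether(self):
        # 0.01 N/m cantilever + ~0.35 pN/nm molecular spring: keff ~ 0.34,
        # giving ~1000 pN/s at 3000 nm/s -- inside the 50-5000 pN/s regime
        keff = effective_spring_constant(10.0, 0.35)
        assert keff == pytest.approx(0.338, abs=0.005)
        assert loading_rate(3000.0, keff) == pytest.approx(1015, rel=0.01)

    @given(kc=st.floats(0.1, 100.0), kl=st.floats(0.01, 1000.0))
    def test_symmetric_and_bounded(self, kc, kl):
        keff = effective_spring_constant(kc, kl)
        assert keff == pytest.approx(effective_spring_constant(kl, kc))
        assert keff <= min(kc, kl) * (1 + 1e-12)

    @pytest.mark.parametrize("args", [(0.0, 1.0), (1.0, -2.0)])
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            effective_spring_constant(*args)


class TestLoadingRate:
    def test_unit_product(self):
        assert loading_rate(3000.0, 1.0) == 3000.0

    def test_linearity(self):
        assert loading_rate(2 * 1234.0, 0.7) == pytest.approx(2 * loading_rate(1234.0, 0.7))

    def test_invalid(self):
        with pytest.raises(ValueError):
            loading_rate(0.0, 1.0)

    def test_velocity_sweep_spans_study_regime(self):
        """With the default tether, velocities 150-12000 nm/s give loading
        rates covering roughly 50-5000 pN/s."""
        rates = [loading_rate(v, effective_spring_constant(10.0, 0.35))
                 for v in (150.0, 12000.0)]
        assert rates[0] == pytest.approx(50, rel=0.05)
        assert 3500 < rates[1] < 5500

    def test_assigned_rates_match_generator_truth(self):
        cfg = SimulationConfig(bind_sat_A=1.0, tau_on=1e-6, double_sat_frac=0.0, seed=21)
        rng = np.random.default_rng(3)
        ratios = []
        for i in range(40):
            curve = simulate_force_curve(cfg, 0.1, rng, f"c{i}")
            if curve.truth["bond_class"] != "single":
                continue
            events = detect_events(curve)
            if len(events) != 1:
                continue
            annotate_loading_rates(curve, events)
            if np.isfinite(events[0].loading_rate):
                ratios.append(events[0].loading_rate / curve.truth["loading_rates"][0])
        assert len(ratios) > 10
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)
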