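"""Force PDFs, bimodal gating, Bell-Evans ML fit, two-bond reductions."""
import math

import numpy as np
import pytest

from forcekinetics import (
    BellParameters,
    DegenerateFit,
    RuptureEvent,
    bond_lifetime,
    build_pdf,
    fit_bell_ml,
    fit_bimodal,
    gate_single_bond,
    most_probable_force,
    predict_double_bond,
    sample_double_bond_forces,
    sample_rupture_forces,
    two_bond_off_rate,
)

KBT = 4.114


def _events(forces, rate=1000.0, sigma=3.0, floor=0.0):
    return [RuptureEvent(force=float(f), position=float(10 * i + 10), noise_sd=sigma,
                         loading_rate=rate, detection_floor=floor)
            for i, f in enumerate(np.atleast_1d(forces))]


class TestForcePdf:
    def test_single_event_unit_area_peak(self):
        pdf = build_pdf(_events([50.0]))
        assert pdf.integral() == pytest.approx(1.0, abs=1e-3)
        assert pdf.mode() == pytest.approx(50.0, abs=0.3)

    def test_duplication_doubles_integral_keeps_shape(self):
        evs = _events([30.0, 45.0, 60.0])
        one = build_pdf(evs)
        two = build_pdf(evs + evs)
        assert two.integral() == pytest.approx(2 * one.integral(), rel=1e-3)
        np.testing.assert_allclose(two.density / two.n_events,
                                   np.interp(two.grid, one.grid, one.density) / one.n_events,
                                   atol=1e-9)

    def test_integral_equals_event_count(self, canonical_bell, rng):
        forces = sample_rupture_forces(canonical_bell, 1000.0, 200, rng)
        pdf = build_pdf(_events(forces))
        assert pdf.integral() == pytest.approx(200, rel=5e-3)

    def test_two_population_fixture_is_bimodal(self, canonical_bell, rng):
        singles = sample_rupture_forces(canonical_bell, 1000.0, 800, rng)
        doubles = sample_double_bond_forces(canonical_bell, 1000.0, 400, rng)
        pdf = build_pdf(_events(np.concatenate([singles, doubles]), sigma=1.5))
        f_single = most_probable_force(canonical_bell, 1000.0)
        f_double = predict_double_bond(canonical_bell, [1000.0])[0].mode
        lo = int(np.searchsorted(pdf.grid, 0.5 * (f_single + f_double)))
        mode_low = pdf.grid[np.argmax(pdf.density[:lo])]
        mode_high = pdf.grid[lo + np.argmax(pdf.density[lo:])]
        assert mode_low == pytest.approx(f_single, abs=4.0)
        assert mode_high == pytest.approx(f_double, abs=5.0)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            build_pdf([])


class TestBimodal:
    def test_mixture_recovery(self, rng):
        forces = np.concatenate([rng.normal(30, 5, 1400), rng.normal(60, 7, 600)])
        fit = fit_bimodal(list(forces))
        assert fit.mu1 == pytest.approx(30.0, abs=1.0)
        assert fit.mu2 == pytest.approx(60.0, abs=1.0)
        assert fit.w1 == pytest.approx(0.7, abs=0.05)

    def test_identical_components_degenerate(self, rng):
        forces = rng.normal(30, 5, 500)
        with pytest.raises(DegenerateFit):
            fit_bimodal(list(forces))

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            fit_bimodal([1.0, 2.0, 3.0])


class TestGate:
    def test_window_definition(self):
        from forcekinetics.off_kinetics import BimodalFit
        bm = BimodalFit(mu1=30.0, sigma1=5.0, w1=0.6, mu2=60.0, sigma2=7.0, w2=0.4)
        events = _events([19.9, 20.0, 30.0, 40.0, 40.1])
        kept = gate_single_bond(events, bm)
        assert [e.force for e in kept] == [20.0, 30.0, 40.0]

    def test_retains_95_percent_of_pure_gaussian(self, rng):
        from forcekinetics.off_kinetics import BimodalFit
        bm = BimodalFit(mu1=30.0, sigma1=5.0, w1=1.0, mu2=30.0, sigma2=5.0, w2=0.0)
        events = _events(rng.normal(30, 5, 20_000))
        assert len(gate_single_bond(events, bm)) / 20_000 == pytest.approx(0.9545, abs=0.006)

    def test_gating_reduces_double_bond_contamination(self, canonical_bell, rng):
        singles = sample_rupture_forces(canonical_bell, 1000.0, 1500, rng)
        doubles = sample_double_bond_forces(canonical_bell, 1000.0, 500, rng)
        labels = np.array([0] * 1500 + [1] * 500)
        events = _events(np.concatenate([singles, doubles]))
        bm = fit_bimodal(events)
        kept_idx = [i for i, e in enumerate(events)
                    if bm.mu1 - 2 * bm.sigma1 <= e.force <= bm.mu1 + 2 * bm.sigma1]
        contamination_gated = labels[kept_idx].mean()
        assert contamination_gated < labels.mean()


class TestBellMl:
    def test_closed_form_mode_line_round_trip(self, canonical_bell):
        """Noiseless most-probable forces at four rates refit by least
        squares on the F* vs ln r line recover the parameters exactly."""
        rates = np.array([100.0, 500.0, 1000.0, 3000.0])
        fstar = np.array([most_probable_force(canonical_bell, r) for r in rates])
        slope, intercept = np.polyfit(np.log(rates), fstar, 1)
        xbeta = KBT / slope
        koff = xbeta / KBT * math.exp(-intercept / slope)
        assert xbeta == pytest.approx(1.23, rel=1e-9)
        assert koff == pytest.approx(0.23, rel=1e-9)

    @pytest.mark.parametrize("convolve", [False, True])
    def test_recovery_within_confidence_interval(self, canonical_bell, convolve):
        """Raw-force likelihood on clean draws; error-convolved likelihood
        on draws blurred by Gaussian measurement noise."""
        rng = np.random.default_rng(314)
        events = []
        for r in (100.0, 500.0, 1000.0, 3000.0):
            draws = sample_rupture_forces(canonical_bell, r, 500, rng)
            if convolve:
                draws = np.clip(draws + rng.normal(0.0, 3.0, draws.size), 0.1, None)
            events += _events(draws, rate=r)
        fit = fit_bell_ml(events, convolve_noise=convolve)
        p = fit.params
        assert abs(math.log10(p.koff / 0.23)) < 3.0 * p.log_koff_err + 0.03
        assert abs(math.log10(p.xbeta / 1.23)) < 3.0 * p.log_xbeta_err + 0.03

    def test_errors_shrink_with_sample_size(self, canonical_bell):
        rng = np.random.default_rng(99)
        def fit_n(n):
            events = []
            for r in (100.0, 1000.0):
                events += _events(sample_rupture_forces(canonical_bell, r, n, rng), rate=r)
            return fit_bell_ml(events).params
        small, large = fit_n(250), fit_n(2500)
        assert large.log_koff_err < small.log_koff_err
        assert large.log_xbeta_err < small.log_xbeta_err
        # ~1/sqrt(n) scaling
        assert large.log_koff_err == pytest.approx(small.log_koff_err / math.sqrt(10), rel=0.5)

    def test_truncated_likelihood_corrects_floor_censoring(self, canonical_bell):
        """Discarding sub-floor ruptures biases the plain fit; conditioning
        each event on its detection floor removes the bias."""
        rng = np.random.default_rng(5)
        floor = 12.0
        events = []
        for r in (100.0, 300.0, 1000.0):
            draws = sample_rupture_forces(canonical_bell, r, 4000, rng)
            events += _events(draws[draws >= floor], rate=r, floor=floor)
        fit = fit_bell_ml(events)
        plain = fit_bell_ml([RuptureEvent(force=e.force, position=e.position,
                                          noise_sd=e.noise_sd, loading_rate=e.loading_rate)
                             for e in events])
        err_trunc = abs(math.log10(fit.params.koff / 0.23))
        err_plain = abs(math.log10(plain.params.koff / 0.23))
        assert err_trunc < err_plain
        assert err_trunc < 0.15

    def test_narrow_rate_span_warns(self, canonical_bell):
        rng = np.random.default_rng(11)
        events = _events(sample_rupture_forces(canonical_bell, 1000.0, 200, rng))
        fit = fit_bell_ml(events)
        assert any("span" in w for w in fit.warnings)


class TestClosedForms:
    @pytest.mark.parametrize("koff,expected", [(0.23, 0.15), (0.77, 0.51), (0.31, 0.21),
                                               (1.5, 1.0)])
    def test_two_bond_off_rate(self, koff, expected):
        assert round(two_bond_off_rate(koff), 2) == expected

    @pytest.mark.parametrize("koff,expected", [(0.23, 4.3), (0.31, 3.2), (1.0, 1.0)])
    def test_bond_lifetime(self, koff, expected):
        assert round(bond_lifetime(koff), 1) == expected

    @pytest.mark.parametrize("func", [two_bond_off_rate, bond_lifetime])
    def test_non_positive_rejected(self, func):
        with pytest.raises(ValueError):
            func(0.0)


class TestDoubleBondPrediction:
    def test_mode_exceeds_single_bond_line(self, canonical_bell):
        rates = [100.0, 1000.0, 3000.0]
        preds = predict_double_bond(canonical_bell, rates)
        for r, pred in zip(rates, preds):
            assert pred.mode > most_probable_force(canonical_bell, r)

    def test_density_normalised(self, canonical_bell):
        pred = predict_double_bond(canonical_bell, [500.0])[0]
        assert np.trapezoid(pred.density, pred.grid) == pytest.approx(1.0, abs=1e-6)

    def test_master_equation_matches_stochastic_simulator(self, canonical_bell):
        """Two independent routes through the same Markov model: exact-
        inversion sampling vs numerical master equation."""
        pred = predict_double_bond(canonical_bell, [1000.0])[0]
        draws = np.sort(sample_double_bond_forces(canonical_bell, 1000.0, 10_000, seed=3))
        cdf_at = np.interp(draws, pred.grid, pred.cdf())
        n = draws.size
        ks = max(np.max(np.abs(np.arange(1, n + 1) / n - cdf_at)),
                 np.max(np.abs(cdf_at - np.arange(n) / n)))
        assert ks < 0.02

    def test_binned_simulator_means_on_predicted_branch(self, canonical_bell):
        """The predicted double-bond branch overlays the simulated double
        ruptures' binned means across loading rates."""
        rng = np.random.default_rng(6)
        for r in (300.0, 1000.0, 3000.0):
            pred = predict_double_bond(canonical_bell, [r])[0]
            pred_mean = np.trapezoid(pred.grid * pred.density, pred.grid)
            sim_mean = sample_double_bond_forces(canonical_bell, r, 4000, rng).mean()
            assert sim_mean == pytest.approx(pred_mean, rel=0.03)

    def test_invalid_arguments(self, canonical_bell):
        with pytest.raises(ValueError):
            predict_double_bond(canonical_bell, [-10.0])
        with pytest.raises(ValueError):
            predict_double_bond(canonical_bell, [100.0], load_sharing="bogus")
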