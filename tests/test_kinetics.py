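"""CRTD construction, exponential fitting, photobleaching, rates."""

import numpy as np
import pytest

from kymotrace import kinetics
from kymotrace.errors import (
    FitFailureError,
    InvalidCorrectionError,
    InvalidInputError,
    InvalidParameterError,
)
from kymotrace.kinetics import (
    build_crtd,
    correct_lifetime,
    estimate_kd,
    estimate_photobleach,
    event_rate,
    fit_dwells_mle,
    fit_exponentials,
    select_model,
    weighted_average_lifetime,
)
from kymotrace.simulate import SimulationConfig, simulate_dwell_times, simulate_kymograph


class TestCRTD:
    def test_simple_counting(self):
        crtd = build_crtd([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(crtd.t, [1, 2, 3])
        np.testing.assert_array_equal(crtd.counts, [3, 2, 1])

    def test_equal_durations_single_step(self):
        crtd = build_crtd([2.0, 2.0, 2.0])
        np.testing.assert_array_equal(crtd.t, [2.0])
        np.testing.assert_array_equal(crtd.counts, [3])

    def test_crtd_at_zero_is_event_count(self):
        d = simulate_dwell_times([(3.0, 1.0)], 500, seed=1)
        crtd = build_crtd(np.concatenate([[0.0], d]))
        assert crtd.t[0] == 0.0
        assert crtd.counts[0] == 501

    def test_exponential_sample_log_slope(self):
        d = simulate_dwell_times([(5.0, 1.0)], 10000, seed=2)
        crtd = build_crtd(d)
        slope = np.polyfit(crtd.t, np.log(crtd.counts), 1)[0]
        assert slope == pytest.approx(-1 / 5.0, rel=0.05)

    def test_non_increasing_property(self, rng):
        for _ in range(20):
            d = rng.exponential(rng.uniform(0.5, 50), size=rng.integers(1, 200))
            crtd = build_crtd(d)
            assert np.all(np.diff(crtd.counts) <= 0)

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            build_crtd([])


class TestExponentialFit:
    def test_single_component_recovery(self):
        d = simulate_dwell_times([(5.0, 1.0)], 1000, seed=3)
        fit = fit_exponentials(build_crtd(d), 1)
        assert fit.lifetimes[0] == pytest.approx(5.0, rel=0.10)

    def test_two_component_recovery(self):
        d = simulate_dwell_times([(1.0, 0.7), (20.0, 0.3)], 2000, seed=4)
        fit = fit_exponentials(build_crtd(d), 2)
        assert fit.lifetimes[0] == pytest.approx(1.0, rel=0.20)
        assert fit.lifetimes[1] == pytest.approx(20.0, rel=0.20)
        assert fit.fractions[0] == pytest.approx(0.7, abs=0.10)

    def test_noiseless_crtd_exact_recovery(self):
        t = np.linspace(0.1, 30, 50)
        counts = 800.0 * np.exp(-t / 6.5)
        fit = fit_exponentials(kinetics.CRTD(t=t, counts=counts), 1)
        assert fit.lifetimes[0] == pytest.approx(6.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(800.0, rel=1e-6)

    def test_mle_mode_agrees(self):
        d = simulate_dwell_times([(5.0, 1.0)], 2000, seed=5)
        fit = fit_dwells_mle(d, 1)
        assert fit.lifetimes[0] == pytest.approx(d.mean(), rel=1e-3)

    def test_too_few_thresholds_raise(self):
        with pytest.raises(InvalidInputError):
            fit_exponentials(build_crtd([1.0, 2.0, 3.0]), 1)


class TestModelSelection:
    def test_single_exponential_selects_one(self):
        hits = 0
        for seed in range(50):
            d = simulate_dwell_times([(5.0, 1.0)], 500, seed=seed)
            if select_model(build_crtd(d)).n_components == 1:
                hits += 1
        assert hits >= 45  # >= 90%

    def test_separated_mixture_selects_two(self):
        d = simulate_dwell_times([(1.0, 0.6), (15.0, 0.4)], 2000, seed=6)
        assert select_model(build_crtd(d)).n_components == 2

    def test_small_sample_never_three(self):
        for seed in range(10):
            d = simulate_dwell_times([(1.0, 0.5), (10.0, 0.5)], 20, seed=seed)
            assert select_model(build_crtd(d)).n_components <= 2


class TestWeightedAverage:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ([(7.7, 0.78), (42.9, 0.22)], 15.4),
            ([(8.9, 0.78), (183.0, 0.22)], 47.2),
            ([(0.9, 0.67), (227.0, 0.33)], 75.5),
            ([(1.8, 0.14), (7.6, 0.44), (95.5, 0.42)], 43.7),
            ([(4.0, 0.24), (54.4, 0.76)], 42.3),
            ([(5.0, 1.0)], 5.0),
        ],
    )
    def test_reported_values(self, components, expected):
        assert round(weighted_average_lifetime(components), 1) == expected

    def test_negative_raises(self):
        with pytest.raises(InvalidParameterError):
            weighted_average_lifetime([(-1.0, 1.0)])

    def test_bad_fraction_sum_raises(self):
        with pytest.raises(InvalidParameterError):
            weighted_average_lifetime([(5.0, 0.5), (1.0, 0.4)])


class TestPhotobleachCorrection:
    def test_no_bleaching_is_identity(self):
        assert correct_lifetime(5.0, np.inf) == 5.0

    def test_closed_form(self):
        assert correct_lifetime(5.0, 100.0) == pytest.approx(1 / (0.2 - 0.01))

    def test_component_pair_consistency(self):
        """A single bleach lifetime explains both printed values of a
        two-component fit: solve tau_b from the slow pair, check the fast."""
        tau_b = 1.0 / (1.0 / 48.7 - 1.0 / 227.0)   # ~62 s from the slow pair
        assert tau_b == pytest.approx(62.0, abs=0.5)
        # the fast 0.9 s component is unchanged at printing precision
        assert correct_lifetime(0.9, tau_b) == pytest.approx(0.9, abs=0.02)

    def test_monotone_in_both_arguments(self):
        taus = np.linspace(1, 10, 10)
        corrected = [correct_lifetime(t, 50.0) for t in taus]
        assert np.all(np.diff(corrected) > 0)
        bleaches = np.linspace(20, 500, 10)
        corrected_b = [correct_lifetime(10.0, b) for b in bleaches]
        assert np.all(np.diff(corrected_b) < 0)  # weaker bleaching, less correction
        assert np.all(np.array(corrected_b) >= 10.0)

    def test_bleach_dominated_raises(self):
        with pytest.raises(InvalidCorrectionError):
            correct_lifetime(10.0, 5.0)


def _immobilized_config(**kw):
    base = dict(
        n_lines=3000, dna_length=48502,
        damage_sites=list(range(100, 48400, 50)),  # ~1000 immobilized emitters
        arrival_rate=10.0, dwell_components=[(1e6, 1.0)],
        photobleach_lifetime=20.0, emission_rate=30.0,
        background_rate=0.5, seed=13,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestPhotobleachEstimate:
    def test_recovery(self):
        kymo, _ = simulate_kymograph(_immobilized_config())
        model = estimate_photobleach(kymo)
        assert model.lifetime == pytest.approx(20.0, rel=0.10)

    def test_constant_emission_fails(self):
        kymo, _ = simulate_kymograph(_immobilized_config(
            photobleach_lifetime=np.inf,
        ))
        with pytest.raises(FitFailureError):
            estimate_photobleach(kymo, max_lifetime=1000.0)

    def test_pulsed_excitation_triples_apparent_lifetime(self):
        kymo, _ = simulate_kymograph(_immobilized_config(
            n_lines=9000, exposure_scheme=[(0.011, 0.022)],
        ))
        model = estimate_photobleach(kymo)
        assert model.lifetime == pytest.approx(60.0, rel=0.15)


class TestRates:
    def test_events_per_second(self):
        assert event_rate(list(range(39)), 300.0) == pytest.approx(0.13)

    def test_no_events(self):
        assert event_rate([], 100.0) == 0.0

    def test_kd_from_rates(self):
        # tau_c ~ 39 s -> koff ~ 0.0256 /s; with kon 6.4e7 /M/s: 0.4 nM
        kd = estimate_kd(koff=1 / 39.0, kon=6.4e7)
        assert kd == pytest.approx(0.4e-9, rel=0.02)

    def test_kd_trivial_identities(self):
        assert estimate_kd(0.5, 0.5) == 1.0
        assert estimate_kd(0.5, 2.0) == 2 * estimate_kd(0.5, 4.0)
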