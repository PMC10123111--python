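"""Simulator statistics: dwell mixtures, diffusing tracks, kymograph rendering."""

import numpy as np
import pytest
from scipy import stats

from kymotrace import kinetics
from kymotrace.errors import InvalidGeometryError, InvalidParameterError
from kymotrace.simulate import (
    SimulationConfig,
    simulate_dwell_times,
    simulate_kymograph,
    simulate_reference_sequence,
    simulate_track,
)


class TestDwellTimes:
    @pytest.mark.parametrize(
        "components,n,expected_mean,tol",
        [
            ([(5.0, 1.0)], 10000, 5.0, 0.15),          # 3 sigma of the sample mean
            ([(7.7, 0.78), (42.9, 0.22)], 50000, 15.44, 0.02 * 15.44 * 2.5),
        ],
    )
    def test_sample_mean_matches_mixture_mean(self, components, n, expected_mean, tol):
        d = simulate_dwell_times(components, n, seed=1)
        assert d.shape == (n,)
        assert np.all(d >= 0)
        assert abs(d.mean() - expected_mean) < tol

    def test_degenerate_mixture_equals_single_exponential(self):
        """Two identical components are indistinguishable from one."""
        d = simulate_dwell_times([(1.0, 0.5), (1.0, 0.5)], 10000, seed=2)
        ks = stats.kstest(d, stats.expon(scale=1.0).cdf)
        assert ks.pvalue > 0.01

    def test_mixture_passes_ks_against_true_survival(self):
        components = [(1.0, 0.7), (20.0, 0.3)]

        def cdf(t):
            return 1 - 0.7 * np.exp(-t / 1.0) - 0.3 * np.exp(-t / 20.0)

        d = simulate_dwell_times(components, 10000, seed=3)
        ks = stats.kstest(d, cdf)
        assert ks.pvalue > 0.01

    def test_reproducible_given_seed(self):
        a = simulate_dwell_times([(2.0, 1.0)], 100, seed=9)
        b = simulate_dwell_times([(2.0, 1.0)], 100, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [[(-1.0, 1.0)], [(0.0, 1.0)], [(1.0, 0.5)]])
    def test_invalid_components_raise(self, bad):
        with pytest.raises(InvalidParameterError):
            simulate_dwell_times(bad, 10, seed=0)


class TestTracks:
    def test_zero_diffusion_is_constant(self):
        pos = simulate_track(0.0, 1.0, 0.033, 50, start=3.0, seed=0)
        np.testing.assert_array_equal(pos, 3.0)

    def test_brownian_increment_variance(self):
        D, dt = 0.05, 0.033
        pos = simulate_track(D, 1.0, dt, 10000, seed=4)
        var = np.var(np.diff(pos))
        assert abs(var - 2 * D * dt) < 0.05 * 2 * D * dt

    def test_msd_at_first_lag(self):
        D, dt = 0.5, 0.033
        pos = simulate_track(D, 1.0, dt, 20000, seed=5)
        msd1 = np.mean(np.diff(pos) ** 2)
        assert abs(msd1 - 2 * D * dt) < 0.1 * 2 * D * dt

    @pytest.mark.parametrize("alpha", [0.0, -0.5, 2.5])
    def test_invalid_alpha_raises(self, alpha):
        with pytest.raises(InvalidParameterError):
            simulate_track(0.1, alpha, 0.033, 10)


class TestKymograph:
    def test_background_only(self):
        cfg = SimulationConfig(
            n_lines=200, dna_length=10000, damage_sites=[5000],
            arrival_rate=0.05, emission_rate=0.0, background_rate=2.0, seed=1,
        )
        kymo, _ = simulate_kymograph(cfg)
        n = kymo.counts[0].size
        se = np.sqrt(2.0 / n)
        assert abs(kymo.counts[0].mean() - 2.0) < 3 * se

    def test_immobile_event_renders_gaussian_column(self):
        """With no noise/bleach, the streak is the PSF at the site's pixel."""
        cfg = SimulationConfig(
            n_lines=400, dna_length=10000, damage_sites=[5000],
            arrival_rate=0.05, dwell_components=[(5.0, 1.0)],
            emission_rate=200.0, background_rate=0.0, seed=3,
        )
        kymo, truth = simulate_kymograph(cfg)
        ev = max(truth.events, key=lambda e: e.frames.size)
        assert ev.frames.size > 0
        site_px = kymo.um_to_pixel(cfg.site_position_um(5000))
        frame = kymo.counts[0][ev.frames[ev.frames.size // 2]]
        assert abs(np.argmax(frame) - site_px) <= 1
        # empirical PSF width from the rendered profile
        prof = frame / frame.sum()
        px = np.arange(prof.size)
        sigma = np.sqrt(np.sum(prof * (px - np.sum(prof * px)) ** 2))
        assert abs(sigma - cfg.psf_sigma) < 0.5

    def test_bleaching_dominates_long_dwells(self):
        """dwell tau=1000 s >> tau_b=20 s: streak lengths follow the bleach clock."""
        # a site stays occupied for the full (unbleached) dwell, so many
        # sites are needed to accumulate hundreds of events
        cfg = SimulationConfig(
            n_lines=40000, dna_length=48502,
            damage_sites=list(range(500, 48000, 160)),
            arrival_rate=0.05, dwell_components=[(1000.0, 1.0)],
            photobleach_lifetime=20.0, seed=6,
        )
        _, truth = simulate_kymograph(cfg)
        streaks = np.array([
            min(e.end, e.bleach_time) - e.start
            for e in truth.events
            if min(e.end, e.bleach_time) < cfg.n_lines * cfg.line_time
        ])
        assert streaks.size >= 300
        fit = kinetics.fit_exponentials(kinetics.build_crtd(streaks), 1)
        assert fit.lifetimes[0] == pytest.approx(20.0, rel=0.15)

    def test_ground_truth_within_duration(self):
        cfg = SimulationConfig(
            n_lines=500, dna_length=10000, damage_sites=[2000, 8000],
            arrival_rate=0.1, dwell_components=[(1.0, 1.0)], seed=8,
        )
        kymo, truth = simulate_kymograph(cfg)
        for e in truth.events:
            assert 0 <= e.start < kymo.duration
            assert e.dwell == pytest.approx(e.end - e.start)

    def test_identical_seeds_bit_identical(self):
        cfg = SimulationConfig(
            n_lines=300, dna_length=10000, damage_sites=[5000],
            arrival_rate=0.05, seed=11,
        )
        k1, t1 = simulate_kymograph(cfg)
        k2, t2 = simulate_kymograph(cfg)
        np.testing.assert_array_equal(k1.counts, k2.counts)
        assert t1.to_frame().equals(t2.to_frame())

    def test_tether_shorter_than_psf_raises(self):
        cfg = SimulationConfig(
            n_lines=10, dna_length=10, tether_span=0.0004,
            damage_sites=[5], arrival_rate=0.01, seed=0,
        )
        with pytest.raises(InvalidGeometryError):
            simulate_kymograph(cfg)

    def test_pulsed_excitation_slows_bleach_clock(self):
        """1/3 duty cycle triples the wall-clock bleach lifetime."""
        sites = list(range(2000, 47000, 1500))
        base = dict(
            n_lines=40000, dna_length=48502, damage_sites=sites,
            arrival_rate=0.002, dwell_components=[(1000.0, 1.0)],
            photobleach_lifetime=20.0, seed=12,
        )
        _, continuous = simulate_kymograph(SimulationConfig(**base))
        _, pulsed = simulate_kymograph(SimulationConfig(
            **base, exposure_scheme=[(0.034, 0.066)],
        ))

        def mean_streak(truth, duration):
            s = [min(e.end, e.bleach_time) - e.start for e in truth.events
                 if min(e.end, e.bleach_time) < duration]
            return np.mean(s)

        dur = 40000 * 0.033
        ratio = mean_streak(pulsed, dur) / mean_streak(continuous, dur)
        assert ratio == pytest.approx(3.0, rel=0.25)


class TestReferenceSequence:
    def test_motif_planted_and_scrubbed(self):
        seq = simulate_reference_sequence(
            5000, "GCTCTTC", top_positions=[100, 2000], bottom_positions=[3500],
            seed=5,
        )
        rc = "GAAGAGC"
        assert len(seq) == 5000
        assert seq.count("GCTCTTC") == 2
        assert seq.count(rc) == 1
        assert seq[100:107] == "GCTCTTC"
        assert seq[3500:3507] == rc
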