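"""Detection precision, linking behavior, and blink-gap curation."""

import numpy as np
import pytest

from kymotrace.errors import InvalidInputError
from kymotrace.simulate import SimulationConfig, simulate_kymograph, simulate_track
from kymotrace.tracking import (
    Detection,
    Track,
    curate_tracks,
    detect_line_centers,
    link_detections,
    track_kymograph,
    track_summary,
)


def _gaussian_line(center_px, amp=100.0, sigma=1.5, n_px=30, offset=0.0):
    x = np.arange(n_px)
    return amp * np.exp(-0.5 * ((x - center_px) / sigma) ** 2) + offset


def _grid_search_center(y, sigma=1.5):
    """Independent oracle: dense grid search for the best-fitting center."""
    x = np.arange(y.size)
    centers = np.arange(2, y.size - 2, 0.001)
    best, best_sse = None, np.inf
    for c in centers:
        model = np.exp(-0.5 * ((x - c) / sigma) ** 2)
        amp = np.dot(model, y) / np.dot(model, model)
        sse = np.sum((y - amp * model) ** 2)
        if sse < best_sse:
            best, best_sse = c, sse
    return best


class TestDetection:
    def test_integer_center_recovered_exactly(self):
        dets = detect_line_centers(_gaussian_line(10.0), min_amplitude=20.0)
        assert len(dets) == 1
        assert dets[0].center_um * 10 == pytest.approx(10.0, abs=0.01)

    def test_subpixel_center_matches_grid_oracle(self):
        y = _gaussian_line(10.4)
        dets = detect_line_centers(y, min_amplitude=20.0)
        oracle = _grid_search_center(y)
        assert len(dets) == 1
        center_px = dets[0].center_um * 10  # 100 nm pixels
        assert center_px == pytest.approx(10.4, abs=0.05)
        assert center_px == pytest.approx(oracle, abs=0.02)

    def test_flat_background_empty(self, rng):
        dets = detect_line_centers(np.full(30, 5.0), min_amplitude=10.0)
        assert dets == []

    def test_two_lines_resolved(self):
        y = _gaussian_line(8.0) + _gaussian_line(22.0)
        dets = detect_line_centers(y, min_amplitude=20.0)
        assert len(dets) == 2

    def test_short_frame_raises(self):
        with pytest.raises(InvalidInputError):
            detect_line_centers(np.ones(4))


def _det(frame, pos_um, amp=50.0):
    return Detection(frame=frame, center_um=pos_um, amplitude=amp,
                     sigma_px=1.5, background=1.0)


class TestLinking:
    def test_immobile_streak_single_track(self):
        frames = [[_det(f, 5.0)] for f in range(30)]
        tracks = link_detections(frames, max_step=0.3)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 30

    def test_distant_streaks_never_merged(self):
        frames = [[_det(f, 5.0), _det(f, 7.0)] for f in range(20)]
        tracks = link_detections(frames, max_step=0.3)
        assert len(tracks) == 2
        for t in tracks:
            assert np.ptp(t.positions_um) < 0.1

    def test_diffusing_track_stays_linked(self):
        """max_step at 3 sigma of the step size keeps >=95% of detections."""
        D, dt = 0.05, 0.033
        sigma_step = np.sqrt(2 * D * dt)
        kept = []
        for seed in range(100):
            pos = simulate_track(D, 1.0, dt, 99, start=8.0, seed=seed)
            frames = [[_det(f, p)] for f, p in enumerate(pos)]
            tracks = link_detections(frames, max_step=3 * sigma_step)
            kept.append(max(len(t.detections) for t in tracks) / 100)
        assert np.mean(kept) >= 0.95


def _segment(frames, pos_um, line_time=0.033):
    return Track(channel=0, line_time=line_time,
                 detections=[_det(f, pos_um) for f in frames])


class TestCuration:
    def test_blink_gap_merged(self):
        """5 s + 5 s segments, 1.5 s gap, 50 nm apart: one 11.5 s track."""
        lt = 0.1
        a = _segment(range(0, 50), 5.00, lt)          # [0, 5) s
        b = _segment(range(65, 115), 5.05, lt)        # [6.5, 11.5) s
        out = curate_tracks([a, b], merge_distance=100.0, merge_gap=2.0)
        assert len(out) == 1
        assert out[0].duration == pytest.approx(11.5)

    def test_long_gap_not_merged(self):
        lt = 0.1
        a = _segment(range(0, 50), 5.0, lt)
        b = _segment(range(75, 125), 5.0, lt)         # gap 2.5 s
        assert len(curate_tracks([a, b])) == 2

    def test_distant_positions_not_merged(self):
        lt = 0.1
        a = _segment(range(0, 50), 5.0, lt)
        b = _segment(range(60, 110), 5.3, lt)         # 300 nm apart, 1 s gap
        assert len(curate_tracks([a, b])) == 2

    def test_transitive_merge(self):
        lt = 0.1
        segs = [_segment(range(i * 60, i * 60 + 50), 5.0, lt) for i in range(4)]
        assert len(curate_tracks(segs)) == 1

    def test_idempotent(self, rng):
        lt = 0.033
        segs = []
        f = 0
        for _ in range(20):
            n = int(rng.integers(3, 30))
            segs.append(_segment(range(f, f + n), float(rng.uniform(0, 16)), lt))
            f += n + int(rng.integers(1, 120))
        once = curate_tracks(segs)
        twice = curate_tracks(once)
        assert [(t.start, t.end, t.mean_position) for t in once] == \
               [(t.start, t.end, t.mean_position) for t in twice]


class TestSummary:
    def test_duration_includes_final_frame(self):
        t = _segment(range(0, 30), 5.0, 0.033)
        duration, mean_pos, start, end = track_summary(t)
        assert duration == pytest.approx(30 * 0.033)

    def test_single_frame_duration_is_line_time(self):
        t = _segment([7], 5.0, 0.033)
        assert track_summary(t)[0] == pytest.approx(0.033)

    def test_mean_position_unweighted(self):
        t = Track(channel=0, line_time=0.033,
                  detections=[_det(0, 5.0), _det(1, 5.2)])
        assert track_summary(t)[1] == pytest.approx(5.1)

    def test_empty_track_raises(self):
        with pytest.raises(InvalidInputError):
            track_summary(Track(channel=0, detections=[], line_time=0.033))


class TestEndToEnd:
    def test_noiseless_recovery_counts_and_durations(self):
        """Every true event becomes exactly one track with matching duration."""
        cfg = SimulationConfig(
            n_lines=3000, dna_length=48502,
            damage_sites=list(range(4000, 46000, 4000)),
            arrival_rate=0.005, dwell_components=[(4.0, 1.0)],
            emission_rate=100.0, background_rate=0.5, seed=21,
        )
        kymo, truth = simulate_kymograph(cfg)
        tracks = track_kymograph(kymo, max_step=0.3, min_amplitude=25.0)
        visible = [e for e in truth.events if e.frames.size > 0]
        assert len(tracks) == len(visible)
        tracks = sorted(tracks, key=lambda t: (t.start, t.mean_position))
        visible = sorted(visible, key=lambda e: (e.frames[0] * cfg.line_time,
                                                 e.positions_um[0]))
        for t, e in zip(tracks, visible):
            observed = e.frames.size * cfg.line_time
            assert abs(t.duration - observed) <= 2 * cfg.line_time
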