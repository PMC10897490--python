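"""Spot detection, track linking, and tethering-event extraction."""

import numpy as np
import pytest

from oracles import best_assignment_tracks

from mitoquant.synthetic import TimelapseSpec, gen_timelapse
from mitoquant.tethering import (
    TrackingParams,
    detect_foci,
    extract_events,
    link_tracks,
    segment_mito_frames,
    tether_stats,
)


def _gauss_spot(frame, r, c, sigma=1.5, amp=150.0):
    rr, cc = np.mgrid[: frame.shape[0], : frame.shape[1]]
    frame += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))


PARAMS = TrackingParams()


class TestDetectFoci:
    def test_single_spot_recovered_subpixel(self):
        frame = np.zeros((40, 40))
        _gauss_spot(frame, 17.4, 22.8)
        spots = detect_foci(frame, PARAMS)
        assert len(spots) == 1
        assert abs(spots[0, 0] - 17.4) < 1 and abs(spots[0, 1] - 22.8) < 1

    def test_blank_frame_empty(self):
        assert len(detect_foci(np.zeros((30, 30)), PARAMS)) == 0

    def test_two_well_separated_spots(self):
        frame = np.zeros((60, 60))
        _gauss_spot(frame, 15, 15)
        _gauss_spot(frame, 45, 45)
        assert len(detect_foci(frame, PARAMS)) == 2


class TestLinkTracks:
    def test_jittering_spot_single_track(self):
        rng = np.random.default_rng(0)
        spots = [np.array([[20 + rng.normal(0, 0.5), 20 + rng.normal(0, 0.5), 100.0]])
                 for _ in range(20)]
        tracks = link_tracks(spots, PARAMS)
        assert len(tracks) == 1 and len(tracks[0].positions) == 20

    def test_gap_closing_bridges_one_missing_frame(self):
        spots = [np.array([[20.0, 20.0, 100.0]])] * 5
        spots[2] = np.empty((0, 3))
        tracks = link_tracks(spots, PARAMS)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 3, 4]

    def test_two_distant_spots_no_identity_swap(self):
        """Greedy linking agrees with the exhaustive assignment oracle
        when spots stay far apart."""
        rng = np.random.default_rng(1)
        per_frame = []
        for t in range(10):
            a = [10 + rng.normal(0, 0.4), 10 + rng.normal(0, 0.4)]
            b = [40 + rng.normal(0, 0.4), 40 + rng.normal(0, 0.4)]
            per_frame.append(np.array([a + [100.0], b + [100.0]]))
        tracks = link_tracks(per_frame, PARAMS)
        assert len(tracks) == best_assignment_tracks(
            [s[:, :2] for s in per_frame], PARAMS.max_link_px
        ) == 2
        for tr in tracks:
            pos = np.array([tr.positions[t] for t in tr.frames])
            assert pos.std(axis=0).max() < 2.0  # never jumped to the other spot


class TestExtractEvents:
    def test_event_recovery_with_outcomes(self):
        """Programmed events are recovered with exact durations and outcomes."""
        spec = TimelapseSpec(n_events=5, dwell_dist=("point", 30.0), p_fusion=0.4, seed=3)
        s = gen_timelapse(spec)
        spots = [detect_foci(f, PARAMS) for f in s.stack[:, 0]]
        tracks = link_tracks(spots, PARAMS)
        events = extract_events(tracks, segment_mito_frames(s.stack[:, 1]), PARAMS)
        assert len(events) == 5
        rec = sorted((e.start_frame, e.duration_s, e.outcome) for e in events)
        tru = sorted(
            (int(r.start_frame), r.duration_s, r.outcome) for r in s.events.itertuples()
        )
        assert rec == tru

    def test_durations_are_multiples_of_dt_above_cutoff(self):
        spec = TimelapseSpec(n_events=6, dwell_dist=("shifted_exponential", 20, 20), seed=9)
        s = gen_timelapse(spec)
        spots = [detect_foci(f, PARAMS) for f in s.stack[:, 0]]
        events = extract_events(
            link_tracks(spots, PARAMS), segment_mito_frames(s.stack[:, 1]), PARAMS
        )
        for e in events:
            assert e.duration_s > PARAMS.min_event_s
            assert e.duration_s % PARAMS.dt_s == pytest.approx(0.0)

    def test_mismatched_frames_raise(self):
        spec = TimelapseSpec(n_events=1, seed=1)
        s = gen_timelapse(spec)
        spots = [detect_foci(f, PARAMS) for f in s.stack[:, 0]]
        tracks = link_tracks(spots, PARAMS)
        with pytest.raises(ValueError):
            extract_events(tracks, segment_mito_frames(s.stack[:5, 1]), PARAMS)


class TestTetherStats:
    def _events(self, durations, outcomes):
        from mitoquant.tethering import TetherEvent
        return [
            TetherEvent(i, i, 0, int(d // 3), d, o, (1, 2))
            for i, (d, o) in enumerate(zip(durations, outcomes))
        ]

    def test_mean_and_sem(self):
        ev = self._events([18.0, 30.0], ["fused", "separated"])
        out = tether_stats({"wt": ev})
        assert out.mean_duration_s.iloc[0] == pytest.approx(24.0)
        assert out.sem_duration_s.iloc[0] == pytest.approx(6.0)
        assert out.n_fruitful.iloc[0] == 1

    def test_all_fused_no_unfruitful(self):
        ev = self._events([18.0, 21.0, 24.0], ["fused"] * 3)
        out = tether_stats({"wt": ev})
        assert out.n_unfruitful.iloc[0] == 0

    def test_two_condition_ratio_and_ttest(self):
        wt = self._events([24.0, 27.0, 30.0, 33.0, 36.0], ["fused"] * 5)
        ko = self._events([54.0, 57.0, 60.0, 63.0, 66.0], ["separated"] * 5)
        out = tether_stats({"wt": wt, "ko": ko})
        assert out.duration_ratio.iloc[0] == pytest.approx(2.0)

    def test_empty_condition_raises(self):
        with pytest.raises(ValueError):
            tether_stats({"wt": []})
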