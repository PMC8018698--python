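"""Trajectory post-processing and both event detectors."""

import numpy as np
import pytest

from stridehall.events import (Event, EventSeries, Trajectory,
                               detect_events_marker, detect_events_markerless,
                               postprocess_trajectory, validate_sequence)
from stridehall.simulate import GaitProfile, generate_gait_trajectory


def traj(t, x=None, y=None, z=None, rate=60.0):
    n = len(t)
    pos = np.zeros((n, 3))
    for c, v in enumerate((x, y, z)):
        if v is not None:
            pos[:, c] = v
    return Trajectory(np.asarray(t, dtype=float), pos, "test", rate)


class TestPostprocess:
    def test_constant_trajectory_unchanged(self):
        t = np.arange(100) / 60.0
        out = postprocess_trajectory(traj(t, x=np.full(100, 7.0), y=np.full(100, -3.0)))
        np.testing.assert_allclose(out.positions[:, 0], 7.0, atol=1e-9)
        np.testing.assert_allclose(out.positions[:, 1], -3.0, atol=1e-9)

    def test_timestamps_preserved_exactly(self, rng):
        t = np.sort(rng.uniform(0, 3, 200))
        t += np.arange(200) * 1e-6  # strictly increasing
        out = postprocess_trajectory(traj(t, z=rng.normal(0, 5, 200)))
        np.testing.assert_array_equal(out.times, t)

    @pytest.mark.parametrize("mode,fs,hi_gain_max", [
        ("markerless", 60.0, 0.10),   # 12 Hz cut-off: 25 Hz attenuated > 90%
        ("marker", 100.0, 0.35),      # 20 Hz cut-off: milder roll-off
    ])
    def test_low_frequency_kept_high_attenuated(self, mode, fs, hi_gain_max):
        t = np.arange(int(4 * fs)) / fs
        lo = 10.0 * np.sin(2 * np.pi * 2.0 * t)
        hi = 10.0 * np.sin(2 * np.pi * 25.0 * t)
        out = postprocess_trajectory(traj(t, z=lo + hi, rate=fs), mode=mode)
        z = out.positions[:, 2]
        # project onto each component on the interior (away from edges)
        sl = slice(int(fs // 2), -int(fs // 2))
        g_lo = np.dot(z[sl], lo[sl]) / np.dot(lo[sl], lo[sl])
        g_hi = np.dot(z[sl], hi[sl]) / np.dot(hi[sl], hi[sl])
        assert g_lo == pytest.approx(1.0, abs=0.05)    # 2 Hz preserved within 5%
        assert abs(g_hi) < hi_gain_max

    def test_planted_spike_removed_and_bridged(self):
        t = np.arange(120) / 60.0
        clean = 50.0 * np.sin(2 * np.pi * 1.0 * t)
        y = clean.copy()
        y[60] += 400.0  # a 10-sigma spike
        out = postprocess_trajectory(traj(t, y=y))
        assert abs(out.positions[60, 1] - clean[60]) < 2.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            postprocess_trajectory(traj(np.arange(10) / 60.0))


def clean_trajectories(duration=4.5, fps=60.0):
    gt = generate_gait_trajectory(GaitProfile(), duration, fps, seed=0)
    return gt


def events_match(series, gt_events, code, tol_s):
    got = [e.time for e in series if e.code == code]
    want = [e.time for e in gt_events if e.code == code]
    matched = 0
    for g in got:
        if any(abs(g - w) <= tol_s for w in want):
            matched += 1
    return matched, len(got), len(want)


class TestMarkerDetector:
    def test_clean_signals_within_one_frame(self):
        gt = clean_trajectories()
        # detections snap to the 60 Hz frame grid while true event times
        # fall between frames: +-1 frame of the nearest sample allows up to
        # 1.5 frame periods in continuous time
        tol = 1.5 / 60 + 1e-9
        for side in ("left", "right"):
            ev = detect_events_marker(gt.trajectories[(side, "heel")],
                                      gt.trajectories[(side, "toe")], side)
            for kind in ("FS", "FO"):
                code = side[0].upper() + kind
                matched, ngot, _ = events_match(ev, gt.events, code, tol)
                assert ngot >= 2
                assert matched == ngot  # every detection is a true event

    def test_small_bump_not_a_peak(self):
        # one genuine swing bump per cycle plus a spurious bump at 0.5*max
        t = np.arange(240) / 60.0
        z = np.zeros_like(t)
        for c in (0.5, 2.5):
            z += 100.0 * np.exp(-0.5 * ((t - c) / 0.12) ** 2)
        z += 50.0 * np.exp(-0.5 * ((t - 1.5) / 0.08) ** 2)
        ev = detect_events_marker(traj(t, z=z), traj(t, z=np.zeros_like(t)))
        # FS found between the two genuine peaks only; the 50% bump adds none
        fs = [e for e in ev if e.kind == "FS"]
        assert len(fs) == 1
        assert 0.5 < fs[0].time < 2.5

    def test_high_dip_not_a_candidate(self):
        # a concave dip at 25% of the vertical range is not in the bottom 20%
        t = np.arange(300) / 60.0
        z = 100.0 * np.exp(-0.5 * ((t - 1.0) / 0.15) ** 2) \
            + 100.0 * np.exp(-0.5 * ((t - 4.0) / 0.15) ** 2) \
            + 25.0 * np.exp(-0.5 * ((t - 2.5) / 0.5) ** 2)
        # between the peaks z dips to ~25 (25% of range) at t~1.9 and 3.1 —
        # the lowest dip at 2.5 sits at 25% so nothing qualifies below 20%
        ev = detect_events_marker(traj(t, z=z), traj(t, z=np.zeros_like(t)))
        assert all(not (1.5 < e.time < 3.5) for e in ev if e.kind == "FS")

    def test_fewer_than_two_peaks_gives_empty(self):
        t = np.arange(100) / 60.0
        z = 100.0 * np.exp(-0.5 * ((t - 0.8) / 0.1) ** 2)
        ev = detect_events_marker(traj(t, z=z), traj(t, z=np.zeros_like(t)))
        assert len([e for e in ev if e.kind == "FS"]) == 0


class TestMarkerlessDetector:
    def test_clean_signals_within_one_frame(self):
        gt = clean_trajectories()
        tol = 1.5 / 60 + 1e-9
        for side in ("left", "right"):
            ev = detect_events_markerless(gt.trajectories[(side, "heel")],
                                          gt.trajectories[(side, "toe")], side)
            for kind in ("FS", "FO"):
                code = side[0].upper() + kind
                matched, ngot, _ = events_match(ev, gt.events, code, tol)
                assert ngot >= 2
                assert matched == ngot

    def test_plateau_with_no_dip_uses_initial_estimate(self):
        # AP halts at exactly t=1.0 while z stays flat: the fallback keeps
        # the AP-based frame
        t = np.arange(180) / 60.0
        y = np.where(t < 1.0, 1000.0 * (1.0 - t), 0.0)
        ev = detect_events_markerless(traj(t, y=y), traj(t, y=np.zeros_like(t)))
        fs = [e for e in ev if e.kind == "FS"]
        assert len(fs) == 1
        assert abs(fs[0].time - 1.0) <= 2 / 60 + 1e-9

    def test_continuous_motion_gives_empty(self):
        t = np.arange(180) / 60.0
        y = 1000.0 * t
        ev = detect_events_markerless(traj(t, y=y), traj(t, y=y))
        assert len(ev) == 0

    def test_deep_dip_refines_fs(self):
        # AP halts at t=1.0; a deep (>20 mm) vertical dip 2 frames later is
        # taken as the final foot strike
        t = np.arange(180) / 60.0
        y = np.where(t < 1.0, 500.0 * (1.0 - t), 0.0)
        z = np.full_like(t, 40.0)
        dip_at = 1.0 + 2 / 60
        z -= 35.0 * np.exp(-0.5 * ((t - dip_at) / 0.02) ** 2)
        ev = detect_events_markerless(traj(t, y=y, z=z), traj(t, y=np.zeros_like(t)))
        fs = [e for e in ev if e.kind == "FS"]
        assert len(fs) == 1
        assert abs(fs[0].time - dip_at) <= 1 / 60 + 1e-9


def ev(code, t):
    return Event(code, int(t * 60), t, np.zeros(3))


class TestValidateSequence:
    def test_well_ordered_unchanged(self):
        left = EventSeries([ev("LFS", 0.0), ev("LFO", 0.68), ev("LFS", 1.1), ev("LFO", 1.78)])
        right = EventSeries([ev("RFO", 0.13), ev("RFS", 0.55), ev("RFO", 1.23), ev("RFS", 1.65)])
        out = validate_sequence(left, right)
        assert [e.code for e in out] == ["LFS", "RFO", "RFS", "LFO", "LFS", "RFO", "RFS", "LFO"]

    def test_duplicate_fs_keeps_closest_to_contralateral(self):
        left = EventSeries([ev("LFO", 0.0), ev("LFS", 0.3), ev("LFS", 0.45)])
        right = EventSeries([ev("RFO", 0.6)])
        out = validate_sequence(left, right)
        codes_times = [(e.code, e.time) for e in out]
        assert ("LFS", 0.45) in codes_times
        assert ("LFS", 0.3) not in codes_times

    def test_missing_event_drops_pair(self):
        # LFO followed directly by RFO (no LFS between): both dropped
        out = validate_sequence(EventSeries([ev("LFO", 0.0)]),
                                EventSeries([ev("RFO", 0.4)]))
        assert len(out) == 0

    def test_longest_chain_survives_boundary_orphan(self):
        # an orphan LFS before the observable window must not erase the
        # complete cycle that follows
        left = EventSeries([ev("LFS", 0.1), ev("LFO", 1.75), ev("LFS", 2.25)])
        right = EventSeries([ev("RFS", 1.65), ev("RFO", 2.3), ev("RFS", 2.75)])
        out = validate_sequence(left, right)
        assert [e.code for e in out] == ["RFS", "LFO", "LFS", "RFO", "RFS"]

    def test_empty_inputs(self):
        assert len(validate_sequence(EventSeries([]), EventSeries([]))) == 0


class TestSeriesInvariants:
    def test_validated_times_non_decreasing_and_cyclic(self):
        gt = clean_trajectories()
        left = detect_events_markerless(gt.trajectories[("left", "heel")],
                                        gt.trajectories[("left", "toe")], "left")
        right = detect_events_markerless(gt.trajectories[("right", "heel")],
                                         gt.trajectories[("right", "toe")], "right")
        out = validate_sequence(left, right)
        times = [e.time for e in out]
        assert times == sorted(times)
        from stridehall.events import _SUCC

        for a, b in zip(out.events[:-1], out.events[1:]):
            assert b.code == _SUCC[a.code]
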