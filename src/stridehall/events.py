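"""Trajectory post-processing and foot-strike / foot-off detection.

Two detectors are provided.  The marker-style detector works on smooth
(optical-capture quality) trajectories: swing peaks are positive-to-negative
vertical-velocity zero crossings above 75% of the maximum height, concave
dips are negative-to-positive crossings in the bottom 20% of the vertical
range, and between two consecutive peaks the deepest dip is the event (heel
-> foot strike, toe -> foot off), with 50%-of-inter-peak-span rules guarding
dips before the first and after the last peak.

The marker-less detector is built for noisier depth-derived trajectories:
foot strike is first estimated as the frame where the heel's AP motion
halts, then refined to the nearest vertical concave dip within the next five
frames; foot off is estimated where the toe's AP displacement resumes, then
refined in the five frames before that estimate.

Before detection, trajectories are cleaned: 2-sigma outlier removal on
detrended coordinates, cubic-spline gap filling, resampling to a uniform
60 Hz grid, 4th-order dual-pass Butterworth low-pass (12 Hz marker-less,
20 Hz marker), and resampling back to the original timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt, medfilt

__all__ = [
    "Trajectory",
    "Event",
    "EventSeries",
    "postprocess_trajectory",
    "detect_events_marker",
    "detect_events_markerless",
    "validate_sequence",
]

STATIONARY_SPEED_MM_S = 50.0
STATIONARY_DWELL_FRAMES = 3
FS_DIP_WINDOW_FRAMES = 5
PEAK_FRACTION = 0.75
DIP_BOTTOM_FRACTION = 0.20

# normal gait-cycle successor for each event code
_SUCC = {"LFO": "LFS", "LFS": "RFO", "RFO": "RFS", "RFS": "LFO"}


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 3-D positions (mm) of one landmark of one foot."""

    times: np.ndarray
    positions: np.ndarray
    landmark: str = ""
    nominal_rate: float = 60.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(t) != len(p):
            raise ValueError("times and positions lengths differ")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Event:
    """One foot event: code in {LFS, LFO, RFS, RFO} plus when and where."""

    code: str
    index: int
    time: float
    position: np.ndarray

    @property
    def kind(self) -> str:          # FS / FO
        return self.code[1:]

    @property
    def side(self) -> str:
        return "left" if self.code[0] == "L" else "right"


@dataclass
class EventSeries:
    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def sorted(self) -> "EventSeries":
        return EventSeries(sorted(self.events, key=lambda e: e.time))


def _dual_pass_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """4th-order (net) zero-phase Butterworth low-pass: a 2nd-order filter
    applied forward and backward."""
    b, a = butter(2, cutoff / (fs / 2.0))
    return filtfilt(b, a, x, axis=0)


def postprocess_trajectory(raw: Trajectory, mode: str = "markerless",
                           resample_hz: float = 60.0,
                           markerless_cutoff_hz: float = 12.0,
                           marker_cutoff_hz: float = 20.0,
                           outlier_sigma: float = 2.0,
                           median_window_s: float = 0.12) -> Trajectory:
    """Clean a raw landmark trajectory; timestamps are preserved exactly.

    Marker-less mode: per-coordinate 2-sigma outlier removal on residuals
    from a short (~7-frame) moving median — a walking trajectory's raw mean
    is non-stationary, and the window must be spike-scale so that genuine
    swing motion is tracked by the trend rather than flagged — then cubic
    spline gap fill at the original timestamps, resample to a uniform
    ``resample_hz`` grid, dual-pass low-pass at 12 Hz, resample back.
    Marker mode: spline gap fill plus dual-pass low-pass at 20 Hz on the
    native (nominal-rate) grid.
    """
    if mode not in ("markerless", "marker"):
        raise ValueError(f"unknown mode {mode!r}")
    t = raw.times
    p = raw.positions
    if len(raw) < 20:
        raise ValueError("need at least 20 samples to post-process")

    if mode == "markerless":
        win = int(round(median_window_s * raw.nominal_rate))
        win = max(3, win | 1)  # odd
        keep = np.ones(len(t), dtype=bool)
        for c in range(3):
            x = p[:, c]
            trend = medfilt(x, min(win, len(x) - (1 - len(x) % 2)))
            resid = x - trend
            sd = resid.std()
            if sd > 0:
                keep &= np.abs(resid - resid.mean()) < outlier_sigma * sd
        if keep.sum() < 4:
            raise ValueError("outlier removal left too few samples")
        # shape-preserving cubic interpolation: an ordinary cubic spline
        # overshoots badly across multi-frame tracking gaps, inventing
        # excursions the low-pass filter then preserves
        splines = [PchipInterpolator(t[keep], p[keep, c]) for c in range(3)]
        filled = np.stack([s(t) for s in splines], axis=1)
        grid = np.arange(t[0], t[-1] + 1e-12, 1.0 / resample_hz)
        on_grid = np.stack([PchipInterpolator(t, filled[:, c])(grid) for c in range(3)], axis=1)
        smooth = _dual_pass_lowpass(on_grid, resample_hz, markerless_cutoff_hz)
        back = np.stack([PchipInterpolator(grid, smooth[:, c])(t) for c in range(3)], axis=1)
        return replace(raw, positions=back)

    grid = np.arange(t[0], t[-1] + 1e-12, 1.0 / raw.nominal_rate)
    on_grid = np.stack([PchipInterpolator(t, p[:, c])(grid) for c in range(3)], axis=1)
    smooth = _dual_pass_lowpass(on_grid, raw.nominal_rate, marker_cutoff_hz)
    back = np.stack([PchipInterpolator(grid, smooth[:, c])(t) for c in range(3)], axis=1)
    return replace(raw, positions=back)


def _velocity(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.gradient(x, t)


def _speed_wide(x: np.ndarray, t: np.ndarray, half: int = 2) -> np.ndarray:
    """|dx/dt| from a symmetric +-``half``-frame difference.

    The wider symmetric stencil suppresses frame-to-frame landmark jitter
    (~3x at half=2) without shifting the location of a speed transition,
    which keeps the stationary-state onset/offset unbiased in noise.
    """
    n = len(x)
    hi = np.minimum(np.arange(n) + half, n - 1)
    lo = np.maximum(np.arange(n) - half, 0)
    return np.abs((x[hi] - x[lo]) / (t[hi] - t[lo]))


def _peaks_and_dips(z: np.ndarray, t: np.ndarray):
    """Swing peaks (75% rule) and concave dips (bottom-20% rule)."""
    v = _velocity(z, t)
    peak_idx, dip_idx = [], []
    for i in range(len(v) - 1):
        if v[i] > 0 >= v[i + 1]:
            j = i if z[i] >= z[i + 1] else i + 1
            peak_idx.append(j)
        elif v[i] < 0 <= v[i + 1]:
            j = i if z[i] <= z[i + 1] else i + 1
            dip_idx.append(j)
    zmax, zmin = z.max(), z.min()
    peaks = [j for j in peak_idx if z[j] > PEAK_FRACTION * zmax]
    dips = [j for j in dip_idx if z[j] <= zmin + DIP_BOTTOM_FRACTION * (zmax - zmin)]
    return peaks, dips


def _events_from_peaks(traj: Trajectory, code: str, is_heel: bool) -> EventSeries:
    """Shared marker-style logic: deepest qualifying dip between peaks."""
    z = traj.positions[:, 2]
    peaks, dips = _peaks_and_dips(z, traj.times)
    out = []
    if len(peaks) < 2:
        return EventSeries(out)

    def emit(j: int) -> None:
        out.append(Event(code, j, traj.times[j], traj.positions[j].copy()))

    # dips between consecutive peaks: exactly one event per interval
    for a, b in zip(peaks[:-1], peaks[1:]):
        inside = [j for j in dips if a < j < b]
        if inside:
            emit(min(inside, key=lambda j: z[j]))
    # boundary dips, guarded by the 50%-of-inter-peak-span rules
    first_span = peaks[1] - peaks[0]
    before = [j for j in dips if j < peaks[0]]
    if before:
        j = min(before, key=lambda j: z[j])
        dist = peaks[0] - j
        if (is_heel and dist >= 0.5 * first_span) or (not is_heel and dist <= 0.5 * first_span):
            emit(j)
    last_span = peaks[-1] - peaks[-2]
    after = [j for j in dips if j > peaks[-1]]
    if after:
        j = min(after, key=lambda j: z[j])
        dist = j - peaks[-1]
        if (is_heel and dist < 0.5 * last_span) or (not is_heel and dist > 0.5 * last_span):
            emit(j)
    return EventSeries(sorted(out, key=lambda e: e.index))


def detect_events_marker(heel: Trajectory, toe: Trajectory, side: str = "left") -> EventSeries:
    """Marker-style detection: FS from heel dips, FO from toe dips."""
    s = side[0].upper()
    fs = _events_from_peaks(heel, f"{s}FS", is_heel=True)
    fo = _events_from_peaks(toe, f"{s}FO", is_heel=False)
    return EventSeries(fs.events + fo.events).sorted()


def _stationary_runs(speed: np.ndarray, threshold: float, dwell: int,
                     ap: np.ndarray | None = None,
                     min_step_mm: float = 200.0) -> list[tuple[int, int]]:
    """Maximal runs [start, end] (inclusive) of at least ``dwell`` frames
    with speed below threshold.

    When the AP signal is given, consecutive runs whose endpoints are less
    than ``min_step_mm`` apart are merged: a genuine swing advances the
    foot by a large fraction of a stride, so a brief speed excursion with
    no net displacement (e.g. the contralateral foot passing close by) is
    jitter inside one stance, not two stances.
    """
    below = speed < threshold
    runs = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if ap is not None and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if abs(ap[s] - ap[pe]) < min_step_mm:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    return [(s, e) for s, e in runs if e - s + 1 >= dwell]


def _concave_dips(z: np.ndarray, t: np.ndarray, min_prominence: float = 0.0) -> np.ndarray:
    """Negative-to-positive vertical-velocity crossings.

    ``min_prominence`` (mm) discards micro-dips whose depth relative to the
    neighbouring signal stays below the depth-noise floor — ripples in a
    flat stance are not vertical movement, so detectors fall back to their
    initial (AP-based) estimate instead of snapping to noise.
    """
    v = _velocity(z, t)
    idx = []
    for i in range(len(v) - 1):
        if v[i] < 0 <= v[i + 1]:
            idx.append(i if z[i] <= z[i + 1] else i + 1)
    if min_prominence > 0 and idx:
        w = 5
        kept = []
        for j in idx:
            lo = max(0, j - w)
            hi = min(len(z), j + w + 1)
            prom = min(z[lo:j + 1].max(), z[j:hi].max()) - z[j]
            if prom >= min_prominence:
                kept.append(j)
        idx = kept
    return np.array(idx, dtype=int)


def detect_events_markerless(heel: Trajectory, toe: Trajectory, side: str = "left",
                             speed_threshold: float = STATIONARY_SPEED_MM_S,
                             dwell: int = STATIONARY_DWELL_FRAMES,
                             dip_window: int = FS_DIP_WINDOW_FRAMES,
                             dip_prominence_mm: float = 20.0) -> EventSeries:
    """Marker-less detection from AP stationarity, refined by vertical dips.

    A stationary state is AP speed below ``speed_threshold`` mm/s for at
    least ``dwell`` consecutive frames.  FS is the first frame of such a
    state (skipped when the trajectory begins mid-stance), refined to the
    nearest concave vertical dip within the next ``dip_window`` frames — or
    kept as the initial estimate when no dip exists.  FO is the frame where
    AP displacement resumes, refined within the ``dip_window`` frames before
    the initial estimate.
    """
    s = side[0].upper()
    out: list[Event] = []

    heel_ap = heel.positions[:, 1]
    heel_speed = _speed_wide(heel_ap, heel.times)
    heel_dips = _concave_dips(heel.positions[:, 2], heel.times, dip_prominence_mm)
    for start, _end in _stationary_runs(heel_speed, speed_threshold, dwell, heel_ap):
        if start == 0:
            continue  # began mid-stance: no strike observed
        cand = heel_dips[(heel_dips >= start) & (heel_dips <= start + dip_window)]
        j = int(cand[np.argmin(np.abs(cand - start))]) if len(cand) else start
        out.append(Event(f"{s}FS", j, heel.times[j], heel.positions[j].copy()))

    toe_ap = toe.positions[:, 1]
    toe_speed = _speed_wide(toe_ap, toe.times)
    toe_dips = _concave_dips(toe.positions[:, 2], toe.times, dip_prominence_mm)
    for _start, end in _stationary_runs(toe_speed, speed_threshold, dwell, toe_ap):
        if end >= len(toe) - 1:
            continue  # still stationary at the end: no foot off observed
        init = end + 1  # first frame where AP displacement resumes
        cand = toe_dips[(toe_dips >= init - dip_window) & (toe_dips <= init)]
        j = int(cand[np.argmin(np.abs(cand - init))]) if len(cand) else init
        out.append(Event(f"{s}FO", j, toe.times[j], toe.positions[j].copy()))

    return EventSeries(out).sorted()


def validate_sequence(left: EventSeries, right: EventSeries,
                      max_link_gap_s: float = 1.5) -> EventSeries:
    """Merge and enforce the normal gait-cycle order LFO -> LFS -> RFO -> RFS.

    Runs of repeated candidates of one type keep only the candidate closest
    in time to the next (bounding) event.  The output is the longest
    time-ordered subsequence in which every consecutive pair follows the
    gait-cycle succession within ``max_link_gap_s``; events that cannot be
    chained to any neighbour (e.g. an LFO followed directly by an RFO with
    no LFS between them) are dropped, and a "chain" of a single event is no
    chain at all, so such isolated pairs disappear entirely.
    """
    merged = sorted(list(left.events) + list(right.events), key=lambda e: e.time)
    # collapse runs of the same code, keeping the last (closest to the next event)
    collapsed: list[Event] = []
    for e in merged:
        if collapsed and collapsed[-1].code == e.code:
            collapsed[-1] = e
        else:
            collapsed.append(e)
    n = len(collapsed)
    if n == 0:
        return EventSeries([])
    # longest valid chain by dynamic programming
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            ok = (collapsed[i].code == _SUCC[collapsed[j].code]
                  and 0 <= collapsed[i].time - collapsed[j].time <= max_link_gap_s)
            if ok and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = int(np.argmax(best))
    if best[end] < 2:
        return EventSeries([])
    chain = []
    while end != -1:
        chain.append(collapsed[end])
        end = prev[end]
    return EventSeries(chain[::-1])
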