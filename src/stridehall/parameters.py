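"""Spatiotemporal stride parameters and system-comparison statistics.

A gait cycle runs from one foot strike to the next ipsilateral foot strike.
Primary parameters come straight from validated event times and landmark
positions; derived ones (stride speed, cadence, double support) follow from
them.  Lengths are anterior-posterior (y-axis) distances and widths
medial-lateral (x-axis) distances, matching the room-frame conventions.

System comparison subtracts paired parameter samples (reference minus
test), removes error samples two population standard deviations from the
mean (false event detections), and reports mean / absolute-mean error
statistics with population-N denominators, Pearson r, and the inlier
percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import _SUCC, Event, EventSeries, Trajectory

__all__ = [
    "StrideParameterSet",
    "ErrorStats",
    "compute_stride_parameters",
    "sync_events",
    "compare_systems",
]

TEMPORAL_PARAMS = ("stride_time", "step_time", "stance_time", "swing_time", "double_support_time")
SPATIAL_PARAMS = ("stride_length", "step_length", "step_width", "foot_angle", "foot_clearance")
DERIVED_PARAMS = ("stride_speed", "cadence")
ALL_PARAMS = SPATIAL_PARAMS + TEMPORAL_PARAMS + DERIVED_PARAMS


@dataclass
class StrideParameterSet:
    """Per-cycle stride parameters as a tidy table.

    One row per (cycle, side) with columns: side, cycle_start_s plus every
    parameter in :data:`ALL_PARAMS` (mm, s, mm/s, steps/min, degrees).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def empty(cls) -> "StrideParameterSet":
        cols = ["side", "cycle_start_s", *ALL_PARAMS]
        return cls(pd.DataFrame(columns=cols))


def _cycle_events(events: list[Event], start: int) -> list[Event] | None:
    """Events of one gait cycle beginning at a FS event index in the merged
    validated list: FS, contralateral FO, contralateral FS, FO, next FS."""
    if start + 4 >= len(events):
        return None
    cyc = events[start:start + 5]
    want = [cyc[0].code]
    for _ in range(4):
        want.append(_SUCC[want[-1]])
    if [e.code for e in cyc] != want:
        return None
    return cyc


def _foot_angle_deg(heel: np.ndarray, toe: np.ndarray, direction: int) -> float:
    """Signed angle between the floor-projected heel->toe vector and the
    walking direction (+ = toe out towards +x when walking +y)."""
    v = toe - heel
    ap = direction * v[1]
    ml = direction * v[0]
    return float(np.degrees(np.arctan2(ml, ap)))


def _clearance(toe_traj: Trajectory | None, t_fo: float, t_fs: float) -> float:
    """Minimum toe height in the middle 50% of the swing window."""
    if toe_traj is None:
        return np.nan
    lo = t_fo + 0.25 * (t_fs - t_fo)
    hi = t_fo + 0.75 * (t_fs - t_fo)
    m = (toe_traj.times >= lo) & (toe_traj.times <= hi)
    if not m.any():
        return np.nan
    return float(toe_traj.positions[m, 2].min())


def compute_stride_parameters(events: EventSeries,
                              landmarks: dict[tuple[str, str], Trajectory] | None = None,
                              direction: int = -1) -> StrideParameterSet:
    """Per-cycle stride parameters from a validated event series.

    ``landmarks`` optionally maps (side, "heel"/"toe") to post-processed
    trajectories; it is needed for foot angle and foot clearance.  Lengths
    are AP (y) distances between heel positions at the relevant strikes,
    widths ML (x) distances.
    """
    evs = events.sorted().events
    rows = []
    for i, e in enumerate(evs):
        if e.kind != "FS":
            continue
        cyc = _cycle_events(evs, i)
        if cyc is None:
            continue
        fs0, fo_c, fs_c, fo_i, fs1 = cyc
        side = fs0.side
        other = fs_c.side
        stride_time = fs1.time - fs0.time
        step_time = fs1.time - fs_c.time            # contralateral FS -> ipsilateral FS
        stance_time = fo_i.time - fs0.time
        swing_time = fs1.time - fo_i.time
        double_support = (fo_c.time - fs0.time) + (fo_i.time - fs_c.time)
        stride_length = abs(fs1.position[1] - fs0.position[1])
        step_length = abs(fs1.position[1] - fs_c.position[1])
        step_width = abs(fs1.position[0] - fs_c.position[0])
        angle = np.nan
        clearance = np.nan
        if landmarks is not None:
            heel_tr = landmarks.get((side, "heel"))
            toe_tr = landmarks.get((side, "toe"))
            if heel_tr is not None and toe_tr is not None:
                j = int(np.argmin(np.abs(heel_tr.times - fs0.time)))
                k = int(np.argmin(np.abs(toe_tr.times - fs0.time)))
                angle = _foot_angle_deg(heel_tr.positions[j], toe_tr.positions[k], direction)
            clearance = _clearance(toe_tr, fo_i.time, fs1.time)
        rows.append({
            "side": side,
            "cycle_start_s": fs0.time,
            "stride_length": stride_length,
            "step_length": step_length,
            "step_width": step_width,
            "foot_angle": angle,
            "foot_clearance": clearance,
            "stride_time": stride_time,
            "step_time": step_time,
            "stance_time": stance_time,
            "swing_time": swing_time,
            "double_support_time": double_support,
            "stride_speed": stride_length / stride_time,
            "cadence": 120.0 / stride_time,
        })
    if not rows:
        return StrideParameterSet.empty()
    return StrideParameterSet(pd.DataFrame(rows))


@dataclass
class SyncedEventPairs:
    """Matched (reference, test) events plus the recovered clock offset (s)."""

    pairs: list[tuple[Event, Event]]
    offset: float

    def __len__(self) -> int:
        return len(self.pairs)


def sync_events(reference: EventSeries, test: EventSeries,
                position_tol_mm: float = 100.0,
                max_pair_dt_s: float = 0.25) -> SyncedEventPairs:
    """Align two independently clocked event series.

    The first event sharing a type between the series, with foot AP
    positions within ``position_tol_mm``, anchors the clock offset
    (test minus reference); subsequent events of each type are then paired
    greedily by aligned time within ``max_pair_dt_s``.  Unmatched events
    are excluded.
    """
    ref = reference.sorted().events
    tst = test.sorted().events
    if not ref or not tst:
        raise ValueError("cannot sync empty event series")
    anchor = None
    for r in ref:
        for m in tst:
            if m.code == r.code and abs(m.position[1] - r.position[1]) <= position_tol_mm:
                anchor = (r, m)
                break
        if anchor:
            break
    if anchor is None:
        raise ValueError("no common foot event to sync on")
    offset = anchor[1].time - anchor[0].time
    pairs = []
    used = set()
    for r in ref:
        best, best_dt = None, max_pair_dt_s
        for k, m in enumerate(tst):
            if k in used or m.code != r.code:
                continue
            dt = abs((m.time - offset) - r.time)
            if dt <= best_dt:
                best, best_dt = k, dt
        if best is not None:
            used.add(best)
            pairs.append((r, tst[best]))
    return SyncedEventPairs(pairs, offset)


@dataclass
class ErrorStats:
    """Agreement statistics between paired parameter samples.

    Errors are reference minus test; sigma uses the population (N)
    denominator.  ``pearson_r`` is NaN with ``r_defined`` False for a
    zero-variance pair set.
    """

    n_inliers: int
    e_mu: float
    e_sigma: float
    e_mu_abs: float
    e_sigma_abs: float
    e_min: float
    e_max: float
    pearson_r: float
    r_defined: bool
    inlier_pct: float


def compare_systems(reference, test, outlier_sigma: float = 2.0) -> ErrorStats:
    """Error statistics between paired reference/test parameter samples.

    Samples whose error lies ``outlier_sigma`` population standard
    deviations or more from the mean error are removed as event-detection
    failures before the statistics are computed on the inliers.
    """
    v = np.asarray(reference, dtype=float)
    m = np.asarray(test, dtype=float)
    if v.shape != m.shape or v.ndim != 1:
        raise ValueError("reference and test must be equal-length 1-D arrays")
    if len(v) < 3:
        raise ValueError("need at least 3 paired samples")
    e = v - m
    mu, sd = e.mean(), e.std()
    inl = np.abs(e - mu) < outlier_sigma * sd if sd > 0 else np.ones_like(e, dtype=bool)
    vi, mi, ei = v[inl], m[inl], e[inl]
    n = len(ei)
    e_mu = ei.mean()
    e_sigma = np.sqrt(((ei - e_mu) ** 2).mean())
    ab = np.abs(ei)
    e_mu_abs = ab.mean()
    e_sigma_abs = np.sqrt(((ab - e_mu_abs) ** 2).mean())
    r_defined = vi.std() > 0 and mi.std() > 0
    r = float(stats.pearsonr(vi, mi).statistic) if r_defined else float("nan")
    return ErrorStats(
        n_inliers=n,
        e_mu=float(e_mu),
        e_sigma=float(e_sigma),
        e_mu_abs=float(e_mu_abs),
        e_sigma_abs=float(e_sigma_abs),
        e_min=float(ei.min()),
        e_max=float(ei.max()),
        pearson_r=r,
        r_defined=bool(r_defined),
        inlier_pct=100.0 * n / len(e),
    )
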