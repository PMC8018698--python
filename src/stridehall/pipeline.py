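"""End-to-end orchestration: depth frames in, stride parameters out.

``run_trial`` drives the whole chain on a trial bundle (in memory or on
disk): per-sensor background modelling and subtraction, point-cloud fusion
and filtering, leg segmentation with bootstrap leg/foot dimension
estimation, fixed-box foot tracking, left/right assignment, trajectory
post-processing, event detection, sequence validation and stride-parameter
computation.  ``score_trial`` closes the validation loop against simulator
ground truth.

Every tunable constant lives in :class:`PipelineConfig`, which is
serialised into the run report for provenance; defaults are the values the
method was designed with at its native 424x240 processing resolution, and
``scaled_for_resolution`` adjusts the two pixel-count thresholds when
frames arrive at a different resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import foot as ft
from . import segmentation as seg
from .calibration import RigidTransform, SensorIntrinsics
from .depthimage import DepthFrame, build_background, binarize_and_filter, downsample_depth, subtract_background
from .events import EventSeries, Trajectory, detect_events_marker, detect_events_markerless, postprocess_trajectory, validate_sequence
from .parameters import ALL_PARAMS, StrideParameterSet, compare_systems, compute_stride_parameters
from .pointcloud import PointCloud, construct_cloud, filter_chain, merge_clouds
from .simulate import SyntheticTrial

log = logging.getLogger("stridehall")

__all__ = ["PipelineConfig", "TrialResult", "run_trial", "score_trial", "save_trial", "load_trial"]

REFERENCE_RESOLUTION = (240, 424)   # rows, cols the pixel-count defaults refer to


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the pipeline (mm, s, px, counts)."""

    depth_min_mm: float = 200.0
    depth_max_mm: float = 5000.0
    downsample: bool = True            # 2x2 non-zero median before processing
    cc_min_px: int = 1000              # connected-component area cut-off
    outlier_k: int = 100
    outlier_n_sigma: float = 1.0
    mls_radius_mm: float = 30.0
    voxel_mm: float = 5.0
    crop_height_mm: float = 700.0
    cluster_tolerance_mm: float = 50.0
    min_cluster_points: int = 1000
    volume_bands: tuple[float, float, float] = (0.75, 1.25, 2.0)
    match_radius_mm: float = 20.0
    moving_split_min_fraction: float = 0.30
    n_slices: int = 12
    slice_cutoff: float = 0.6
    calibration_frames: int = 40
    trimmed_keep: int = 20
    workspace_shift_mm: float = 5000.0
    markerless_cutoff_hz: float = 12.0
    marker_cutoff_hz: float = 20.0
    resample_hz: float = 60.0
    filter_order: int = 4              # net order of the dual-pass filter
    fs_dip_window_frames: int = 5
    stationary_speed_mm_s: float = 50.0
    stationary_dwell_frames: int = 3
    trajectory_outlier_sigma: float = 2.0
    capture_zone_mm: float = 1000.0    # half-width; events outside are not used
    seed: int = 0

    def scaled_for_resolution(self, rows: int, cols: int) -> "PipelineConfig":
        """Scale pixel-count thresholds to a different processing resolution.

        The connected-component cut-off and the minimum cluster point count
        are proportional to how many pixels an adult leg subtends, i.e. to
        the pixel area of the image, so both scale by
        (rows*cols) / (240*424).
        """
        ratio = (rows * cols) / (REFERENCE_RESOLUTION[0] * REFERENCE_RESOLUTION[1])
        return replace(
            self,
            cc_min_px=max(1, int(round(self.cc_min_px * ratio))),
            min_cluster_points=max(10, int(round(self.min_cluster_points * ratio))),
        )


@dataclass
class TrialResult:
    """Everything one trial run produces."""

    landmarks: pd.DataFrame            # frame, timestamp_s, side, landmark, x/y/z mm
    events: EventSeries
    parameters: StrideParameterSet
    report: dict
    trajectories: dict = field(default_factory=dict)   # (side, landmark) -> post-processed Trajectory
    sides: dict = field(default_factory=dict)          # track index -> side


def _frame_clouds(trial_frames: dict[str, list[DepthFrame]],
                  backgrounds: dict[str, list[DepthFrame]],
                  intrinsics: dict[str, SensorIntrinsics],
                  extrinsics: dict[str, RigidTransform],
                  config: PipelineConfig) -> list[PointCloud]:
    """Background-subtract, mask, deproject and fuse every frame."""
    bg_models = {}
    proc_intr = {}
    for sid, frames in backgrounds.items():
        if config.downsample:
            frames = [downsample_depth(f) for f in frames]
            proc_intr[sid] = intrinsics[sid].halved()
        else:
            proc_intr[sid] = intrinsics[sid]
        bg_models[sid] = build_background(frames)
    sensor_ids = list(trial_frames)
    n = min(len(v) for v in trial_frames.values())
    clouds = []
    for i in range(n):
        per_sensor = []
        for sid in sensor_ids:
            f = trial_frames[sid][i]
            if config.downsample:
                f = downsample_depth(f)
            bs = subtract_background(f, bg_models[sid])
            _, masked = binarize_and_filter(bs, cc_min_px=config.cc_min_px)
            per_sensor.append(construct_cloud(masked, proc_intr[sid], extrinsics[sid]))
        merged = merge_clouds(per_sensor)
        if len(merged):
            merged = filter_chain(merged, k=config.outlier_k, n_sigma=config.outlier_n_sigma,
                                  mls_radius=config.mls_radius_mm, voxel=config.voxel_mm)
            merged = seg.crop_lower(merged, config.crop_height_mm)
            merged = ft.translate_workspace(merged, config.workspace_shift_mm)
        clouds.append(merged)
    return clouds


def _segment_sequence(clouds: list[PointCloud], config: PipelineConfig):
    """Cluster every frame, bootstrap average leg dimensions, classify."""
    cluster_lists = [seg.euclidean_cluster(c, config.cluster_tolerance_mm) if len(c) else []
                     for c in clouds]
    bootstrap = [seg.classify_frame(cl, None, config.min_cluster_points, config.volume_bands)
                 for cl in cluster_lists]
    avg = seg.average_leg_dimensions(bootstrap, config.calibration_frames, config.trimmed_keep)
    segs = [seg.classify_frame(cl, avg, config.min_cluster_points, config.volume_bands)
            for cl in cluster_lists]
    counts = {}
    for s in segs:
        counts[s.category.value] = counts.get(s.category.value, 0) + 1
    log.info("frame categories: %s", counts)
    return segs, avg, counts


def _resolve_legs(segs, config: PipelineConfig):
    """Resolve merged frames via moving-points segmentation.

    Returns a per-frame list of leg clouds (0-2 per frame).
    """
    resolved = []
    history = []
    for s in segs:
        legs = []
        if s.category is seg.FrameCategory.TWO_LEGS:
            legs = list(s.legs)
        elif s.category is seg.FrameCategory.SINGLE_LEG:
            legs = list(s.legs)
        elif s.category is seg.FrameCategory.MERGED_SINGLE_CLUSTER:
            try:
                ref = seg.find_reference_frame(history, now=s.timestamp)
                stat, mov = seg.moving_points_segmentation(
                    s.legs[0], ref, config.match_radius_mm,
                    config.moving_split_min_fraction, config.outlier_k)
                legs = [stat, mov]
            except ValueError as exc:
                log.debug("merged frame skipped: %s", exc)
        resolved.append(legs)
        history.append(s)
        if len(history) > 120:
            history.pop(0)
    return resolved


class _FootTracker:
    """Associate per-frame leg clouds with two temporal tracks by centroid
    continuity and fit the fixed-dimension foot box on each."""

    def __init__(self, fd: ft.FootDimensions, config: PipelineConfig, rng: np.random.Generator):
        self.fd = fd
        self.config = config
        self.rng = rng
        self.last_centroid = [None, None]
        self.samples = [[], []]  # per track: list of (timestamp, FootBox)

    def _assign(self, centroids: list[np.ndarray]) -> list[int]:
        known = [c is not None for c in self.last_centroid]
        if len(centroids) == 2:
            if not any(known):
                order = int(centroids[0][0] > centroids[1][0])
                return [order, 1 - order]
            d = np.zeros((2, 2))
            for i, c in enumerate(centroids):
                for k in range(2):
                    ref = self.last_centroid[k]
                    d[i, k] = np.linalg.norm(c[:2] - ref[:2]) if ref is not None else 1e12
            return [0, 1] if d[0, 0] + d[1, 1] <= d[0, 1] + d[1, 0] else [1, 0]
        if not any(known):
            return [0]
        dists = [np.linalg.norm(centroids[0][:2] - self.last_centroid[k][:2])
                 if self.last_centroid[k] is not None else np.inf for k in range(2)]
        return [int(np.argmin(dists))]

    def update(self, legs: list[PointCloud]) -> None:
        if not legs:
            return
        cents = [leg.points.mean(axis=0) for leg in legs]
        tracks = self._assign(cents)
        for leg, cent, k in zip(legs, cents, tracks):
            self.last_centroid[k] = cent
            try:
                plane = ft.foot_bottom_plane(leg, rng=self.rng)
                box = ft.fit_foot_box(leg, plane, self.fd)
            except ValueError:
                continue
            self.samples[k].append((leg.timestamp, box))


def _collect_valid_leg_clouds(segs, config: PipelineConfig):
    for s in segs:
        if s.category is seg.FrameCategory.TWO_LEGS:
            yield from s.legs


def run_trial(trial: SyntheticTrial | dict, config: PipelineConfig | None = None,
              out_dir=None, trial_id: str = "trial",
              mode: str = "markerless") -> TrialResult:
    """Run the full marker-less pipeline on one trial bundle.

    ``trial`` is a :class:`SyntheticTrial` (or an equivalent mapping with
    ``frames``, ``background``, ``intrinsics``, ``extrinsics`` entries).
    Deterministic given config and seed.  When ``out_dir`` is set, the
    landmark, event and parameter CSVs plus a JSON report are written there.
    """
    config = config or PipelineConfig()
    if isinstance(trial, SyntheticTrial):
        intrinsics = {s.sensor_id: s.intrinsics for s in trial.rig.sensors}
        extrinsics = {s.sensor_id: s.pose for s in trial.rig.sensors}
        frames, background = trial.frames, trial.background
    else:
        intrinsics, extrinsics = trial["intrinsics"], trial["extrinsics"]
        frames, background = trial["frames"], trial["background"]
    if not frames or not min(len(v) for v in frames.values()):
        raise ValueError("no input frames")

    clouds = _frame_clouds(frames, background, intrinsics, extrinsics, config)
    segs, avg, counts = _segment_sequence(clouds, config)
    fd = ft.foot_dimensions(_collect_valid_leg_clouds(segs, config),
                            config.calibration_frames, config.trimmed_keep)
    legs_per_frame = _resolve_legs(segs, config)

    rng = np.random.default_rng(config.seed)
    tracker = _FootTracker(fd, config, rng)
    for legs in legs_per_frame:
        tracker.update(legs)

    # left/right from the two box-centroid trajectories
    tracks = tracker.samples
    if not tracks[0] or not tracks[1]:
        raise ValueError("tracking failed: fewer than two foot tracks")
    cent = [np.array([b.position for _, b in tr]) for tr in tracks]
    shift = np.array([config.workspace_shift_mm, config.workspace_shift_mm, 0.0])
    side0, side1, direction = ft.assign_left_right(cent[0], cent[1])
    sides = {0: side0, 1: side1}

    rows = []
    raw_traj: dict[tuple[str, str], Trajectory] = {}
    for k, track in enumerate(tracks):
        times = np.array([t for t, _ in track])
        heels, toes = [], []
        for _, box in track:
            heel, toe = ft.heel_toe_points(box, direction)
            heels.append(heel - shift)
            toes.append(toe - shift)
        order = np.argsort(times)
        uniq = np.ones(len(order), dtype=bool)
        st = times[order]
        uniq[1:] = np.diff(st) > 0
        sel = order[uniq]
        raw_traj[(sides[k], "heel")] = Trajectory(times[sel], np.array(heels)[sel],
                                                  f"{sides[k]}_heel", config.resample_hz)
        raw_traj[(sides[k], "toe")] = Trajectory(times[sel], np.array(toes)[sel],
                                                 f"{sides[k]}_toe", config.resample_hz)
        for i in sel:
            for name, p in (("heel", heels[i]), ("toe", toes[i])):
                rows.append({"trial_id": trial_id, "frame": i, "timestamp_s": times[i],
                             "side": sides[k], "landmark": name,
                             "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    landmarks = pd.DataFrame(rows).sort_values(["timestamp_s", "side", "landmark"]).reset_index(drop=True)

    proc: dict[tuple[str, str], Trajectory] = {}
    for key, tr in raw_traj.items():
        proc[key] = postprocess_trajectory(
            tr, mode=mode, resample_hz=config.resample_hz,
            markerless_cutoff_hz=config.markerless_cutoff_hz,
            marker_cutoff_hz=config.marker_cutoff_hz,
            outlier_sigma=config.trajectory_outlier_sigma)

    per_side = {}
    for side in ("left", "right"):
        heel, toe = proc[(side, "heel")], proc[(side, "toe")]
        if mode == "markerless":
            per_side[side] = detect_events_markerless(
                heel, toe, side, config.stationary_speed_mm_s,
                config.stationary_dwell_frames, config.fs_dip_window_frames)
        else:
            per_side[side] = detect_events_marker(heel, toe, side)
        # only events inside the capture zone are used, mirroring the
        # protocol of restricting analysis to the instrumented zone
        per_side[side] = EventSeries(
            [e for e in per_side[side] if abs(e.position[1]) <= config.capture_zone_mm])
    validated = validate_sequence(per_side["left"], per_side["right"])
    params = compute_stride_parameters(validated, proc, direction)

    report = {
        "trial_id": trial_id,
        "mode": mode,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "frame_categories": counts,
        "n_frames": len(clouds),
        "n_events_detected": sum(len(s) for s in per_side.values()),
        "n_events_validated": len(validated),
        "n_cycles": len(params),
        "avg_leg_dims_mm": [avg.length, avg.width, avg.height],
        "foot_dims_mm": [fd.length, fd.width, fd.height],
        "walking_direction": direction,
    }
    result = TrialResult(landmarks, validated, params, report, proc, sides)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), trial_id)
    return result


def _write_outputs(result: TrialResult, out_dir: Path, trial_id: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.landmarks.to_csv(out_dir / "landmarks.csv", index=False)
    ev_rows = [{"trial_id": trial_id, "event_type": e.code, "frame": e.index,
                "time_s": e.time, "x_mm": e.position[0], "y_mm": e.position[1],
                "z_mm": e.position[2], "detector": result.report.get("mode", "markerless")}
               for e in result.events]
    pd.DataFrame(ev_rows).to_csv(out_dir / "events.csv", index=False)
    result.parameters.table.to_csv(out_dir / "parameters.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=2))


# ---------------------------------------------------------------------------
# scoring against ground truth


def score_trial(result: TrialResult, gt, max_cycle_dt: float | None = None) -> pd.DataFrame:
    """Per-parameter errors of a run against simulator ground truth.

    Measured cycles are paired with ground-truth cycles of the same side by
    nearest cycle-start time; one row per paired cycle and parameter with
    the signed error (measured - truth) in the parameter's units.
    """
    meas = result.parameters.table
    truth = gt.parameters.table
    if max_cycle_dt is None:
        max_cycle_dt = 0.6 * float(truth["stride_time"].iloc[0])
    rows = []
    for _, m in meas.iterrows():
        cand = truth[truth["side"] == m["side"]]
        if not len(cand):
            continue
        dt = np.abs(cand["cycle_start_s"].to_numpy() - m["cycle_start_s"])
        j = int(np.argmin(dt))
        if dt[j] > max_cycle_dt:
            continue
        t = cand.iloc[j]
        for p in ALL_PARAMS:
            if pd.isna(m[p]):
                continue
            rows.append({"side": m["side"], "cycle_start_s": m["cycle_start_s"],
                         "parameter": p, "measured": m[p], "truth": t[p],
                         "error": m[p] - t[p]})
    return pd.DataFrame(rows)


def side_labels_correct(result: TrialResult, gt) -> bool:
    """True when each assigned side's median ML position matches the
    ground-truth heel line of that side more closely than the other's."""
    ok = True
    gt_x = {s: float(np.median(gt.trajectories[(s, "heel")].positions[:, 0]))
            for s in ("left", "right")}
    for side in ("left", "right"):
        tr = result.trajectories.get((side, "heel"))
        if tr is None:
            return False
        mx = float(np.median(tr.positions[:, 0]))
        other = "right" if side == "left" else "left"
        ok &= abs(mx - gt_x[side]) < abs(mx - gt_x[other])
    return bool(ok)


def error_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean / absolute-mean error per parameter over paired cycles."""
    if not len(scores):
        return pd.DataFrame(columns=["parameter", "n", "mean_error", "mean_abs_error"])
    g = scores.groupby("parameter")["error"]
    out = pd.DataFrame({"n": g.size(), "mean_error": g.mean(),
                        "mean_abs_error": g.apply(lambda e: e.abs().mean())})
    return out.reset_index()


# ---------------------------------------------------------------------------
# trial bundle I/O (for the CLI)


def save_trial(trial: SyntheticTrial, out_dir) -> None:
    """Write a trial bundle: 16-bit PNG depth frames with JSON sidecars,
    calibration, and the ground truth as CSV + JSON."""
    from .depthimage import write_depth_png

    out = Path(out_dir)
    for sid, frames in trial.frames.items():
        d = out / "frames" / sid
        d.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(frames):
            write_depth_png(d / f"{i:05d}.png", f)
    for sid, frames in trial.background.items():
        d = out / "background" / sid
        d.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(frames):
            write_depth_png(d / f"{i:05d}.png", f)
    from .calibration import save_calibration

    save_calibration(out / "calibration.json",
                     {s.sensor_id: s.intrinsics for s in trial.rig.sensors},
                     {s.sensor_id: s.pose for s in trial.rig.sensors})
    gt = trial.ground_truth
    rows = []
    for (side, lm), tr in gt.trajectories.items():
        for t, p in zip(tr.times, tr.positions):
            rows.append({"time_s": t, "side": side, "landmark": lm,
                         "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    pd.DataFrame(rows).to_csv(out / "ground_truth_trajectories.csv", index=False)
    gt.parameters.table.to_csv(out / "ground_truth_parameters.csv", index=False)
    (out / "ground_truth_events.json").write_text(json.dumps(
        [{"event": e.code, "time_s": e.time, "position_mm": list(map(float, e.position))}
         for e in gt.events], indent=2))
    meta = {"fps": trial.rig.fps, "depth_noise_sigma": trial.rig.depth_noise_sigma,
            "duration": gt.duration,
            "profile": asdict(gt.profile)}
    (out / "trial.json").write_text(json.dumps(meta, indent=2))


def load_trial(in_dir) -> dict:
    """Load a bundle written by :func:`save_trial` into run_trial's input form."""
    from .calibration import load_calibration
    from .depthimage import read_depth_png

    root = Path(in_dir)
    if not (root / "calibration.json").exists():
        raise ValueError(f"not a trial bundle: missing calibration.json in {root}")
    intrinsics, extrinsics, _ = load_calibration(root / "calibration.json")

    def read_all(sub):
        out = {}
        base = root / sub
        if not base.exists():
            raise ValueError(f"missing {sub}/ in trial bundle")
        for d in sorted(base.iterdir()):
            out[d.name] = [read_depth_png(p) for p in sorted(d.glob("*.png"))]
        return out

    return {"frames": read_all("frames"), "background": read_all("background"),
            "intrinsics": intrinsics, "extrinsics": extrinsics}
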