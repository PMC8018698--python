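"""Synthetic walking scenes with known ground truth.

The generator emulates an instrumented hallway: a floor plane and one
walking person's lower legs — each leg a vertical shank cylinder joined to a
rectangular foot box — observed by six virtual pinhole depth sensors at the
standard rig geometry (0.8 m height, 1.4 m spacing along the walkway,
1.8 m across it) at ~60 fps with Gaussian depth noise.

Gait kinematics are analytic and piecewise smooth.  During stance the foot
is flat on the floor and perfectly stationary; during swing the heel
advances one stride length along a quintic profile while heel and toe
heights follow monotone-cubic bump profiles (heel rise early in swing,
toe clearance minimum at mid-swing, soft touchdown), and the rigid foot's
pitch follows from the heel/toe heights.  Foot strike and foot off are exactly
the stance/swing transitions, so every downstream detector can be scored
against exact event times.

Rendering is exact ray casting (floor plane, capped cylinders, oriented
boxes) through each sensor's pinhole model, so a rendered depth image
back-projects onto the analytic surfaces to within the 1 mm integer-depth
quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .calibration import RigidTransform, SensorIntrinsics
from .depthimage import DEPTH_MAX_MM, DEPTH_MIN_MM, DepthFrame
from .events import Event, EventSeries, Trajectory
from .parameters import StrideParameterSet

import pandas as pd

__all__ = [
    "GaitProfile",
    "VirtualSensor",
    "VirtualRig",
    "GroundTruth",
    "SyntheticTrial",
    "default_rig",
    "generate_gait_trajectory",
    "render_depth_sequence",
    "render_background_frames",
    "simulate_trial",
]


# ---------------------------------------------------------------------------
# profile and rig


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of the simulated gait and leg geometry (mm, s).

    Defaults describe a comfortable able-bodied walk: 1.3 m stride at a
    0.55 s step (~1.18 m/s), 100 mm step width, 62% stance fraction,
    250x90x80 mm feet on 40 mm-radius shanks, 180 mm peak heel rise and a
    25 mm minimum toe clearance at mid-swing.
    """

    stride_length: float = 1300.0
    step_width: float = 100.0
    step_time: float = 0.55
    stance_fraction: float = 0.62
    foot_length: float = 250.0
    foot_width: float = 90.0
    foot_height: float = 80.0
    shank_radius: float = 40.0
    shank_length: float = 700.0
    swing_peak_heel_rise: float = 180.0
    toe_clearance_min: float = 25.0
    toe_spring: float = 12.0         # resting toe-bottom height of the shoe
    walking_direction: int = -1      # +1 towards +y, -1 towards the origin
    # initial left-heel AP position: all five events of one left gait
    # cycle (stances at +450 / -850 mm plus the contralateral foot-off at
    # +850 mm) fall symmetrically inside the rig's central capture zone
    start_offset: float = 1750.0

    def __post_init__(self) -> None:
        vals = [self.stride_length, self.step_width, self.step_time,
                self.stance_fraction, self.foot_length, self.foot_width,
                self.foot_height, self.shank_radius, self.shank_length,
                self.swing_peak_heel_rise, self.toe_clearance_min,
                self.start_offset]
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile fields must be finite")
        if self.stride_length <= 0:
            raise ValueError("stride_length must be positive")
        if not 0.5 < self.stance_fraction < 0.8:
            raise ValueError("stance_fraction must be in (0.5, 0.8)")
        if not self.foot_length > self.foot_width > 0:
            raise ValueError("need foot_length > foot_width > 0")
        if self.walking_direction not in (-1, 1):
            raise ValueError("walking_direction must be +1 or -1")

    @property
    def stride_time(self) -> float:
        return 2.0 * self.step_time


@dataclass(frozen=True)
class VirtualSensor:
    sensor_id: str
    intrinsics: SensorIntrinsics
    pose: RigidTransform        # sensor -> room


@dataclass(frozen=True)
class VirtualRig:
    sensors: tuple[VirtualSensor, ...]
    fps: float = 60.0
    depth_noise_sigma: float = 5.0
    timestamp_jitter_sigma: float = 0.001
    rng_seed: int = 0


def _look_at_pose(position, target) -> RigidTransform:
    """Camera pose with +z towards ``target`` and image rows pointing down."""
    position = np.asarray(position, dtype=float)
    f = np.asarray(target, dtype=float) - position
    f = f / np.linalg.norm(f)
    r = np.cross(f, [0.0, 0.0, 1.0])
    r = r / np.linalg.norm(r)
    d = np.cross(f, r)  # image "down"
    rot = np.stack([r, d, f], axis=1)
    return RigidTransform.from_rotation_translation(rot, position)


def default_rig(rows: int = 120, cols: int = 212, fps: float = 60.0,
                depth_noise_sigma: float = 5.0,
                timestamp_jitter_sigma: float = 0.001,
                rng_seed: int = 0) -> VirtualRig:
    """Six sensors at 0.8 m height, 1.4 m apart along the walkway and 1.8 m
    across it, each aimed at the shank height of the walkway centre line.

    The focal length follows a 65-degree horizontal field of view, so
    halving the resolution halves fx/fy exactly as a real sensor's
    intrinsics would.
    """
    f = (cols / 2.0) / np.tan(np.deg2rad(65.0 / 2.0))
    intr = SensorIntrinsics(f, f, cols / 2.0, rows / 2.0, rows, cols)
    sensors = []
    # (id, x, y, aim y): the four corner sensors aim into the central
    # capture zone so it is seen from ahead and behind at once; the two
    # mid-walkway sensors stagger their aims so each end of the zone also
    # gets a cross view of the heel side of the landing foot
    layout = [("s1", -900, 1400, 448.0), ("s2", 900, 1400, 448.0),
              ("s3", 900, 0, -250.0), ("s4", 900, -1400, -448.0),
              ("s5", -900, -1400, -448.0), ("s6", -900, 0, 250.0)]
    for sid, x, y, aim_y in layout:
        pose = _look_at_pose([x, y, 800.0], [0.0, aim_y, 150.0])
        sensors.append(VirtualSensor(sid, intr, pose))
    return VirtualRig(tuple(sensors), fps, depth_noise_sigma,
                      timestamp_jitter_sigma, rng_seed)


# ---------------------------------------------------------------------------
# analytic kinematics


def _quintic_step(w: np.ndarray) -> np.ndarray:
    """Smoothstep with zero velocity and acceleration at both ends."""
    w = np.clip(w, 0.0, 1.0)
    return w ** 3 * (10.0 - 15.0 * w + 6.0 * w * w)


class _GaitKinematics:
    """Continuous-time heel/toe positions for both feet.

    Swing height profiles are monotone cubics (PCHIP) through fixed knots:
    the heel rises to its peak just after foot off and is nearly flat again
    by mid-swing; the toe clears early, dips to the minimum clearance at
    mid-swing and rises at the next foot off.  The toe's AP position
    follows rigidly from the heel and the foot pitch implied by the two
    heights, so |toe - heel| always equals the foot length.
    """

    def __init__(self, profile: GaitProfile):
        self.p = profile
        h = profile.swing_peak_heel_rise
        c = profile.toe_clearance_min
        s = profile.toe_spring
        # heel rise peaks early in swing (just after toe-off) and the foot
        # is close to flat again by mid-swing, as in physiological gait;
        # liftoff and touchdown are soft — vertical velocity tapers to ~0
        # at the stance transitions, so the landmark heights join the flat
        # stance smoothly (no impact transient in the analytic model)
        self._heel_z = PchipInterpolator(
            [0.0, 0.2, 0.35, 0.6, 0.85, 0.92, 1.0],
            [0.0, 0.9 * h, h, 0.35 * h, 0.07 * h, 0.02 * h, 0.0])
        # the toe bottom rests at the shoe's toe-spring height and presses
        # down during push-off, reaching its minimum exactly at foot off —
        # the concave dip marker-style foot-off detection relies on
        self._toe_z_stance = PchipInterpolator(
            [0.0, 0.8, 1.0], [s, s, 0.5 * s])
        self._toe_z_swing = PchipInterpolator(
            [0.0, 0.15, 0.5, 0.85, 1.0],
            [0.5 * s, 1.8 * c, c, 1.4 * c, s])

    def phase(self, t, side: str):
        """(cycle index, cycle fraction) for one foot."""
        offset = 0.0 if side == "left" else 0.5
        phi = np.asarray(t, dtype=float) / self.p.stride_time + offset
        k = np.floor(phi)
        return k, phi - k

    def _stance_y(self, k, side: str):
        p = self.p
        lag = 0.0 if side == "left" else -0.5 * p.stride_length
        return p.start_offset + p.walking_direction * (k * p.stride_length + lag)

    def heel(self, t, side: str) -> np.ndarray:
        """Heel landmark position(s) at time(s) t; (N, 3) or (3,)."""
        p = self.p
        t = np.asarray(t, dtype=float)
        k, u = self.phase(t, side)
        sf = p.stance_fraction
        w = np.clip((u - sf) / (1.0 - sf), 0.0, None)
        in_swing = u >= sf
        y = self._stance_y(k, side) + np.where(
            in_swing, p.walking_direction * p.stride_length * _quintic_step(w), 0.0)
        z = np.where(in_swing, self._heel_z(np.clip(w, 0, 1)), 0.0)
        sign = -p.walking_direction if side == "left" else p.walking_direction
        x = np.full_like(y, sign * p.step_width / 2.0)
        out = np.stack([x, y, z], axis=-1)
        return out

    def toe(self, t, side: str) -> np.ndarray:
        p = self.p
        t = np.asarray(t, dtype=float)
        heel = self.heel(t, side)
        k, u = self.phase(t, side)
        sf = p.stance_fraction
        w = np.clip((u - sf) / (1.0 - sf), 0.0, 1.0)
        in_swing = u >= sf
        toe_z = np.where(in_swing, self._toe_z_swing(w),
                         self._toe_z_stance(np.clip(u / sf, 0.0, 1.0)))
        dz = heel[..., 2] - toe_z
        reach = np.sqrt(np.maximum(p.foot_length ** 2 - dz ** 2, 0.0))
        toe = heel.copy()
        toe[..., 1] = heel[..., 1] + p.walking_direction * reach
        toe[..., 2] = toe_z
        return toe

    def events(self, duration: float) -> EventSeries:
        """Exact stance/swing transition events inside [0, duration]."""
        p = self.p
        T = p.stride_time
        sf = p.stance_fraction
        evs = []
        for side, code_s, off in (("left", "L", 0.0), ("right", "R", 0.5)):
            k = -2
            while True:
                t_fs = (k - off) * T
                t_fo = (k - off + sf) * T
                if t_fs > duration and t_fo > duration:
                    break
                if 0.0 <= t_fs <= duration:
                    pos = self.heel(t_fs, side)
                    evs.append(Event(f"{code_s}FS", int(round(t_fs * 1e6)), t_fs, pos))
                if 0.0 <= t_fo <= duration:
                    pos = self.toe(t_fo, side)
                    evs.append(Event(f"{code_s}FO", int(round(t_fo * 1e6)), t_fo, pos))
                k += 1
        return EventSeries(sorted(evs, key=lambda e: e.time))


@dataclass
class GroundTruth:
    """Exact landmark trajectories, event times and stride parameters."""

    trajectories: dict          # (side, "heel"/"toe") -> Trajectory
    events: EventSeries
    parameters: StrideParameterSet
    profile: GaitProfile
    duration: float
    fps: float
    kinematics: _GaitKinematics = field(repr=False, default=None)  # type: ignore[assignment]


def _analytic_parameters(profile: GaitProfile, duration: float) -> StrideParameterSet:
    p = profile
    T = p.stride_time
    rows = []
    for side, off in (("left", 0.0), ("right", 0.5)):
        k = 0
        while True:
            t0 = (k - off) * T
            k += 1
            if t0 < 0:
                continue
            if t0 + T > duration:
                break
            rows.append({
                "side": side,
                "cycle_start_s": t0,
                "stride_length": p.stride_length,
                "step_length": p.stride_length / 2.0,
                "step_width": p.step_width,
                "foot_angle": 0.0,
                "foot_clearance": p.toe_clearance_min,
                "stride_time": T,
                "step_time": p.step_time,
                "stance_time": p.stance_fraction * T,
                "swing_time": (1.0 - p.stance_fraction) * T,
                "double_support_time": 2.0 * (p.stance_fraction - 0.5) * T,
                "stride_speed": p.stride_length / T,
                "cadence": 120.0 / T,
            })
    return StrideParameterSet(pd.DataFrame(rows))


def generate_gait_trajectory(profile: GaitProfile, duration: float,
                             fps: float = 60.0, seed: int = 0) -> GroundTruth:
    """Sample the analytic gait model on a regular fps grid.

    Raises when ``duration`` covers fewer than two full gait cycles.  The
    returned parameters are computed analytically from the profile, not from
    the sampled trajectories.
    """
    if duration < 2.0 * profile.stride_time:
        raise ValueError("duration must cover at least two full gait cycles")
    kin = _GaitKinematics(profile)
    t = np.arange(0.0, duration, 1.0 / fps)
    traj = {}
    for side in ("left", "right"):
        traj[(side, "heel")] = Trajectory(t, kin.heel(t, side), f"{side}_heel", fps)
        traj[(side, "toe")] = Trajectory(t, kin.toe(t, side), f"{side}_toe", fps)
    return GroundTruth(traj, kin.events(duration), _analytic_parameters(profile, duration),
                       profile, duration, fps, kin)


# ---------------------------------------------------------------------------
# ray-cast depth rendering


def _ray_grid(intr: SensorIntrinsics) -> np.ndarray:
    """Camera-frame ray directions through integer pixel coordinates, with
    unit z so the ray parameter equals the stored depth."""
    rr, cc = np.meshgrid(np.arange(intr.rows), np.arange(intr.cols), indexing="ij")
    x = (cc - intr.cx) / intr.fx
    y = (rr - intr.cy) / intr.fy
    return np.stack([x, y, np.ones_like(x)], axis=-1).reshape(-1, 3)


def _intersect_floor(o: np.ndarray, d: np.ndarray) -> np.ndarray:
    t = np.full(d.shape[0], np.inf)
    dz = d[:, 2]
    m = dz < -1e-12
    t[m] = -o[2] / dz[m]
    return t


def _intersect_cylinder(o, d, center_xy, radius, z0, z1) -> np.ndarray:
    """Smallest positive hit with a finite vertical cylinder (plus top cap)."""
    ox, oy = o[0] - center_xy[0], o[1] - center_xy[1]
    dx, dy = d[:, 0], d[:, 1]
    a = dx * dx + dy * dy
    b = 2.0 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - radius * radius
    disc = b * b - 4.0 * a * c
    t = np.full(d.shape[0], np.inf)
    m = (disc > 0) & (a > 1e-15)
    sq = np.sqrt(disc[m])
    for sgn in (-1.0, 1.0):
        tc = (-b[m] + sgn * sq) / (2.0 * a[m])
        z = o[2] + tc * d[m, 2]
        ok = (tc > 0) & (z >= z0) & (z <= z1)
        tm = t[m]
        tm[ok] = np.minimum(tm[ok], tc[ok])
        t[m] = tm
    # top cap
    dz = d[:, 2]
    mcap = np.abs(dz) > 1e-12
    tcap = np.where(mcap, (z1 - o[2]) / np.where(mcap, dz, 1.0), np.inf)
    px = o[0] + tcap * d[:, 0] - center_xy[0]
    py = o[1] + tcap * d[:, 1] - center_xy[1]
    ok = (tcap > 0) & (px * px + py * py <= radius * radius)
    t[ok] = np.minimum(t[ok], tcap[ok])
    return t


def _intersect_box(o, d, center, rot, half) -> np.ndarray:
    """Slab-method entry distance for an oriented box (inf when missed)."""
    ol = (o - center) @ rot
    dl = d @ rot
    # parallel rays outside a slab never hit; nudge exact zeros so the slab
    # arithmetic stays finite
    par_miss = ((np.abs(dl) < 1e-15) & (np.abs(ol) > half)).any(axis=1)
    dl = np.where(np.abs(dl) < 1e-15, 1e-15, dl)
    inv = 1.0 / dl
    t1 = (-half - ol) * inv
    t2 = (half - ol) * inv
    tnear = np.maximum.reduce(np.minimum(t1, t2), axis=1)
    tfar = np.minimum.reduce(np.maximum(t1, t2), axis=1)
    hit = (tfar >= tnear) & (tfar > 0) & ~par_miss
    t = np.where(hit, np.where(tnear > 0, tnear, np.inf), np.inf)
    return t


def _foot_box_geometry(heel: np.ndarray, toe: np.ndarray, profile: GaitProfile):
    """Oriented-box (center, rotation, half-dims) for a foot given its
    heel and toe landmarks (which lie on the box's bottom edge midpoints)."""
    e1 = (toe - heel) / np.linalg.norm(toe - heel)
    ml = np.array([1.0, 0.0, 0.0])
    n = np.cross(e1, ml)
    n = n / np.linalg.norm(n)
    if n[2] < 0:
        n = -n
    e2 = np.cross(n, e1)
    center = (heel + toe) / 2.0 + n * profile.foot_height / 2.0
    rot = np.stack([e1, e2, n], axis=1)
    half = np.array([profile.foot_length, profile.foot_width, profile.foot_height]) / 2.0
    return center, rot, half


def _leg_primitives(kin: _GaitKinematics, t: float):
    """Foot boxes and shank cylinders of both legs at time t."""
    p = kin.p
    boxes, cyls = [], []
    for side in ("left", "right"):
        heel = kin.heel(t, side)
        toe = kin.toe(t, side)
        boxes.append(_foot_box_geometry(heel, toe, p))
        ankle = heel + 0.3 * (toe - heel)
        z0 = heel[2] + 0.7 * p.foot_height
        cyls.append(((heel[0], ankle[1]), p.shank_radius, z0, z0 + p.shank_length))
    return boxes, cyls


def _legs_depth(o: np.ndarray, d: np.ndarray, boxes, cyls) -> np.ndarray:
    depth = np.full(d.shape[0], np.inf)
    for center, rot, half in boxes:
        depth = np.minimum(depth, _intersect_box(o, d, center, rot, half))
    for center_xy, radius, z0, z1 in cyls:
        depth = np.minimum(depth, _intersect_cylinder(o, d, center_xy, radius, z0, z1))
    return depth


def _leg_pixel_window(sensor: VirtualSensor, boxes, cyls, margin: int = 3):
    """Image-row/col bounds covering the projected leg geometry (or None)."""
    pts = []
    for center, rot, half in boxes:
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float)
        pts.append(center + (signs * half) @ rot.T)
    for (cx_, cy_), radius, z0, z1 in cyls:
        for z in (z0, z1):
            for dx, dy in ((radius, 0), (-radius, 0), (0, radius), (0, -radius)):
                pts.append(np.array([[cx_ + dx, cy_ + dy, z]]))
    pts = np.vstack(pts)
    inv = sensor.pose.inverse()
    cam = inv.apply(pts)
    z = cam[:, 2]
    if np.all(z <= 1.0):
        return None
    z = np.maximum(z, 1.0)  # clamp points behind the camera to the view plane
    intr = sensor.intrinsics
    rows = cam[:, 1] * intr.fy / z + intr.cy
    cols = cam[:, 0] * intr.fx / z + intr.cx
    r0 = max(0, int(np.floor(rows.min())) - margin)
    r1 = min(intr.rows, int(np.ceil(rows.max())) + margin + 1)
    c0 = max(0, int(np.floor(cols.min())) - margin)
    c1 = min(intr.cols, int(np.ceil(cols.max())) + margin + 1)
    if r0 >= r1 or c0 >= c1:
        return None
    return r0, r1, c0, c1


def _render_scene(sensor: VirtualSensor, rays: np.ndarray, kin: _GaitKinematics | None,
                  t: float, static_depth: np.ndarray | None = None) -> np.ndarray:
    """Noiseless depth image (float mm) of floor plus (optionally) both legs.

    ``static_depth`` is the cached floor-only ray-cast; when given, legs are
    cast only inside their projected pixel window.
    """
    intr = sensor.intrinsics
    o = sensor.pose.translation
    if static_depth is None:
        d = rays @ sensor.pose.rotation.T
        depth = _intersect_floor(o, d)
    else:
        depth = static_depth.copy()
    if kin is not None:
        boxes, cyls = _leg_primitives(kin, t)
        if static_depth is None:
            d = rays @ sensor.pose.rotation.T
            depth = np.minimum(depth, _legs_depth(o, d, boxes, cyls))
        else:
            win = _leg_pixel_window(sensor, boxes, cyls)
            if win is not None:
                r0, r1, c0, c1 = win
                sel = (slice(r0, r1), slice(c0, c1))
                idx = (np.arange(r0, r1)[:, None] * intr.cols + np.arange(c0, c1)[None, :]).ravel()
                d = rays[idx] @ sensor.pose.rotation.T
                legs = _legs_depth(o, d, boxes, cyls).reshape(r1 - r0, c1 - c0)
                depth = depth.reshape(intr.rows, intr.cols)
                depth[sel] = np.minimum(depth[sel], legs)
                depth = depth.reshape(-1)
    img = depth.reshape(intr.rows, intr.cols)
    img = np.where(np.isfinite(img) & (img >= DEPTH_MIN_MM) & (img <= DEPTH_MAX_MM), img, 0.0)
    return img


def _quantize(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma > 0:
        noisy = np.where(img > 0, img + rng.normal(0.0, sigma, img.shape), 0.0)
    else:
        noisy = img
    return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)


def render_background_frames(rig: VirtualRig, n_frames: int = 1000,
                             seed: int | None = None) -> dict[str, list[DepthFrame]]:
    """Empty-scene (floor only) depth sequences, one per sensor.

    The static scene is ray cast once per sensor; each frame adds fresh
    depth noise, which is what the per-pixel minimum background model sees
    in practice.
    """
    rng = np.random.default_rng(rig.rng_seed if seed is None else seed)
    out: dict[str, list[DepthFrame]] = {}
    for sensor in rig.sensors:
        rays = _ray_grid(sensor.intrinsics)
        static = _render_scene(sensor, rays, None, 0.0)
        frames = []
        for i in range(n_frames):
            img = _quantize(static, rig.depth_noise_sigma, rng)
            frames.append(DepthFrame(img, i / rig.fps, sensor.sensor_id))
        out[sensor.sensor_id] = frames
    return out


def render_depth_sequence(gt: GroundTruth, rig: VirtualRig,
                          seed: int | None = None) -> tuple[dict[str, list[DepthFrame]], np.ndarray]:
    """Render per-sensor depth sequences of a walking trial.

    Frame timestamps follow the nominal 1/fps spacing plus zero-mean jitter
    (shared across sensors, emulating a synchronised rig whose frame rate
    varies slightly).  Returns (frames by sensor, timestamps).  With zero
    noise and zero jitter, rendering is deterministic.
    """
    for s in rig.sensors:
        if s.intrinsics.fx <= 0 or s.intrinsics.fy <= 0:
            raise ValueError("degenerate intrinsics")
    rng = np.random.default_rng(rig.rng_seed if seed is None else seed)
    n = int(np.floor(gt.duration * rig.fps))
    times = np.arange(n) / rig.fps
    if rig.timestamp_jitter_sigma > 0:
        jitter = rng.normal(0.0, rig.timestamp_jitter_sigma, n)
        times = np.sort(times + jitter)
        times[0] = max(times[0], 0.0)
    out: dict[str, list[DepthFrame]] = {s.sensor_id: [] for s in rig.sensors}
    kin = gt.kinematics or _GaitKinematics(gt.profile)
    ray_cache = {s.sensor_id: _ray_grid(s.intrinsics) for s in rig.sensors}
    static_cache = {
        s.sensor_id: _intersect_floor(s.pose.translation,
                                      ray_cache[s.sensor_id] @ s.pose.rotation.T)
        for s in rig.sensors
    }
    for i, t in enumerate(times):
        for sensor in rig.sensors:
            img = _render_scene(sensor, ray_cache[sensor.sensor_id], kin, float(t),
                                static_cache[sensor.sensor_id])
            out[sensor.sensor_id].append(
                DepthFrame(_quantize(img, rig.depth_noise_sigma, rng), float(t), sensor.sensor_id))
    return out, times


@dataclass
class SyntheticTrial:
    """A rendered trial bundle: frames, empty-scene backgrounds, truth."""

    frames: dict[str, list[DepthFrame]]
    background: dict[str, list[DepthFrame]]
    ground_truth: GroundTruth
    rig: VirtualRig
    timestamps: np.ndarray


def simulate_trial(profile: GaitProfile | None = None, rig: VirtualRig | None = None,
                   duration: float = 4.5, seed: int = 0,
                   n_background: int = 1000, render: bool = True) -> SyntheticTrial:
    """Generate ground truth and (optionally) render the full trial.

    ``render=False`` returns trajectories and events only — the fast path
    for exercising event detection and parameter code without ray casting.
    """
    profile = profile or GaitProfile()
    rig = rig or default_rig()
    rig = replace(rig, rng_seed=seed)
    gt = generate_gait_trajectory(profile, duration, rig.fps, seed)
    if not render:
        return SyntheticTrial({}, {}, gt, rig, gt.trajectories[("left", "heel")].times)
    frames, times = render_depth_sequence(gt, rig, seed=seed)
    background = render_background_frames(rig, n_background, seed=seed + 1)
    return SyntheticTrial(frames, background, gt, rig, times)
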