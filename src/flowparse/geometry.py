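"""Stimulus geometry: 3-D scenes, pinhole projection, and optic-flow kinematics.

Both experiments simulate forward self-movement through a static scene and
need the instantaneous on-screen (retinal) velocity of scene points under
observer translation.  Everything is computed in eye-centered coordinates
(X right, Y up, Z away from the eye along gaze, all in cm) and projected
onto a screen plane at the viewing distance.  Degrees are obtained from
screen cm by an exact ``atan`` conversion.

Experiment 1: a sparse volume of wireframe objects around 82 cm with a probe
at ±2.4° eccentricity; simulated self-movement (12.5 cm/s) is directed at the
probe's initial position, so the focus of expansion coincides with the probe
at trial onset.

Experiment 2: a limited-lifetime cloud of 300 dots between 107 and 207 cm
with translation along gaze (120 cm/s), optionally restricted to one
hemifield; the probe sits at ±4° on the horizontal meridian.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SceneConfig",
    "FlowConfig",
    "ScreenKinematics",
    "project",
    "flow_velocity",
    "deg_to_screen_cm",
    "screen_cm_to_deg",
    "generate_scene_exp1",
    "generate_flow_trial_exp2",
    "exp1_translation",
    "probe_kinematics_exp1",
    "flow_at_probe_exp1",
    "flow_speed_at_probe_exp2",
]


@dataclass(frozen=True)
class SceneConfig:
    """Experiment 1 scene geometry (lengths cm, angles deg, speeds cm/s)."""

    grid_cols: int = 11
    grid_rows: int = 5
    grid_spacing: float = 3.5
    jitter_halfwidth: float = 1.2
    depth_halfrange: float = 25.0
    array_distance: float = 82.0
    exclusion_width: float = 10.0
    exclusion_height: float = 2.0
    probe_eccentricity: float = 2.4
    self_speed: float = 12.5
    motion_duration: float = 1.0
    viewing_distance: float = 57.0

    def __post_init__(self) -> None:
        for name in ("grid_spacing", "array_distance", "viewing_distance",
                     "motion_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter_halfwidth < 0 or self.depth_halfrange < 0:
            raise ValueError("jitter_halfwidth and depth_halfrange must be >= 0")
        if self.depth_halfrange >= self.array_distance:
            raise ValueError("depth range would place objects behind the eye")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FlowConfig:
    """Experiment 2 flow-field geometry.

    ``field_mask`` selects where dots may live: ``"Full"`` (whole screen),
    ``"HemiL"`` (screen x < 0) or ``"HemiR"`` (screen x > 0).
    """

    n_dots: int = 300
    screen_width: float = 47.3
    screen_height: float = 29.6
    depth_min: float = 107.0
    depth_max: float = 207.0
    self_speed: float = 120.0
    dot_lifetime: float = 20.0
    frame_rate: float = 120.0
    probe_eccentricity: float = 4.0
    probe_speed: float = 0.8
    probe_angles: tuple = (75.0, 90.0, 105.0)
    stimulus_duration: float = 2.0
    field_mask: str = "Full"
    viewing_distance: float = 57.0

    def __post_init__(self) -> None:
        if not self.depth_min < self.depth_max:
            raise ValueError("depth_min must be < depth_max")
        if self.depth_min <= 0:
            raise ValueError("depths must be positive")
        if self.field_mask not in ("Full", "HemiL", "HemiR"):
            raise ValueError(f"unknown field_mask {self.field_mask!r}")
        if not all(0.0 < a < 180.0 for a in self.probe_angles):
            raise ValueError("probe angles must lie strictly inside (0, 180)")
        if np.isfinite(self.dot_lifetime):
            if self.dot_lifetime / self.frame_rate >= self.stimulus_duration:
                raise ValueError("dot lifetime must be shorter than the trial")

    @property
    def n_frames(self) -> int:
        return int(round(self.stimulus_duration * self.frame_rate))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["probe_angles"] = list(self.probe_angles)
        return d


class ScreenKinematics(NamedTuple):
    """On-screen position (cm) and velocity (cm/s) of a point stimulus."""

    position: np.ndarray
    velocity: np.ndarray


def deg_to_screen_cm(deg, viewing_distance: float = 57.0):
    """Eccentricity in degrees -> cm on the screen plane (exact tangent)."""
    return viewing_distance * np.tan(np.radians(deg))


def screen_cm_to_deg(cm, viewing_distance: float = 57.0):
    """cm on the screen plane -> visual degrees (exact arctangent)."""
    return np.degrees(np.arctan2(cm, viewing_distance))


def project(points: np.ndarray, viewing_distance: float) -> np.ndarray:
    """Pinhole projection of eye-centered points onto the screen plane.

    Parameters
    ----------
    points : array, shape (..., 3)
        Eye-centered positions (X, Y, Z) in cm; Z must be positive.
    viewing_distance : float
        Eye-to-screen distance f in cm.

    Returns
    -------
    array, shape (..., 2)
        Screen positions f * (X/Z, Y/Z) in cm.
    """
    points = np.asarray(points, dtype=float)
    z = points[..., 2]
    if np.any(z <= 0):
        raise ValueError("cannot project a point at or behind the eye (Z <= 0)")
    return viewing_distance * points[..., :2] / z[..., None]


def flow_velocity(points: np.ndarray, translation: np.ndarray,
                  viewing_distance: float) -> np.ndarray:
    """Instantaneous screen velocity of scene-stationary points under
    observer translation.

    For translation T = (Tx, Ty, Tz) the projected point at screen position
    (x, y) with depth Z moves at

        dx/dt = (-f*Tx + x*Tz) / Z,   dy/dt = (-f*Ty + y*Tz) / Z.

    The focus of expansion sits at (f*Tx/Tz, f*Ty/Tz) and carries exactly
    zero flow.
    """
    points = np.asarray(points, dtype=float)
    t = np.asarray(translation, dtype=float)
    z = points[..., 2]
    if np.any(z <= 0):
        raise ValueError("flow undefined for a point at or behind the eye")
    xy = project(points, viewing_distance)
    f = viewing_distance
    vx = (-f * t[0] + xy[..., 0] * t[2]) / z
    vy = (-f * t[1] + xy[..., 1] * t[2]) / z
    return np.stack([vx, vy], axis=-1)


def generate_scene_exp1(config: SceneConfig, rng) -> np.ndarray:
    """Generate the Experiment 1 background-object positions.

    Objects start on a regular grid_cols x grid_rows grid centred on the
    gaze axis at the array distance, receive uniform x/y jitter and a uniform
    depth offset, and any object whose initial projection falls inside the
    exclusion rectangle around fixation is removed.

    Returns an (N, 3) array of eye-centered positions.
    """
    rng = np.random.default_rng(rng)
    cols = np.arange(config.grid_cols) - (config.grid_cols - 1) / 2
    rows = np.arange(config.grid_rows) - (config.grid_rows - 1) / 2
    gx, gy = np.meshgrid(cols * config.grid_spacing, rows * config.grid_spacing)
    n = gx.size
    x = gx.ravel() + rng.uniform(-config.jitter_halfwidth,
                                 config.jitter_halfwidth, n)
    y = gy.ravel() + rng.uniform(-config.jitter_halfwidth,
                                 config.jitter_halfwidth, n)
    z = config.array_distance + rng.uniform(-config.depth_halfrange,
                                            config.depth_halfrange, n)
    pts = np.column_stack([x, y, z])
    # exclusion region is specified in visual degrees around fixation
    ecc = screen_cm_to_deg(project(pts, config.viewing_distance),
                           config.viewing_distance)
    inside = ((np.abs(ecc[:, 0]) < config.exclusion_width / 2)
              & (np.abs(ecc[:, 1]) < config.exclusion_height / 2))
    return pts[~inside]


def _spawn_dots(config: FlowConfig, rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform screen positions (restricted to the active hemifield) and
    uniform depths for n new dots."""
    half_w = config.screen_width / 2
    half_h = config.screen_height / 2
    if config.field_mask == "HemiL":
        x = rng.uniform(-half_w, 0.0, n)
    elif config.field_mask == "HemiR":
        x = rng.uniform(0.0, half_w, n)
    else:
        x = rng.uniform(-half_w, half_w, n)
    y = rng.uniform(-half_h, half_h, n)
    z = rng.uniform(config.depth_min, config.depth_max, n)
    return np.column_stack([x, y]), z


def _offsides(config: FlowConfig, xy: np.ndarray) -> np.ndarray:
    """Dots outside the screen or outside the active hemifield."""
    half_w = config.screen_width / 2
    half_h = config.screen_height / 2
    out = (np.abs(xy[:, 0]) > half_w) | (np.abs(xy[:, 1]) > half_h)
    if config.field_mask == "HemiL":
        out |= xy[:, 0] > 0
    elif config.field_mask == "HemiR":
        out |= xy[:, 0] < 0
    return out


def generate_flow_trial_exp2(config: FlowConfig, rng,
                             trial_id: int = 0) -> pd.DataFrame:
    """Simulate one Experiment 2 flow-field trial frame by frame.

    Dots are advected by the radial flow of forward translation along gaze;
    a dot is re-seeded at a fresh uniform location after ``dot_lifetime``
    frames (initial ages are staggered so re-seeding is spread over the
    trial) or as soon as it leaves the screen / active hemifield.

    Returns a tidy frame with columns
    ``trial_id, frame, dot_id, x_cm, y_cm, z_cm`` where x/y are screen
    coordinates and z is the dot's depth.
    """
    rng = np.random.default_rng(rng)
    n = config.n_dots
    dt = 1.0 / config.frame_rate
    translation = np.array([0.0, 0.0, config.self_speed])
    f = config.viewing_distance

    xy, z = _spawn_dots(config, rng, n)
    if np.isfinite(config.dot_lifetime):
        age = rng.integers(0, int(config.dot_lifetime), n).astype(float)
    else:
        age = np.zeros(n)

    frames = []
    for frame in range(config.n_frames):
        frames.append(pd.DataFrame({
            "trial_id": trial_id,
            "frame": frame,
            "dot_id": np.arange(n),
            "x_cm": xy[:, 0].copy(),
            "y_cm": xy[:, 1].copy(),
            "z_cm": z.copy(),
        }))
        # advect: screen velocity of a scene point at this screen position/depth
        pts = np.column_stack([xy * z[:, None] / f, z])
        vel = flow_velocity(pts, translation, f)
        xy = xy + vel * dt
        z = z - config.self_speed * dt
        age = age + 1

        dead = _offsides(config, xy) | (z <= config.depth_min * 0.1)
        if np.isfinite(config.dot_lifetime):
            dead |= age >= config.dot_lifetime
        k = int(dead.sum())
        if k:
            xy[dead], z[dead] = _spawn_dots(config, rng, k)
            age[dead] = 0.0
    return pd.concat(frames, ignore_index=True)


def exp1_translation(config: SceneConfig, probe_side: str) -> np.ndarray:
    """Self-movement velocity vector for Experiment 1.

    Translation is directed at the probe's initial position (eccentricity
    ±2.4° at the array distance), so the focus of expansion coincides with
    the probe at trial onset.
    """
    sign = {"left": -1.0, "right": 1.0}[probe_side]
    x0 = sign * config.array_distance * np.tan(
        np.radians(config.probe_eccentricity))
    d = np.array([x0, 0.0, config.array_distance])
    return config.self_speed * d / np.linalg.norm(d)


def _probe_state_exp1(v: float, condition: str, config: SceneConfig,
                      probe_side: str, t: float):
    """Eye-centered probe position and velocity at time t.

    The probe is scene-stationary apart from a horizontal scene-relative
    velocity ``v``; in the moving condition the observer translates, which
    shifts the probe in eye coordinates.
    """
    sign = {"left": -1.0, "right": 1.0}[probe_side]
    x0 = sign * config.array_distance * np.tan(
        np.radians(config.probe_eccentricity))
    pos = np.array([x0 + v * t, 0.0, config.array_distance])
    vel = np.array([v, 0.0, 0.0])
    if condition == "moving":
        trans = exp1_translation(config, probe_side)
        pos = pos - trans * t
        vel = vel - trans
    elif condition != "static":
        raise ValueError(f"unknown condition {condition!r}")
    return pos, vel


def probe_kinematics_exp1(scene_lateral_velocity: float, condition: str,
                          config: SceneConfig, probe_side: str,
                          t: float = 0.0) -> ScreenKinematics:
    """On-screen probe position and velocity at time ``t`` into the trial.

    Static condition: pure projection of the lateral scene velocity
    (speed f/Z * v).  Moving condition: that plus the optic-flow component
    of a point riding at the probe's current position; the probe starts at
    the focus of expansion, so the flow contribution is zero at onset and
    grows as the probe translates away from it.
    """
    pos, vel = _probe_state_exp1(scene_lateral_velocity, condition, config,
                                 probe_side, t)
    f = config.viewing_distance
    screen_pos = project(pos, f)
    x, y = screen_pos
    z = pos[2]
    # d/dt [f X / Z] = f (Xdot Z - X Zdot) / Z^2, written via screen coords
    vx = (f * vel[0] - x * vel[2]) / z
    vy = (f * vel[1] - y * vel[2]) / z
    return ScreenKinematics(screen_pos, np.array([vx, vy]))


def flow_at_probe_exp1(scene_lateral_velocity: float, config: SceneConfig,
                       probe_side: str, t: float) -> np.ndarray:
    """Optic-flow vector (screen cm/s) at the probe's position at time t
    in the moving condition — the component a flow-parsing observer would
    subtract."""
    pos, _ = _probe_state_exp1(scene_lateral_velocity, "moving", config,
                               probe_side, t)
    trans = exp1_translation(config, probe_side)
    return flow_velocity(pos, trans, config.viewing_distance)


def flow_speed_at_probe_exp2(config: FlowConfig) -> float:
    """Expected optic-flow speed (screen cm/s) at the probe's location.

    The flow field is radial from fixation, so at the probe (±4° on the
    horizontal meridian) the flow is horizontal, pointing outward, with
    speed x * Tz / Z.  Depth is uniform over [depth_min, depth_max], so the
    expected speed uses the mean inverse depth
    E[1/Z] = ln(depth_max/depth_min) / (depth_max - depth_min).
    """
    x = deg_to_screen_cm(config.probe_eccentricity, config.viewing_distance)
    inv_z = (np.log(config.depth_max / config.depth_min)
             / (config.depth_max - config.depth_min))
    return float(x * config.self_speed * inv_z)
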