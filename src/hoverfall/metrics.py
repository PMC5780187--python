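"""Computations applied to (real or synthetic) 3-D trajectory recordings.

These mirror the experimental analysis chain: wing-force magnitude from
double-differentiated stereo positions, body pitch from head/centroid/tail
landmark regressions, the theoretical optic flow seen from a trajectory, and
the stereo-metrology error budget of the dual-view camera rig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "RawTrajectory3D",
    "StereoRig",
    "DEFAULT_RIG",
    "accel_from_positions",
    "body_axis_pitch",
    "theoretical_of",
    "stereo_min_distance",
    "quantization_uncertainty",
    "grating_spatial_frequency",
]

SAVGOL_ORDER = 1
SAVGOL_WINDOW = 11


@dataclass
class RawTrajectory3D:
    """Landmark positions tracked over time: head, centroid and tail of the
    body axis, in metres, sampled at the camera rate (1600 Hz)."""

    t: np.ndarray
    head: np.ndarray  # (n, 3)
    centroid: np.ndarray  # (n, 3)
    tail: np.ndarray  # (n, 3)
    pitch: np.ndarray | None = None  # derived, rad
    yaw: np.ndarray | None = None  # derived, rad

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("head", "centroid", "tail"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for name in ("head", "centroid", "tail"):
            arr = getattr(self, name)
            for i, ax in enumerate("xyz"):
                cols[f"{name}_{ax}"] = arr[:, i]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RawTrajectory3D":
        return cls(
            t=df["t"].to_numpy(),
            head=df[["head_x", "head_y", "head_z"]].to_numpy(),
            centroid=df[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(),
            tail=df[["tail_x", "tail_y", "tail_z"]].to_numpy(),
        )


@dataclass(frozen=True)
class StereoRig:
    """Geometry of the split-view stereo rig, all lengths in millimetres
    except the image width (pixels)."""

    sensor_width: float = 25.6  # SW, mm
    baseline: float = 333.5  # BL, mm
    image_width: float = 1280.0  # IW, pixels
    focal_length: float = 30.0  # FL, mm

    def __post_init__(self) -> None:
        for f in ("sensor_width", "baseline", "image_width", "focal_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


DEFAULT_RIG = StereoRig()


def accel_from_positions(positions: np.ndarray, ts: float
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Acceleration components and wing-force magnitude from a 3-D position
    series.

    Positions are double-differentiated by central differences and the
    resulting acceleration series smoothed with a Savitzky-Golay filter
    (order 1, window 11).  The force magnitude removes gravity from the
    vertical axis: ``|F| = sqrt(Axy^2 + (Az - g)^2)`` with g = -9.81, so an
    unpowered ballistic segment gives |F| ~ 0 and a stationary hover 9.81.

    Returns ``(a_xy, a_z, f_mag)``; the first and last sample of the central
    difference are edge-padded before filtering, so only filter-edge effects
    remain near the ends.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must have shape (n, 3)")
    if len(pos) < SAVGOL_WINDOW:
        raise ValueError(f"need at least {SAVGOL_WINDOW} samples")
    acc = np.empty_like(pos)
    acc[1:-1] = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) / ts**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    acc = savgol_filter(acc, SAVGOL_WINDOW, SAVGOL_ORDER, axis=0)
    a_xy = np.hypot(acc[:, 0], acc[:, 1])
    a_z = acc[:, 2]
    g = -9.81
    f_mag = np.sqrt(a_xy**2 + (a_z - g) ** 2)
    return a_xy, a_z, f_mag


def _regress_angle(u: np.ndarray, v: np.ndarray) -> tuple[float, bool]:
    """Angle of the best-fit line v = f(u) through a point cloud, via least
    squares on the centred coordinates; falls back to the principal component
    axis when the cloud is degenerate in u (vertical line).  Returns
    (angle, used_pca_fallback)."""
    uc = u - u.mean()
    vc = v - v.mean()
    suu = float(np.dot(uc, uc))
    if suu < 1e-12 * max(float(np.dot(vc, vc)), 1e-30):
        cov = np.cov(np.stack([uc, vc]))
        w, vecs = np.linalg.eigh(cov)
        axis = vecs[:, np.argmax(w)]
        return math.atan2(axis[1], axis[0]), True
    slope = float(np.dot(uc, vc)) / suu
    return math.atan2(slope, 1.0), False


def body_axis_pitch(head: np.ndarray, centroid: np.ndarray, tail: np.ndarray
                    ) -> tuple[float, float, bool]:
    """Yaw and pitch of the body axis from landmark point clouds of a single
    frame (the tracked clouds are stacked head/centroid/tail replicates).

    Two successive linear regressions, as in the stereo analysis: first the
    yaw angle in the XY plane, then — after counter-rotating the cloud to
    align the axis with X — the pitch angle in the ZX plane.  The head
    landmark orients the axis so the sign of the pitch follows the head.
    Pitch is confined to [-pi/2, pi/2].  Returns ``(yaw, pitch, degenerate)``.
    """
    pts = np.vstack([np.atleast_2d(head), np.atleast_2d(centroid),
                     np.atleast_2d(tail)]).astype(float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    yaw, degenerate = _regress_angle(pts[:, 0], pts[:, 1])
    # orient the yaw axis from tail to head
    head_xy = np.atleast_2d(head)[:, :2].mean(axis=0)
    tail_xy = np.atleast_2d(tail)[:, :2].mean(axis=0)
    d = head_xy - tail_xy
    if d @ np.array([math.cos(yaw), math.sin(yaw)]) < 0:
        yaw = math.atan2(math.sin(yaw + math.pi), math.cos(yaw + math.pi))
    c, s = math.cos(-yaw), math.sin(-yaw)
    x_rot = c * pts[:, 0] - s * pts[:, 1]
    pitch, deg2 = _regress_angle(x_rot, pts[:, 2])
    # regression slope angle is already within (-pi/2, pi/2)
    return yaw, pitch, degenerate or deg2


def theoretical_of(velocities: np.ndarray, wall_distances: tuple[float, float],
                   pitch: np.ndarray | None = None) -> pd.DataFrame:
    """Theoretical optic flow along a trajectory: magnitude = speed divided
    by the distance to the *nearest* wall (the larger of the two candidate
    flow vectors), direction opposite to the velocity, fly-frame components
    through the measured pitch.

    ``velocities`` has shape (n, 2) for planar (vx, vz).  Returns a DataFrame
    with omega_mag, omega_x, omega_z.
    """
    d1, d2 = wall_distances
    if d1 <= 0 or d2 <= 0:
        raise ValueError("wall distances must be > 0")
    d = min(d1, d2)
    vel = np.asarray(velocities, dtype=float)
    if vel.ndim != 2 or vel.shape[1] != 2:
        raise ValueError("velocities must have shape (n, 2)")
    th = np.zeros(len(vel)) if pitch is None else np.asarray(pitch, dtype=float)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    mag = speed / d
    ang = np.arctan2(vel[:, 1], vel[:, 0]) - th + math.pi
    with np.errstate(invalid="ignore"):
        wx = np.where(speed > 0, mag * np.cos(ang), 0.0)
        wz = np.where(speed > 0, mag * np.sin(ang), 0.0)
    return pd.DataFrame({"omega_mag": mag, "omega_x": wx, "omega_z": wz})


def stereo_min_distance(rig: StereoRig, d: float) -> float:
    """Minimal resolvable distance between two points (mm) at object distance
    ``d`` (mm): ``Delta_d = d^2 * SW / (BL * IW * FL)``.  Grows with the
    square of the distance."""
    if d <= 0:
        raise ValueError("object distance must be > 0")
    return d**2 * rig.sensor_width / (
        rig.baseline * rig.image_width * rig.focal_length
    )


def quantization_uncertainty(delta_d: float) -> float:
    """RMS positional uncertainty (mm) induced by pixel quantization:
    ``QPU_rms = sqrt(Delta_d^2 / 12)`` — linear in Delta_d."""
    if delta_d < 0:
        raise ValueError("delta_d must be >= 0")
    return math.sqrt(delta_d**2 / 12.0)


def grating_spatial_frequency(stripe_width: float, distance: float) -> float:
    """Spatial frequency (cycles/degree) of a square-wave grating with the
    given stripe width, viewed at the given distance (both in metres).

    One cycle is two stripes; the subtended angle of one cycle is the exact
    arctangent ``2*atan(period / (2*distance))`` converted to degrees.
    """
    if stripe_width <= 0 or distance <= 0:
        raise ValueError("stripe width and distance must be > 0")
    period = 2.0 * stripe_width
    angle_deg = math.degrees(2.0 * math.atan(period / (2.0 * distance)))
    return 1.0 / angle_deg
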