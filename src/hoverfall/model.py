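"""Geometric and kinematic primitives of the free-fall flight model.

The virtual fly moves in a vertical plane inside an infinitely long corridor
(distance ``d_wall`` to each textured wall).  Conventions used throughout:

* z is up, the floor is at z = 0, the release point at z = 0.40 m;
* pitch ``theta_p`` is 0 when the body is horizontal, negative head-down,
  bounded physiologically to [-pi/2, pi/2] in reported phases;
* the mass-normalised wing force (units m/s^2) is orthogonal to the body
  axis, so ``L = cos(theta_p)*F`` (vertical lift) and ``T = -sin(theta_p)*F``
  (horizontal thrust): pitching down from the head tilts the force forward —
  the helicopter analogy;
* translational optic flow has magnitude |V|/d_wall and points opposite to
  the velocity; its components are taken in the fly frame, i.e. rotated by
  -theta_p from the inertial frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "BodyState",
    "OpticFlowSample",
    "ForceState",
    "ControllerGains",
    "IMPROVED_GAINS",
    "SimConfig",
    "lift_thrust",
    "optic_flow",
    "integrate_kinematics",
    "visual_pd",
    "halteres_loop_step",
]


@dataclass(frozen=True)
class BodyState:
    """Full planar kinematic/attitude state of the fly at one instant."""

    t: float  # s since release
    theta_p: float  # body pitch, rad
    theta_p_dot: float  # pitch rate, rad/s
    x: float  # horizontal position, m
    z: float  # height above the floor, m
    vx: float  # horizontal speed, m/s
    vz: float  # vertical speed, m/s (negative = falling)


@dataclass(frozen=True)
class OpticFlowSample:
    """Translational optic-flow magnitude and fly-frame components.

    ``omega_mag`` is kept non-negative; direction is carried by the angles.
    ``theta_v_ri`` is the inertial-frame direction of the velocity vector,
    ``theta_v_rfly`` the same direction seen in the fly frame; the flow itself
    points the opposite way (angle + pi).
    """

    omega_mag: float  # |omega|, rad/s (model units |V|/d_wall)
    theta_v_ri: float  # velocity direction, inertial frame, rad
    theta_v_rfly: float  # velocity direction, fly frame, rad
    omega_x: float  # forward flow component, fly frame
    omega_z: float  # vertical flow component, fly frame


@dataclass(frozen=True)
class ForceState:
    """Mass-normalised wing force and its inertial-frame decomposition."""

    f_mag: float  # |F|, m/s^2
    lift: float  # vertical component L, m/s^2
    thrust: float  # horizontal component T, m/s^2


@dataclass(frozen=True)
class ControllerGains:
    """All controller gains of the model.

    The halteres PI gains are fixed from prior measurements on flies; the
    visual PD gains (KpV, KdV) are the free parameters identified from data
    by the grid-likelihood procedure.  The absolute-pitch PD and vertical-OF
    PI gains belong to the improved model only and are zero in the basic one.
    """

    kp_h: float = 7.0  # halteres proportional gain
    ki_h: float = 0.3  # halteres integral gain
    kp_v: float = 5.0  # visual PD proportional gain (estimated)
    kd_v: float = 0.3  # visual PD derivative gain (estimated)
    tau_d: float = 0.01  # derivative filter time constant, s
    omega_x_setpoint: float = 0.04  # forward-OF reference, model OF units
    actuator_lag: float = 0.002  # wing-pitch first-order lag, s
    # improved-model loops (zero = disabled -> reduces to the basic model)
    kp_theta: float = 0.0  # absolute-pitch PD proportional, 1/s
    kd_theta: float = 0.0  # absolute-pitch PD derivative, dimensionless
    kp_wz: float = 0.0  # vertical-OF PI proportional
    ki_wz: float = 0.0  # vertical-OF PI integral

    def __post_init__(self) -> None:
        for name in ("kp_h", "ki_h", "kp_v", "kd_v", "kp_theta", "kd_theta",
                     "kp_wz", "ki_wz", "omega_x_setpoint"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"gain {name} must be finite, got {v}")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be > 0")
        if self.actuator_lag <= 0:
            raise ValueError("actuator_lag must be > 0")

    def with_visual(self, kp_v: float, kd_v: float) -> "ControllerGains":
        """Copy with different visual PD gains (used on the estimation grid)."""
        return replace(self, kp_v=kp_v, kd_v=kd_v)


#: Improved-model gains tuned so the closed loop reproduces the observed
#: recovery: pitch realigned with the horizontal within 150 ms of wingbeat
#: onset and no crash over a 3 s hover (see docs/methods.md for the tuning
#: rationale).
IMPROVED_GAINS = ControllerGains(
    kp_theta=100.0,
    kd_theta=2.0,
    kp_wz=6.0,
    ki_wz=80.0,
)


@dataclass(frozen=True)
class SimConfig:
    """Physical constants and simulation settings of the free-fall protocol."""

    d_wall: float = 0.20  # distance to each corridor wall, m
    box_height: float = 0.40  # release height above the floor, m
    g: float = 9.81  # gravity magnitude, m/s^2
    ts: float = 1.0 / 1600.0  # sample period (camera frame rate), s
    onset_window: tuple[float, float] = (0.075, 0.150)  # wingbeat onset range, s
    horizon: float = 3.0  # simulation length, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_wall <= 0:
            raise ValueError("d_wall must be > 0")
        if self.ts <= 0:
            raise ValueError("ts must be > 0")
        lo, hi = self.onset_window
        if not (0 < lo <= hi < self.horizon):
            raise ValueError("onset_window must lie within (0, horizon)")


def lift_thrust(theta_p: float, f_mag: float) -> ForceState:
    """Decompose the wing force (orthogonal to the body axis) into vertical
    lift and horizontal thrust:  L = sin(theta_p + pi/2)*|F| = cos(theta_p)*|F|,
    T = cos(theta_p + pi/2)*|F| = -sin(theta_p)*|F|."""
    if f_mag < 0:
        raise ValueError("force magnitude must be >= 0")
    return ForceState(
        f_mag=f_mag,
        lift=math.cos(theta_p) * f_mag,
        thrust=-math.sin(theta_p) * f_mag,
    )


def optic_flow(vx: float, vz: float, theta_p: float, d_wall: float) -> OpticFlowSample:
    """Translational optic flow experienced at speed (vx, vz) and pitch
    ``theta_p`` at distance ``d_wall`` from the wall.

    Magnitude |V|/d_wall; the flow vector is the opposite of the velocity, and
    the fly-frame direction subtracts the body pitch.  During a straight fall
    (vz < 0, vx = 0, theta_p = 0) the flow sweeps upward through the visual
    field: omega_z = -vz/d_wall > 0 and omega_x = 0.
    """
    if d_wall <= 0:
        raise ValueError("d_wall must be > 0")
    v = math.hypot(vx, vz)
    if v == 0.0:
        return OpticFlowSample(0.0, 0.0, 0.0, 0.0, 0.0)
    theta_v_ri = math.atan2(vz, vx)
    theta_v_rfly = theta_v_ri - theta_p
    mag = v / d_wall
    flow_angle = theta_v_rfly + math.pi  # flow opposes motion
    return OpticFlowSample(
        omega_mag=mag,
        theta_v_ri=theta_v_ri,
        theta_v_rfly=theta_v_rfly,
        omega_x=mag * math.cos(flow_angle),
        omega_z=mag * math.sin(flow_angle),
    )


def integrate_kinematics(
    state: BodyState, lift: float, thrust: float, g: float, ts: float,
    theta_p_dot_new: float | None = None,
) -> BodyState:
    """One explicit integration step of the mass-normalised dynamics
    (vdot_z = -g + L, vdot_x = T), forward Euler on velocity and trapezoid on
    position, so an unforced step reproduces the ballistic closed form
    exactly.  If ``theta_p_dot_new`` is given, pitch advances by the trapezoid
    of the old and new rates."""
    vz_new = state.vz + ts * (lift - g)
    vx_new = state.vx + ts * thrust
    z_new = state.z + ts * 0.5 * (state.vz + vz_new)
    x_new = state.x + ts * 0.5 * (state.vx + vx_new)
    if theta_p_dot_new is None:
        theta_p_dot_new = state.theta_p_dot
    theta_new = state.theta_p + ts * 0.5 * (state.theta_p_dot + theta_p_dot_new)
    return BodyState(
        t=state.t + ts,
        theta_p=theta_new,
        theta_p_dot=theta_p_dot_new,
        x=x_new,
        z=z_new,
        vx=vx_new,
        vz=vz_new,
    )


def visual_pd(omega_x_error_series, kp_v: float, kd_v: float, tau_d: float,
              ts: float = 1.0 / 1600.0):
    """Filtered-derivative PD of the forward-OF error sequence:
    ``Kp + Kd*s/(tau*s + 1)`` applied sample-wise at period ``ts``.
    For a constant error e the output settles at Kp*e (DC gain Kp)."""
    from .blocks import LTIBlock, pd_tf

    num, den = pd_tf(kp_v, kd_v, tau_d)
    blk = LTIBlock(num, den, ts)
    import numpy as np

    return blk.simulate(np.asarray(omega_x_error_series, dtype=float))


def halteres_loop_step(theta_p_dot_star_series, kp_h: float = 7.0,
                       ki_h: float = 0.3, actuator_lag: float = 0.002,
                       ts: float = 1.0 / 1600.0):
    """Closed-loop pitch-rate tracking by the halteres reflex: PI controller
    cascaded with the wing-pitch actuator lag under unity feedback, simulated
    as the algebraically reduced closed-loop transfer function.  Constant
    setpoints are tracked with zero steady-state error."""
    from .blocks import LTIBlock, halteres_closed_loop_tf

    num, den = halteres_closed_loop_tf(kp_h, ki_h, actuator_lag)
    blk = LTIBlock(num, den, ts)
    import numpy as np

    return blk.simulate(np.asarray(theta_p_dot_star_series, dtype=float))
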