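"""End-to-end free-fall simulations: passive drop, wingbeat onset, closed loop.

Two model variants are composed from the block layer:

* **basic** — pitch-rate command from a PD controller on the forward optic
  flow error only; wing force follows the open-loop step transient C_WB.
  Reproduces the first ~200 ms of the recovery but is structurally unstable
  (three integrators separate the measured flow from the commanded pitch).
* **improved** — adds (a) a PI loop on the vertical optic flow that modulates
  the wing-force magnitude (the integrator nulls the vertical flow while
  retaining the steady lift needed to hover) and (b) a PD loop on the absolute
  pitch angle feeding the pitch-rate command.  This variant settles to a
  stable hover.

The simulation is planar (corridor axis x, height z), fixed step at the
camera period Ts = 1/1600 s, with the optic-flow measurement fed back with a
one-sample sensor delay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .blocks import (
    PASSIVE_PITCH_DEN,
    PASSIVE_PITCH_NUM,
    WING_FORCE_DEN,
    WING_FORCE_NUM,
    halteres_closed_loop_tf,
    pd_tf,
    pi_tf,
    tustin,
)


def _df2t_coeffs(num, den, fs: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tustin coefficients padded to a fixed difference-equation order."""
    b, a = tustin(num, den, fs)
    b = np.concatenate([b, np.zeros(order + 1 - len(b))])
    a = np.concatenate([a, np.zeros(order + 1 - len(a))])
    return b, a
from .model import ControllerGains, SimConfig

__all__ = ["FallTrajectory", "simulate_fall_basic", "simulate_fall_improved",
           "simulate_fall", "detect_crash"]

VARIANTS = ("basic", "improved")

#: Divergence guard: a run is flagged 'diverged' (and halted) once the pitch
#: or speed leaves any physically meaningful range, keeping ensembles finite.
MAX_ABS_PITCH = math.pi
MAX_SPEED = 50.0


@dataclass
class FallTrajectory:
    """A simulated fall sampled at Ts: state, optic flow and force series."""

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    vx: np.ndarray
    vz: np.ndarray
    theta_p: np.ndarray
    theta_p_dot: np.ndarray
    f_mag: np.ndarray
    lift: np.ndarray
    thrust: np.ndarray
    omega_x: np.ndarray
    omega_z: np.ndarray
    onset_time: float
    variant: str
    crashed: bool
    crash_time: float | None
    diverged: bool = False
    diverge_time: float | None = None
    horizon_censored: bool = False

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "x": self.x, "z": self.z,
                "vx": self.vx, "vz": self.vz,
                "theta_p": self.theta_p, "theta_p_dot": self.theta_p_dot,
                "F_mag": self.f_mag, "L": self.lift, "T": self.thrust,
                "omega_x": self.omega_x, "omega_z": self.omega_z,
            }
        )

    def save_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        """Write the state table as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "onset_time": self.onset_time,
            "variant": self.variant,
            "crashed": self.crashed,
            "crash_time": self.crash_time,
            "diverged": self.diverged,
            "horizon_censored": self.horizon_censored,
        }
        if metadata:
            meta.update(metadata)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


@lru_cache(maxsize=8)
def _passive_pitch_table(ts: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Passive pitch and pitch-rate series over the fall phase (n samples).
    Sample 0 is the release instant (pitch 0); the -pi/2 step drives the
    fifth-order tilt transfer function from sample 1 on."""
    b, a = signal.bilinear(PASSIVE_PITCH_NUM, PASSIVE_PITCH_DEN, fs=1.0 / ts)
    y = signal.lfilter(b, a, np.full(n, -math.pi / 2.0))
    theta = np.concatenate([[0.0], y])[:n]
    rate = np.empty(n)
    rate[1:] = np.diff(theta) / ts
    rate[0] = 0.0
    return theta, rate


@lru_cache(maxsize=8)
def _wing_force_table(ts: float, n: int, g: float) -> np.ndarray:
    """Open-loop wing-force transient after onset: C_WB driven by a step of
    amplitude g, zero at the onset sample itself, clamped non-negative."""
    b, a = signal.bilinear(WING_FORCE_NUM, WING_FORCE_DEN, fs=1.0 / ts)
    y = signal.lfilter(b, a, np.full(n, g))
    return np.maximum(np.concatenate([[0.0], y])[:n], 0.0)


def simulate_fall(
    config: SimConfig,
    gains: ControllerGains,
    onset: float,
    variant: str = "basic",
    horizon: float | None = None,
    record: str = "full",
) -> FallTrajectory:
    """Simulate one fall from release to floor contact, divergence, or the
    horizon.

    Phase 1 (t < onset): frictionless ballistic drop with the passive
    nose-down pitch transient; no wing force.  Phase 2 (t >= onset): the wing
    force step and both optic-flow control loops are activated
    simultaneously; the halteres loop takes over the pitch rate from its
    passive value at onset.

    ``record='pitch'`` returns only the pitch series (fast path used by the
    likelihood grid); ``'full'`` records every signal.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    horizon = config.horizon if horizon is None else horizon
    if horizon <= onset:
        raise ValueError(f"horizon {horizon} s must exceed onset {onset} s")
    ts = config.ts
    g = config.g
    d_wall = config.d_wall
    n = int(round(horizon / ts)) + 1
    k_onset = int(round(onset / ts))

    # round table lengths up to coarse buckets so the lru_cache actually hits
    n_pass = max(512, 1 << (k_onset + 1).bit_length())
    theta_pass, rate_pass = _passive_pitch_table(ts, n_pass)
    f_wb = _wing_force_table(ts, ((n // 4096) + 1) * 4096, g)

    # ---- phase 1: closed-form ballistic fall + passive pitch ----
    kk = np.arange(k_onset + 1)
    t1 = kk * ts
    z1 = config.box_height - 0.5 * g * t1**2
    vz1 = -g * t1
    th1 = theta_pass[: k_onset + 1]
    thd1 = rate_pass[: k_onset + 1]

    full = record == "full"
    if full:
        t_l = list(t1)
        x_l = [0.0] * (k_onset + 1)
        z_l = list(z1)
        vx_l = [0.0] * (k_onset + 1)
        vz_l = list(vz1)
        th_l = list(th1)
        thd_l = list(thd1)
        f_l = [0.0] * (k_onset + 1)
        li_l = [0.0] * (k_onset + 1)
        tr_l = [0.0] * (k_onset + 1)
        wx_l = []
        wz_l = []
        for i in range(k_onset + 1):
            v = abs(vz1[i])
            if v == 0.0:
                wx_l.append(0.0)
                wz_l.append(0.0)
            else:
                mag = v / d_wall
                ang = math.atan2(vz1[i], 0.0) - th1[i] + math.pi
                wx_l.append(mag * math.cos(ang))
                wz_l.append(mag * math.sin(ang))
    else:
        th_l = list(th1)

    # ---- controller discretizations (direct form II transposed) ----
    fs = 1.0 / ts
    b_pd, a_pd = _df2t_coeffs(*pd_tf(gains.kp_v, gains.kd_v, gains.tau_d), fs, 1)
    pd_b0, pd_b1 = float(b_pd[0]), float(b_pd[1])
    pd_a1 = float(a_pd[1])
    b_h, a_h = _df2t_coeffs(
        *halteres_closed_loop_tf(gains.kp_h, gains.ki_h, gains.actuator_lag), fs, 2
    )
    h_b0, h_b1, h_b2 = (float(v) for v in b_h)
    h_a1, h_a2 = float(a_h[1]), float(a_h[2])
    improved = variant == "improved"
    if improved:
        b_pi, a_pi = _df2t_coeffs(*pi_tf(gains.kp_wz, gains.ki_wz), fs, 1)
        pi_b0, pi_b1 = float(b_pi[0]), float(b_pi[1])
        pi_a1 = float(a_pi[1])
        kp_th, kd_th = gains.kp_theta, gains.kd_theta

    # ---- phase 2 initial conditions ----
    theta = float(th1[-1])
    theta_dot = float(thd1[-1])
    x = 0.0
    z = float(z1[-1])
    vx = 0.0
    vz = float(vz1[-1])
    # halteres loop hands over from the passive pitch rate (continuous output)
    h_z1 = theta_dot * ((h_b1 - h_a1) + (h_b2 - h_a2))
    h_z2 = theta_dot * (h_b2 - h_a2)
    pd_z = 0.0
    pi_z = 0.0
    # measured OF at onset (one-sample sensor delay thereafter)
    v = math.hypot(vx, vz)
    if v == 0.0:
        wx_m = wz_m = 0.0
    else:
        mag = v / d_wall
        ang = math.atan2(vz, vx) - theta + math.pi
        wx_m = mag * math.cos(ang)
        wz_m = mag * math.sin(ang)

    setpoint = gains.omega_x_setpoint
    f_wb_list = f_wb[: n - k_onset].tolist()  # pure floats in the hot loop
    crashed = False
    crash_time = None
    diverged = False
    diverge_time = None
    k_end = n - 1

    for k in range(k_onset + 1, n):
        # pitch-rate command: visual PD on forward-OF error (+ pitch PD)
        err = setpoint - wx_m
        u_pd = pd_b0 * err + pd_z
        pd_z = pd_b1 * err - pd_a1 * u_pd
        cmd = u_pd
        if improved:
            cmd += kp_th * (0.0 - theta) + kd_th * (0.0 - theta_dot)
        # halteres closed loop tracks the command
        td_new = h_b0 * cmd + h_z1
        h_z1 = h_b1 * cmd - h_a1 * td_new + h_z2
        h_z2 = h_b2 * cmd - h_a2 * td_new
        # wing-force magnitude
        f = f_wb_list[k - k_onset]
        if improved:
            u_pi = pi_b0 * wz_m + pi_z
            pi_z = pi_b1 * wz_m - pi_a1 * u_pi
            f += u_pi
            if f < 0.0:
                f = 0.0
        lift = math.cos(theta) * f
        thrust = -math.sin(theta) * f
        # kinematics (Euler on velocity, trapezoid on position and pitch)
        vz_new = vz + ts * (lift - g)
        vx_new = vx + ts * thrust
        z += ts * 0.5 * (vz + vz_new)
        x += ts * 0.5 * (vx + vx_new)
        theta += ts * 0.5 * (theta_dot + td_new)
        theta_dot = td_new
        vz, vx = vz_new, vx_new
        # optic flow from the new state (measured next sample)
        v = math.hypot(vx, vz)
        if v == 0.0:
            wx_m = wz_m = 0.0
        else:
            mag = v / d_wall
            ang = math.atan2(vz, vx) - theta + math.pi
            wx_m = mag * math.cos(ang)
            wz_m = mag * math.sin(ang)

        if full:
            t_l.append(k * ts)
            x_l.append(x)
            z_l.append(z)
            vx_l.append(vx)
            vz_l.append(vz)
            th_l.append(theta)
            thd_l.append(theta_dot)
            f_l.append(f)
            li_l.append(lift)
            tr_l.append(thrust)
            wx_l.append(wx_m)
            wz_l.append(wz_m)
        else:
            th_l.append(theta)

        if z <= 0.0:
            crashed = True
            crash_time = k * ts
            k_end = k
            break
        if abs(theta) > MAX_ABS_PITCH or v > MAX_SPEED:
            diverged = True
            diverge_time = k * ts
            k_end = k
            break

    censored = bool((not crashed) and (not diverged) and vz < 0.0)
    if not full:
        m = len(th_l)
        empty = np.zeros(0)
        return FallTrajectory(
            t=np.arange(m) * ts, x=empty, z=empty, vx=empty, vz=empty,
            theta_p=np.asarray(th_l), theta_p_dot=empty,
            f_mag=empty, lift=empty, thrust=empty, omega_x=empty, omega_z=empty,
            onset_time=onset, variant=variant,
            crashed=crashed, crash_time=crash_time,
            diverged=diverged, diverge_time=diverge_time,
            horizon_censored=censored,
        )
    return FallTrajectory(
        t=np.asarray(t_l), x=np.asarray(x_l), z=np.asarray(z_l),
        vx=np.asarray(vx_l), vz=np.asarray(vz_l),
        theta_p=np.asarray(th_l), theta_p_dot=np.asarray(thd_l),
        f_mag=np.asarray(f_l), lift=np.asarray(li_l), thrust=np.asarray(tr_l),
        omega_x=np.asarray(wx_l), omega_z=np.asarray(wz_l),
        onset_time=onset, variant=variant,
        crashed=crashed, crash_time=crash_time,
        diverged=diverged, diverge_time=diverge_time,
        horizon_censored=censored,
    )


def simulate_fall_basic(config: SimConfig, gains: ControllerGains, onset: float,
                        horizon: float | None = None) -> FallTrajectory:
    """Basic model (forward-OF regulation only)."""
    return simulate_fall(config, gains, onset, "basic", horizon)


def simulate_fall_improved(config: SimConfig, gains: ControllerGains, onset: float,
                           horizon: float | None = None) -> FallTrajectory:
    """Improved model (adds the vertical-OF force loop and absolute-pitch PD)."""
    return simulate_fall(config, gains, onset, "improved", horizon)


def detect_crash(traj: FallTrajectory, floor_z: float = 0.0
                 ) -> tuple[bool, float | None]:
    """First sample at which the height reaches the floor, or (False, None).

    A trajectory that ends above the floor while still descending is
    horizon-censored, not crash-free evidence; the flag on the trajectory
    records that.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    below = np.nonzero(traj.z <= floor_z)[0]
    if below.size == 0:
        return False, None
    return True, float(traj.t[below[0]])
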