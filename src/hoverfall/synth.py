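"""Synthetic pseudo-experimental cohorts.

The study's raw material is a set of high-speed stereo recordings of falling
hoverflies.  This module emulates that material: each trial is a simulated
fall (improved model by default — the variant that, like the animals,
recovers), converted to 3-D landmark tracks (head, centroid, tail placed
along the body axis), with Gaussian position noise at the stereo
quantization scale and onset times drawn from the measured distribution.
A truth sidecar records everything needed to re-derive any label.

Non-recovering trials — the study discarded 13 of 57 — are produced either
by delaying the wingbeat onset past the 150 ms cut-off or by zeroing the
force loop (the fly never pulls out), exercising both clauses of the trial
selection filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import RawTrajectory3D
from .model import IMPROVED_GAINS, ControllerGains, SimConfig
from .simulate import FallTrajectory, simulate_fall

__all__ = ["SynthCohortSpec", "generate_onsets", "generate_cohort", "synthesize_landmarks"]

#: Lognormal onset distribution matched to the measured wingbeat-initiation
#: times: the shape puts ~95% of the open-form mass within [60, 180] ms, and
#: the location is calibrated so the mean *after* truncation to the 75-150 ms
#: sampling window equals the measured 103 ms.
ONSET_LOGNORMAL_MEAN = 0.103
ONSET_LOGNORMAL_SIGMA = 0.28
ONSET_LOGNORMAL_MU = -2.35404945850051  # truncated-mean calibration


@dataclass(frozen=True)
class SynthCohortSpec:
    """Parameters of a synthetic cohort of falls."""

    n_trials: int = 57
    gains: ControllerGains = field(default_factory=lambda: IMPROVED_GAINS)
    variant: str = "improved"
    onset_distribution: str = "lognormal"  # or "uniform"
    pitch_noise_sd: float = 0.08  # rad, stereo pitch-measurement error
    position_noise_sd: float = 0.0005  # m, sub-millimetre quantization noise
    nonrecovering_fraction: float = 13.0 / 57.0
    body_length_range: tuple[float, float] = (0.010, 0.015)  # m
    horizon: float = 0.5  # s, covers onset + the 300 ms analysis window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.pitch_noise_sd < 0 or self.position_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 <= self.nonrecovering_fraction <= 1:
            raise ValueError("nonrecovering_fraction must be in [0, 1]")


def generate_onsets(n: int, distribution: str, rng: np.random.Generator,
                    window: tuple[float, float] = (0.075, 0.150)) -> np.ndarray:
    """Draw ``n`` iid wingbeat-onset times (s).

    'uniform' samples the stated window; 'lognormal' draws from the
    distribution matched to the measured onsets (mean ~103 ms) truncated to
    the window by rejection.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = window
    if distribution == "uniform":
        return rng.uniform(lo, hi, size=n)
    if distribution == "lognormal":
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.lognormal(ONSET_LOGNORMAL_MU, ONSET_LOGNORMAL_SIGMA,
                                 size=2 * (n - filled) + 8)
            keep = draw[(draw >= lo) & (draw <= hi)]
            take = min(len(keep), n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out
    raise ValueError(f"unknown onset distribution {distribution!r}")


def synthesize_landmarks(
    traj: FallTrajectory,
    body_length: float,
    rng: np.random.Generator,
    position_noise_sd: float = 0.0005,
    pitch_noise_sd: float = 0.0,
    n_replicates: int = 1,
    y_drift: float = 0.0,
) -> RawTrajectory3D:
    """Convert a planar simulated fall into 3-D landmark tracks.

    Head and tail sit at +/- half the body length along the body axis from
    the centroid; the planar state is embedded at y = y_drift * t (slow
    lateral drift, zero by default).  Pitch noise perturbs the axis
    orientation per frame (emulating the stereo pitch error); position noise
    is iid Gaussian per landmark and axis.  ``n_replicates`` > 1 emulates the
    threshold-sweep point clouds of the tracking procedure by stacking noisy
    replicates — frames are then repeated row-wise.
    """
    n = len(traj.t)
    if n == 0 or len(traj.x) != n:
        raise ValueError("need a fully recorded trajectory")
    half = 0.5 * body_length
    pitch_obs = traj.theta_p + (
        rng.normal(0.0, pitch_noise_sd, size=n) if pitch_noise_sd > 0 else 0.0
    )
    cx = traj.x
    cy = y_drift * traj.t
    cz = traj.z
    # body axis unit vector in the XZ plane (yaw = 0: heading along +x)
    ux = np.cos(pitch_obs)
    uz = np.sin(pitch_obs)
    reps = []
    for _ in range(max(n_replicates, 1)):
        centroid = np.stack([cx, cy, cz], axis=1)
        head = np.stack([cx + half * ux, cy, cz + half * uz], axis=1)
        tail = np.stack([cx - half * ux, cy, cz - half * uz], axis=1)
        if position_noise_sd > 0:
            head = head + rng.normal(0.0, position_noise_sd, head.shape)
            tail = tail + rng.normal(0.0, position_noise_sd, tail.shape)
            centroid = centroid + rng.normal(0.0, position_noise_sd, centroid.shape)
        reps.append((head, centroid, tail))
    head = np.concatenate([r[0] for r in reps])
    centroid = np.concatenate([r[1] for r in reps])
    tail = np.concatenate([r[2] for r in reps])
    t = np.tile(traj.t, max(n_replicates, 1))
    return RawTrajectory3D(t=t, head=head, centroid=centroid, tail=tail,
                           pitch=np.tile(pitch_obs, max(n_replicates, 1)))


def generate_cohort(
    spec: SynthCohortSpec,
    config: SimConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[RawTrajectory3D], list[FallTrajectory], dict]:
    """Generate a cohort of pseudo-experimental falls.

    Runs the configured simulator per trial, synthesizes noisy landmark
    tracks, and assembles a truth sidecar (gains, onsets, crash labels,
    non-recovery mechanism per trial).  The number of non-recovering trials
    is ``round(n_trials * nonrecovering_fraction)``; they alternate between
    the delayed-onset and the zeroed-force mechanism.

    Returns ``(raw_trajectories, fall_trajectories, truth)`` and, if
    ``outdir`` is given, writes one CSV per trial plus ``truth.json``.
    """
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(spec.seed)
    n_bad = int(round(spec.n_trials * spec.nonrecovering_fraction))
    onsets = generate_onsets(spec.n_trials, spec.onset_distribution, rng,
                             window=config.onset_window)
    body_lengths = rng.uniform(*spec.body_length_range, size=spec.n_trials)
    # which trials fail to recover, and by which mechanism
    bad_idx = rng.choice(spec.n_trials, size=n_bad, replace=False)
    mechanisms = ["recovering"] * spec.n_trials
    for rank, idx in enumerate(sorted(bad_idx)):
        mechanisms[idx] = "late_onset" if rank % 2 == 0 else "no_force"

    raws: list[RawTrajectory3D] = []
    falls: list[FallTrajectory] = []
    trials_meta = []
    for i in range(spec.n_trials):
        onset = float(onsets[i])
        if mechanisms[i] == "late_onset":
            onset = float(rng.uniform(0.155, 0.200))
        if mechanisms[i] == "no_force":
            traj = _passive_fall(config, onset, spec.horizon)
        else:
            traj = simulate_fall(config, spec.gains, onset, spec.variant,
                                 horizon=spec.horizon)
        trial_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        raw = synthesize_landmarks(
            traj, float(body_lengths[i]), trial_rng,
            position_noise_sd=spec.position_noise_sd,
            pitch_noise_sd=spec.pitch_noise_sd,
        )
        raws.append(raw)
        falls.append(traj)
        trials_meta.append(
            {
                "trial": i,
                "onset_time": traj.onset_time,
                "body_length": float(body_lengths[i]),
                "mechanism": mechanisms[i],
                "crashed": traj.crashed,
                "crash_time": traj.crash_time,
            }
        )
    truth = {
        "spec": {
            "n_trials": spec.n_trials,
            "variant": spec.variant,
            "onset_distribution": spec.onset_distribution,
            "pitch_noise_sd": spec.pitch_noise_sd,
            "position_noise_sd": spec.position_noise_sd,
            "nonrecovering_fraction": spec.nonrecovering_fraction,
            "seed": spec.seed,
        },
        "gains": {
            "kp_v": spec.gains.kp_v, "kd_v": spec.gains.kd_v,
            "kp_h": spec.gains.kp_h, "ki_h": spec.gains.ki_h,
            "kp_theta": spec.gains.kp_theta, "kd_theta": spec.gains.kd_theta,
            "kp_wz": spec.gains.kp_wz, "ki_wz": spec.gains.ki_wz,
        },
        "trials": trials_meta,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, raw in enumerate(raws):
            raw.to_frame().to_csv(outdir / f"trial_{i:03d}.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return raws, falls, truth


def _passive_fall(config: SimConfig, onset: float, horizon: float) -> FallTrajectory:
    """A trial whose wingbeats engage but produce no force: pure ballistic
    drop with the passive pitch dynamics, ending at the floor."""
    from .simulate import _passive_pitch_table

    ts, g = config.ts, config.g
    n = int(round(horizon / ts)) + 1
    t = np.arange(n) * ts
    z = config.box_height - 0.5 * g * t**2
    hit = np.nonzero(z <= 0.0)[0]
    k_end = int(hit[0]) if hit.size else n - 1
    n_keep = k_end + 1
    n_pass = max(512, 1 << n_keep.bit_length())
    theta, rate = _passive_pitch_table(ts, n_pass)
    t = t[:n_keep]
    z = z[:n_keep]
    vz = -g * t
    theta = theta[:n_keep].copy()
    rate = rate[:n_keep].copy()
    zero = np.zeros(n_keep)
    mag = np.abs(vz) / config.d_wall
    ang = np.where(vz < 0, -math.pi / 2, 0.0) - theta + math.pi
    wx = np.where(vz < 0, mag * np.cos(ang), 0.0)
    wz = np.where(vz < 0, mag * np.sin(ang), 0.0)
    return FallTrajectory(
        t=t, x=zero.copy(), z=z, vx=zero.copy(), vz=vz,
        theta_p=theta, theta_p_dot=rate, f_mag=zero.copy(), lift=zero.copy(),
        thrust=zero.copy(), omega_x=wx, omega_z=wz,
        onset_time=onset, variant="passive",
        crashed=bool(hit.size), crash_time=float(t[k_end]) if hit.size else None,
    )
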