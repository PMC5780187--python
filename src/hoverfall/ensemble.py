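"""Randomized ensembles of simulated falls and their summary statistics.

Reproduces the study's grouping and selection logic: falls are binned by
wingbeat-onset time (75-100, 100-125, 125-150 ms), time series are aligned on
the onset instant before averaging, trials are kept only if the wingbeats
started within 150 ms and the fly reached a positive vertical speed inside
the 300 ms analysis window, and onset-time samples are fitted with normal and
lognormal distributions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ControllerGains, SimConfig
from .simulate import FallTrajectory, simulate_fall

__all__ = [
    "ONSET_GROUPS",
    "EnsembleResult",
    "run_ensemble",
    "onset_group_label",
    "group_mean_series",
    "settling_time",
    "instability_onset",
    "select_trials",
    "fit_onset_distribution",
    "sample_onsets",
]

#: Onset-time bins used for all group-wise averaging, in seconds.
ONSET_GROUPS: tuple[tuple[float, float], ...] = (
    (0.075, 0.100),
    (0.100, 0.125),
    (0.125, 0.150),
)


def onset_group_label(onset: float) -> str | None:
    """Bin label ('75-100ms', ...) for an onset time; None outside all bins.
    Bins are closed on the left, the last closed on both sides."""
    for i, (lo, hi) in enumerate(ONSET_GROUPS):
        last = i == len(ONSET_GROUPS) - 1
        if lo <= onset < hi or (last and onset == hi):
            return f"{int(lo * 1000)}-{int(hi * 1000)}ms"
    return None


def sample_onsets(n: int, rng: np.random.Generator,
                  window: tuple[float, float] = (0.075, 0.150),
                  distribution: str = "uniform") -> np.ndarray:
    """Draw wingbeat-onset times. 'uniform' samples the stated window;
    'lognormal' mimics the measured onset distribution (mean ~103 ms),
    truncated to the window (see synth.generate_onsets for the open form)."""
    from .synth import generate_onsets

    return generate_onsets(n, distribution, rng, window=window)


@dataclass
class EnsembleResult:
    """Trajectories of one ensemble plus the study's summary statistics."""

    trajectories: list[FallTrajectory]
    variant: str
    seed: int
    crash_fraction: float
    settling_times: dict[str, float | None]  # per onset group, s after onset
    group_mean_pitch: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    instability_onsets: list[float | None] = field(default_factory=list)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([tr.onset_time for tr in self.trajectories])

    def median_instability_onset(self) -> float | None:
        vals = [v for v in self.instability_onsets if v is not None]
        return float(np.median(vals)) if vals else None

    def save(self, outdir: str | Path) -> None:
        """Write per-group mean series as CSV and scalar metrics as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, df in self.group_mean_pitch.items():
            df.to_csv(outdir / f"group_mean_{label}.csv", index=False)
        metrics = {
            "variant": self.variant,
            "seed": self.seed,
            "n": len(self.trajectories),
            "crash_fraction": self.crash_fraction,
            "settling_times_s": self.settling_times,
            "median_instability_onset_s": self.median_instability_onset(),
            "instability_onsets_s": self.instability_onsets,
        }
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))


def group_mean_series(trajectories: list[FallTrajectory], ts: float,
                      signals: tuple[str, ...] = ("theta_p",),
                      ) -> dict[str, pd.DataFrame]:
    """Onset-aligned per-group mean time series.

    Each trajectory is re-indexed to time-since-onset; within every onset
    group the series are truncated at the shortest member and averaged sample
    by sample (means need at least two contributors, so singleton groups are
    returned as-is but flagged by an ``n`` column).
    """
    groups: dict[str, list[FallTrajectory]] = {}
    for tr in trajectories:
        label = onset_group_label(tr.onset_time)
        if label is not None:
            groups.setdefault(label, []).append(tr)
    out: dict[str, pd.DataFrame] = {}
    for label, members in groups.items():
        k0s = [int(round(tr.onset_time / ts)) for tr in members]
        n_post = min(len(tr.t) - k0 for tr, k0 in zip(members, k0s))
        if n_post <= 0:
            continue
        data = {"t_since_onset": np.arange(n_post) * ts, "n": len(members)}
        for sig in signals:
            stack = np.stack(
                [getattr(tr, sig)[k0 : k0 + n_post] for tr, k0 in zip(members, k0s)]
            )
            data[sig] = stack.mean(axis=0)
        out[label] = pd.DataFrame(data)
    return out


def settling_time(pitch: np.ndarray, ts: float, onset: float,
                  band: float = 0.1, t0: float = 0.0,
                  min_dwell: float = 0.05) -> float | None:
    """First time after ``onset`` from which the pitch stays within ``band``
    (rad) of its final value for the rest of the series; None if it never
    does.  ``t0`` is the time of the first sample.

    The trailing in-band stretch must last at least ``min_dwell`` seconds —
    the last sample alone is always within the band of itself, which would
    make every oscillating series 'settle' at its final instant.
    """
    pitch = np.asarray(pitch, dtype=float)
    final = pitch[-1]
    outside = np.abs(pitch - final) > band
    k_onset = max(int(math.ceil((onset - t0) / ts - 1e-9)), 0)
    # last sample outside the band determines the entry point
    out_idx = np.nonzero(outside)[0]
    k_entry = 0 if out_idx.size == 0 else int(out_idx[-1]) + 1
    if (len(pitch) - k_entry) * ts < min_dwell:
        return None
    k_entry = max(k_entry, k_onset)
    return (k_entry * ts + t0) - onset


def instability_onset(traj: FallTrajectory, setpoint: float = 0.04,
                      error_factor: float = 10.0) -> float | None:
    """Time (from fall start) at which the basic model's divergence becomes
    detectable: the first sample where |pitch| exceeds pi/2 or the forward-OF
    error exceeds ``error_factor`` times its value at wingbeat onset."""
    if len(traj.t) < 2 or len(traj.omega_x) == 0:
        raise ValueError("instability detection needs a fully recorded trajectory")
    ts = float(traj.t[1] - traj.t[0])
    k0 = int(round(traj.onset_time / ts))
    e0 = abs(setpoint - traj.omega_x[k0])
    pitch_bad = np.abs(traj.theta_p) > math.pi / 2
    err_bad = np.abs(setpoint - traj.omega_x) > error_factor * max(e0, 1e-12)
    bad = np.nonzero((pitch_bad | err_bad) & (np.arange(len(traj.t)) >= k0))[0]
    if bad.size == 0:
        # a run halted by the divergence guard is unstable by construction
        return traj.diverge_time
    return float(traj.t[bad[0]])


def select_trials(trajectories: list[FallTrajectory],
                  max_onset: float = 0.150,
                  window: float = 0.300) -> list[FallTrajectory]:
    """Apply the study's trial-selection filter.

    Keeps trajectories whose wingbeats started before ``max_onset`` and that
    reach a positive vertical speed within ``window`` seconds of onset; each
    kept trajectory is truncated at the first positive-vz instant or at the
    window end, whichever comes first.
    """
    kept: list[FallTrajectory] = []
    for tr in trajectories:
        if tr.onset_time >= max_onset:
            continue
        if len(tr.vz) == 0:
            raise ValueError("selection needs recorded vertical speed")
        ts = tr.t[1] - tr.t[0]
        k0 = int(round(tr.onset_time / ts))
        k_max = min(k0 + int(round(window / ts)), len(tr.t) - 1)
        pos = np.nonzero(tr.vz[k0 : k_max + 1] > 0.0)[0]
        if pos.size == 0:
            continue
        k_cut = k0 + int(pos[0])
        kept.append(_truncate(tr, k_cut))
    return kept


def _truncate(tr: FallTrajectory, k: int) -> FallTrajectory:
    arrays = dict(
        t=tr.t[: k + 1], x=tr.x[: k + 1], z=tr.z[: k + 1],
        vx=tr.vx[: k + 1], vz=tr.vz[: k + 1],
        theta_p=tr.theta_p[: k + 1], theta_p_dot=tr.theta_p_dot[: k + 1],
        f_mag=tr.f_mag[: k + 1], lift=tr.lift[: k + 1], thrust=tr.thrust[: k + 1],
        omega_x=tr.omega_x[: k + 1], omega_z=tr.omega_z[: k + 1],
    )
    return FallTrajectory(
        **arrays, onset_time=tr.onset_time, variant=tr.variant,
        crashed=False, crash_time=None, diverged=False, diverge_time=None,
        horizon_censored=False,
    )


def fit_onset_distribution(onsets) -> dict[str, dict[str, float]]:
    """Maximum-likelihood normal and lognormal fits of onset times.

    Returns location/scale parameters and the implied means of both families
    (the measured distribution had nearly equal normal and lognormal means,
    ~103 ms).  Lognormal fitting requires strictly positive samples.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 5:
        raise ValueError("need at least 5 onset samples to fit")
    mu, sd = float(np.mean(onsets)), float(np.std(onsets))
    tiny = 1e-12 * max(1.0, abs(mu))
    normal = {"mean": mu, "sd": sd, "implied_mean": mu, "degenerate": sd < tiny}
    if np.any(onsets <= 0):
        raise ValueError("lognormal fit requires positive onsets")
    log = np.log(onsets)
    lmu, lsd = float(np.mean(log)), float(np.std(log))
    lognormal = {
        "mu_log": lmu,
        "sigma_log": lsd,
        "implied_mean": float(math.exp(lmu + 0.5 * lsd**2)),
        "degenerate": lsd < 1e-12,
    }
    return {"normal": normal, "lognormal": lognormal}


def run_ensemble(
    n: int,
    config: SimConfig,
    gains: ControllerGains,
    variant: str = "basic",
    seed: int | None = None,
    horizon: float | None = None,
    onset_distribution: str = "uniform",
) -> EnsembleResult:
    """Run ``n`` independent simulated falls with randomly drawn onset times
    and compute the group summaries.  Deterministic given the seed: each
    trial's randomness comes from a substream spawned by trial index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    onsets = sample_onsets(n, rng, window=config.onset_window,
                           distribution=onset_distribution)
    onsets = np.sort(onsets)  # order never matters for the summaries
    trajs = [simulate_fall(config, gains, float(o), variant, horizon)
             for o in onsets]
    crash_fraction = float(np.mean([tr.crashed for tr in trajs]))
    means = group_mean_series(trajs, config.ts, signals=("theta_p", "z", "vz", "vx",
                                                         "omega_x", "omega_z"))
    settling = {
        label: settling_time(df["theta_p"].to_numpy(), config.ts, onset=0.0)
        for label, df in means.items()
    }
    instab = [instability_onset(tr, gains.omega_x_setpoint) for tr in trajs]
    return EnsembleResult(
        trajectories=trajs,
        variant=variant,
        seed=seed,
        crash_fraction=crash_fraction,
        settling_times=settling,
        group_mean_pitch=means,
        instability_onsets=instab,
    )
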