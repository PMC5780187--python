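"""Grid-likelihood identification of the visual PD controller gains.

The study estimated the free gains (KpV, KdV) of the forward-optic-flow PD
controller by simulating a fall for every gain combination on a grid
(KpV in [0, 20], KdV in [0, 2]), scoring each simulation against one recorded
fall, and averaging the per-fall likelihood maps over the selected cohort
(44 falls).  The likelihood objective here is Gaussian iid residuals on the
pitch time series over a 200 ms window after wingbeat onset, with the
residual scale set to the pitch measurement error (sd 0.08 rad ~ 5 deg).

Also provides a least-squares re-fit of the passive-pitch transfer function
structure to averaged pre-onset pitch data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .blocks import PASSIVE_PITCH_DEN, PASSIVE_PITCH_NUM
from .model import ControllerGains, SimConfig
from .simulate import FallTrajectory, simulate_fall

__all__ = [
    "LikelihoodMap",
    "default_grids",
    "trajectory_loglik",
    "mle_grid",
    "fit_passive_tf",
    "PITCH_NOISE_SD",
    "ESTIMATION_WINDOW",
]

#: Pitch measurement error of the stereo reconstruction, rad (~5 degrees).
PITCH_NOISE_SD = 0.08
#: Post-onset window over which simulated and observed pitch are compared, s.
ESTIMATION_WINDOW = 0.200

KP_RANGE = (0.0, 20.0)
KD_RANGE = (0.0, 2.0)


def default_grids(n_kp: int = 41, n_kd: int = 41) -> tuple[np.ndarray, np.ndarray]:
    """Default estimation grids: KpV in [0, 20], KdV in [0, 2]."""
    return np.linspace(*KP_RANGE, n_kp), np.linspace(*KD_RANGE, n_kd)


@dataclass
class LikelihoodMap:
    """Log-likelihood surface over the (KpV, KdV) grid for one fall (or the
    cohort average), with the selected optimum."""

    kp_grid: np.ndarray
    kd_grid: np.ndarray
    loglik: np.ndarray  # shape (len(kp_grid), len(kd_grid))
    argmax: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        if self.loglik.shape != (len(self.kp_grid), len(self.kd_grid)):
            raise ValueError("loglik matrix shape must match the grids")

    @staticmethod
    def _select(kp_grid, kd_grid, loglik) -> tuple[float, float]:
        """Grid point attaining the maximum; ties broken toward the smaller
        KdV then smaller KpV (lowest-complexity controller)."""
        best = None
        best_val = -math.inf
        for j, kd in enumerate(kd_grid):
            for i, kp in enumerate(kp_grid):
                v = loglik[i, j]
                if v > best_val:
                    best_val = v
                    best = (float(kp), float(kd))
        return best

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loglik, index=self.kp_grid, columns=self.kd_grid)
        df.index.name = "KpV"
        df.columns.name = "KdV"
        return df

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def trajectory_loglik(
    observed: FallTrajectory,
    kp_v: float,
    kd_v: float,
    config: SimConfig,
    gains: ControllerGains | None = None,
    noise_sd: float = PITCH_NOISE_SD,
    window: float = ESTIMATION_WINDOW,
    variant: str = "basic",
) -> float:
    """Gaussian log-likelihood of the observed pitch series under the model
    simulated with candidate visual gains.

    The model is run with the observed onset time; residuals are taken on the
    pitch series over ``window`` seconds after onset (or to the end of the
    observation, if shorter).  A simulation that diverges before the window
    ends scores -inf.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    base = gains if gains is not None else ControllerGains()
    onset = observed.onset_time
    ts = config.ts
    k0 = int(round(onset / ts))
    n_window = int(round(window / ts))
    n_obs = min(len(observed.theta_p) - k0 - 1, n_window)
    if n_obs * ts < 0.5 * window:
        raise ValueError(
            f"observed trajectory covers only {n_obs * ts:.3f} s after onset; "
            f"need at least {0.5 * window:.3f} s"
        )
    sim = simulate_fall(
        config, base.with_visual(kp_v, kd_v), onset, variant,
        horizon=onset + (n_obs + 1) * ts, record="pitch",
    )
    if sim.diverged or len(sim.theta_p) < k0 + n_obs + 1:
        return -math.inf
    obs = observed.theta_p[k0 + 1 : k0 + n_obs + 1]
    mod = sim.theta_p[k0 + 1 : k0 + n_obs + 1]
    resid = obs - mod
    return float(
        -0.5 * np.sum(resid**2) / noise_sd**2
        - n_obs * (math.log(noise_sd) + 0.5 * math.log(2 * math.pi))
    )


def mle_grid(
    observed_set: list[FallTrajectory],
    kp_grid: np.ndarray | None = None,
    kd_grid: np.ndarray | None = None,
    config: SimConfig | None = None,
    gains: ControllerGains | None = None,
    noise_sd: float = PITCH_NOISE_SD,
    window: float = ESTIMATION_WINDOW,
    variant: str = "basic",
) -> tuple[list[LikelihoodMap], LikelihoodMap, tuple[float, float]]:
    """Likelihood map per observed fall, their element-wise average, and the
    gains selected at the average map's maximum.

    Returns ``(per_fall_maps, averaged_map, (kp_v, kd_v))``.  The average is
    over maps, as in the original procedure, so each fall contributes equally
    regardless of its length; permutation of the input order cannot change
    the result.
    """
    if not observed_set:
        raise ValueError("observed_set must be non-empty")
    if kp_grid is None or kd_grid is None:
        d_kp, d_kd = default_grids()
        kp_grid = d_kp if kp_grid is None else np.asarray(kp_grid, float)
        kd_grid = d_kd if kd_grid is None else np.asarray(kd_grid, float)
    if len(kp_grid) == 0 or len(kd_grid) == 0:
        raise ValueError("grids must be non-empty")
    config = config if config is not None else SimConfig()
    maps: list[LikelihoodMap] = []
    for idx, obs in enumerate(observed_set):
        ll = np.empty((len(kp_grid), len(kd_grid)))
        for i, kp in enumerate(kp_grid):
            for j, kd in enumerate(kd_grid):
                ll[i, j] = trajectory_loglik(
                    obs, float(kp), float(kd), config, gains=gains,
                    noise_sd=noise_sd, window=window, variant=variant,
                )
        maps.append(
            LikelihoodMap(
                kp_grid=kp_grid, kd_grid=kd_grid, loglik=ll,
                argmax=LikelihoodMap._select(kp_grid, kd_grid, ll),
                source=f"fall_{idx}",
            )
        )
    avg_ll = np.mean([m.loglik for m in maps], axis=0)
    averaged = LikelihoodMap(
        kp_grid=kp_grid, kd_grid=kd_grid, loglik=avg_ll,
        argmax=LikelihoodMap._select(kp_grid, kd_grid, avg_ll),
        source="average",
    )
    return maps, averaged, averaged.argmax


def fit_passive_tf(
    mean_preonset_pitch: np.ndarray,
    ts: float = 1.0 / 1600.0,
    x0: np.ndarray | None = None,
) -> dict:
    """Least-squares re-fit of the passive-pitch transfer-function structure
    to an averaged pre-onset pitch series.

    The structure is ``(b2*s^2 + b1*s) / (s^2 * (a3*s^3 + a2*s^2 + a1*s + 1))``
    driven by a -pi/2 step; the five free coefficients are fitted to the
    series by trust-region least squares, initialised at the canonical
    coefficients.  Returns the coefficients, the RMS residual (rad) and a
    degeneracy flag (raised for an essentially flat input, where the surface
    has no usable minimum).
    """
    y = np.asarray(mean_preonset_pitch, dtype=float)
    if y.size < 16:
        raise ValueError("series too short to constrain a fifth-order fit")
    u = np.full(y.size, -math.pi / 2.0)
    degenerate = float(np.max(np.abs(y))) < 1e-9

    def response(p):
        b2, b1, a3, a2, a1 = p
        num = (b2, b1, 0.0)
        den = (a3, a2, a1, 1.0, 0.0, 0.0)
        try:
            b, a = signal.bilinear(num, den, fs=1.0 / ts)
        except (ValueError, np.linalg.LinAlgError):
            return np.full(y.size, 1e6)
        sim = signal.lfilter(b, a, u)
        return np.concatenate([[0.0], sim])[: y.size]

    if x0 is None:
        x0 = np.array([PASSIVE_PITCH_NUM[0], PASSIVE_PITCH_NUM[1],
                       PASSIVE_PITCH_DEN[0], PASSIVE_PITCH_DEN[1],
                       PASSIVE_PITCH_DEN[2]])
    sol = optimize.least_squares(lambda p: response(p) - y, x0, method="lm")
    rms = float(np.sqrt(np.mean((response(sol.x) - y) ** 2)))
    return {
        "coefficients": {
            "b2": float(sol.x[0]), "b1": float(sol.x[1]),
            "a3": float(sol.x[2]), "a2": float(sol.x[3]), "a1": float(sol.x[4]),
        },
        "rms_residual": rms,
        "degenerate": degenerate,
        "success": bool(sol.success) and not degenerate,
    }
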