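"""End-to-end identification pipeline on synthetic cohorts.

Chains the generator, trial selection, landmark-level pitch measurement and
the grid-likelihood estimator — the same sequence the study applied to its
recordings, with generated data standing in for them.
"""

from __future__ import annotations

import numpy as np

from .ensemble import select_trials
from .estimate import LikelihoodMap, mle_grid
from .metrics import body_axis_pitch
from .model import ControllerGains, SimConfig
from .simulate import FallTrajectory
from .synth import SynthCohortSpec, generate_cohort

__all__ = ["measure_pitch_from_landmarks", "identify_gains_synthetic"]


def measure_pitch_from_landmarks(raw, n_frames: int) -> np.ndarray:
    """Frame-by-frame body pitch from noisy head/centroid/tail tracks, the
    way the stereo recordings were measured."""
    pitch = np.empty(n_frames)
    for j in range(n_frames):
        _, pitch[j], _ = body_axis_pitch(raw.head[j], raw.centroid[j], raw.tail[j])
    return pitch


def identify_gains_synthetic(
    seed: int,
    config: SimConfig | None = None,
    spec: SynthCohortSpec | None = None,
    grid_n: int = 21,
    variant: str = "basic",
) -> tuple[tuple[float, float], LikelihoodMap, list[FallTrajectory]]:
    """Run the full identification chain on a generated cohort.

    Generates the cohort (57 trials by default, with the study's
    non-recovery rate), applies the onset/positive-climb selection filter,
    measures pitch from the noisy landmarks of each kept trial, and averages
    the per-trial likelihood maps over a ``grid_n x grid_n`` (KpV, KdV) grid.

    Returns ``(selected_gains, averaged_map, observed_trials)``.
    """
    config = config if config is not None else SimConfig()
    if spec is None:
        spec = SynthCohortSpec(variant=variant, gains=ControllerGains(),
                               horizon=0.5, seed=seed)
    raws, falls, _ = generate_cohort(spec, config)
    kept = select_trials(falls)
    if not kept:
        raise RuntimeError("trial selection left an empty cohort")
    observed = []
    for sel in kept:
        idx = next(i for i, f in enumerate(falls)
                   if f.onset_time == sel.onset_time)
        sel.theta_p[:] = measure_pitch_from_landmarks(raws[idx], len(sel.t))
        observed.append(sel)
    kp_grid = np.linspace(0.0, 20.0, grid_n)
    kd_grid = np.linspace(0.0, 2.0, grid_n)
    _, averaged, selected = mle_grid(observed, kp_grid, kd_grid, config,
                                     gains=spec.gains, variant=spec.variant)
    return selected, averaged, observed
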