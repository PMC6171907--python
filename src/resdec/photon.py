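"""Single-photon decision maker with a polarization local reservoir.

A linearly polarized photon at angle ``theta`` from horizontal hits a
polarizing beam splitter; detection at the horizontal port (Decision 1)
occurs with Malus-law probability ``cos^2(theta)``, at the vertical port
(Decision 2) with ``sin^2(theta)``.  After each detection a half waveplate
rotates the polarization by ``delta = pi / R`` toward the winning port
(Decision 1 decreases theta, Decision 2 increases it), so repeated
detections at the same port become more likely — choice-based learning.
The resolution ``R`` plays the role of the reservoir size: large ``R``
means small updates and near-fair decisions.

When an update would take the angle strictly outside ``[0, pi/2]`` the run
terminates: the waveplate is pinned at the boundary it crossed and no
further decisions are made.  Boundary angles themselves (0 or pi/2) remain
active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhotonConfig",
    "PhotonState",
    "detection_probability",
    "step_decision",
    "run_photon_trace",
    "photon_ensemble",
    "photon_consistency_curve",
    "photon_active_portion",
    "mean_photon_active_portion",
]

_HALF_PI = np.pi / 2
_QUARTER_PI = np.pi / 4


@dataclass(frozen=True)
class PhotonConfig:
    """Waveplate resolution ``R`` (update step ``pi/R``), run length, seed."""

    resolution: int
    n_decisions: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.resolution, (int, np.integer)) or self.resolution < 4:
            raise ValueError(f"resolution must be an integer >= 4, got {self.resolution!r}")
        if self.n_decisions < 1:
            raise ValueError("n_decisions must be >= 1")

    @property
    def delta(self) -> float:
        return np.pi / self.resolution


@dataclass
class PhotonState:
    """Polarization angle, activity flag and the decisions made so far."""

    theta: float = _QUARTER_PI
    active: bool = True
    decisions: list[int] = field(default_factory=list)


def detection_probability(theta: float) -> float:
    """Malus law: probability of Decision 1 (horizontal port) at angle ``theta``."""
    if not 0.0 <= theta <= _HALF_PI + 1e-12:
        raise ValueError(f"theta must lie in [0, pi/2], got {theta!r}")
    return float(np.cos(theta) ** 2)


def step_decision(
    state: PhotonState, config: PhotonConfig, rng: np.random.Generator
) -> PhotonState:
    """Detect one photon and rotate the waveplate toward the winning port.

    Mutates ``state`` in place.  If the rotated angle leaves ``[0, pi/2]``
    the state is pinned at that boundary and deactivated.
    """
    if not state.active:
        raise RuntimeError("cannot step a terminated photon decision maker")
    p1 = detection_probability(state.theta)
    decision = 1 if rng.random() < p1 else 2
    state.decisions.append(decision)
    state.theta += -config.delta if decision == 1 else config.delta
    if state.theta < 0.0 or state.theta > _HALF_PI:
        state.theta = float(np.clip(state.theta, 0.0, _HALF_PI))
        state.active = False
    return state


def run_photon_trace(config: PhotonConfig) -> np.ndarray:
    """Decisions (1/2) of one run from ``theta = pi/4``; length <= n_decisions."""
    rng = np.random.default_rng(config.seed)
    state = PhotonState()
    for _ in range(config.n_decisions):
        if not state.active:
            break
        step_decision(state, config, rng)
    return np.asarray(state.decisions, dtype=np.int8)


def photon_active_portion(state: PhotonState) -> float:
    """Normalized waveplate rotation away from pi/4: ``|theta - pi/4| / (pi/4)``."""
    return float(abs(state.theta - _QUARTER_PI) / _QUARTER_PI)


def photon_ensemble(
    config: PhotonConfig, n_runs: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simulation of ``n_runs`` independent photon runs.

    Returns ``(decisions, theta)``: ``decisions`` is int8 of shape
    ``(n_runs, n_decisions)`` with 0 marking cycles after termination;
    ``theta`` holds the final (clamped) angles.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    delta = config.delta
    theta = np.full(n_runs, _QUARTER_PI)
    active = np.ones(n_runs, dtype=bool)
    decisions = np.zeros((n_runs, config.n_decisions), dtype=np.int8)
    for t in range(config.n_decisions):
        if not active.any():
            break
        u = rng.random(n_runs)
        d1 = u < np.cos(theta) ** 2
        step = np.where(d1, -delta, delta)
        decisions[active, t] = np.where(d1[active], 1, 2)
        theta[active] += step[active]
        out = active & ((theta < 0.0) | (theta > _HALF_PI))
        np.clip(theta, 0.0, _HALF_PI, out=theta)
        active &= ~out
    return decisions, theta


def photon_consistency_curve(
    resolutions,
    n_decisions: int = 500,
    n_runs: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean consistency with the initial decision, per cycle and resolution.

    The indicator at cycle ``t >= 1`` is 1 when the decision equals the run's
    initial decision; terminated runs contribute no indicator and are
    tallied in ``surviving_runs``.  Columns: ``resolution, cycle,
    mean_consistency, surviving_runs``.
    """
    frames = []
    for idx, r in enumerate(resolutions):
        cfg = PhotonConfig(resolution=int(r), n_decisions=n_decisions)
        dec, _ = photon_ensemble(cfg, n_runs, seed=np.random.SeedSequence([seed, idx]))
        first = dec[:, 0][:, None]
        alive = dec != 0
        match = (dec == first) & alive
        surviving = alive.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(surviving > 0, match.sum(axis=0) / np.maximum(surviving, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "resolution": int(r),
                    "cycle": np.arange(1, n_decisions),
                    "mean_consistency": mean[1:],
                    "surviving_runs": surviving[1:],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def mean_photon_active_portion(
    resolution: int, cycle: int, n_runs: int = 10_000, seed: int = 0
) -> float:
    """Mean normalized rotation after ``cycle`` decisions, over all runs.

    Terminated runs are pinned at a boundary and therefore count as fully
    rotated (active portion 1).
    """
    cfg = PhotonConfig(resolution=resolution, n_decisions=cycle)
    _, theta = photon_ensemble(cfg, n_runs, seed=seed)
    return float(np.mean(np.abs(theta - _QUARTER_PI) / _QUARTER_PI))
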