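"""Repetition-consistency scoring of paired-preference choice data.

The protocol emulated here presents two items (e.g. professions) per trial
and asks which the participant prefers.  Pairs are drawn at random under the
constraint that every one of ``M`` items appears exactly ``K`` times over
``M*K/2`` trials (the reference protocol uses 28 items, 8 repetitions, 112
trials).  For each item its k-th appearance yields a chosen / not-chosen
indicator; the repetition consistency ``c_k`` is the fraction of items whose
indicator at appearance ``k`` equals the one at appearance ``k+1``.

The reported learning score is ``max(c_2..c_{K-1}) - c_1 + 0.5``: the
initial consistency is subtracted from the best later consistency, and the
0.5 no-learning reference of the local reservoir model is added back, so
0.5 means no learning and values toward 1 mean strong choice-based
learning.  Observed scores are mapped onto a reservoir size by inverting
the model curve of consistency-at-lag-8 versus N (lifetime 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reservoir import ReservoirConfig, decision_consistency_curve

__all__ = [
    "ChoiceSchedule",
    "ChoiceRecord",
    "LearningScore",
    "ReservoirEstimate",
    "build_schedule",
    "repetition_consistency",
    "learning_score",
    "simulate_participant",
    "model_curve_vs_n",
    "estimate_reservoir_size",
    "read_choice_record",
    "write_choice_record",
]


@dataclass(frozen=True)
class ChoiceSchedule:
    """Trial sequence in which every item appears exactly ``reps`` times."""

    n_items: int
    reps: int
    trials: tuple[tuple[object, object], ...]  # (item_a, item_b) per trial

    def __post_init__(self) -> None:
        counts: dict[object, int] = {}
        for a, b in self.trials:
            if a == b:
                raise ValueError(f"self-paired trial {a!r}")
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        if len(counts) != self.n_items or any(c != self.reps for c in counts.values()):
            raise ValueError("every item must appear exactly `reps` times")


@dataclass(frozen=True)
class ChoiceRecord:
    """A schedule plus the item chosen on each trial."""

    schedule: ChoiceSchedule
    chosen: tuple[object, ...]

    def __post_init__(self) -> None:
        if len(self.chosen) != len(self.schedule.trials):
            raise ValueError("one choice per trial required")
        for (a, b), ch in zip(self.schedule.trials, self.chosen):
            if ch not in (a, b):
                raise ValueError(f"chosen item {ch!r} not in pair ({a!r}, {b!r})")


@dataclass(frozen=True)
class LearningScore:
    """Reported learning score with its components."""

    initial: float  # c_1
    max_rest: float  # max over c_2..c_{K-1}
    reported: float  # max_rest - initial + 0.5


@dataclass(frozen=True)
class ReservoirEstimate:
    """Reservoir size inverted from an observed consistency.

    ``status`` is ``"in-range"`` when the observation falls inside the model
    curve, ``"at-boundary"`` when it is at or below the 0.5 no-learning floor
    (any reservoir at least as large as the largest grid size fits), and
    ``"above-curve"`` when it exceeds the curve maximum (a longer lifetime
    than the curve assumes would be needed).
    """

    n_hat: float
    status: str
    curve: pd.Series


def build_schedule(n_items: int, reps: int, seed=0, max_tries: int = 10_000) -> ChoiceSchedule:
    """Random pairing of item appearances with no self-pairs.

    The multiset of ``n_items * reps`` appearance slots is shuffled and
    paired off; shuffles producing a self-pair are rejected and retried.
    Deterministic under ``seed``.
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if (n_items * reps) % 2:
        raise ValueError("n_items * reps must be even to pair all appearances")
    rng = np.random.default_rng(seed)
    slots = np.repeat(np.arange(n_items), reps)
    for _ in range(max_tries):
        rng.shuffle(slots)
        pairs = slots.reshape(-1, 2)
        if (pairs[:, 0] != pairs[:, 1]).all():
            trials = tuple((int(a), int(b)) for a, b in pairs)
            return ChoiceSchedule(n_items=n_items, reps=reps, trials=trials)
    raise RuntimeError(
        f"no self-pair-free pairing found in {max_tries} shuffles; "
        "the requested schedule may be infeasible"
    )


def _appearance_indicators(record: ChoiceRecord) -> dict[object, list[int]]:
    """Per item, the chosen(1)/not-chosen(0) indicator at each appearance, in trial order."""
    ind: dict[object, list[int]] = {}
    for (a, b), ch in zip(record.schedule.trials, record.chosen):
        ind.setdefault(a, []).append(int(ch == a))
        ind.setdefault(b, []).append(int(ch == b))
    return ind


def repetition_consistency(record: ChoiceRecord) -> np.ndarray:
    """``c_k`` for adjacent appearance pairs ``k = 1..K-1``.

    ``c_k`` is the fraction of items whose chosen/not-chosen indicator at
    their k-th appearance equals the indicator at their (k+1)-th appearance.
    """
    reps = record.schedule.reps
    ind = _appearance_indicators(record)
    for item, vals in ind.items():
        if len(vals) != reps:
            raise ValueError(f"item {item!r} has {len(vals)} appearances, expected {reps}")
    mat = np.array([ind[item] for item in ind], dtype=np.int8)  # (M, K)
    return (mat[:, :-1] == mat[:, 1:]).mean(axis=0)


def learning_score(consistencies: Sequence[float]) -> LearningScore:
    """``max(c_2..c_{K-1}) - c_1 + 0.5`` from the K-1 repetition consistencies."""
    c = np.asarray(consistencies, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two repetition consistencies (K >= 3)")
    initial = float(c[0])
    max_rest = float(c[1:].max())
    return LearningScore(initial=initial, max_rest=max_rest, reported=max_rest - initial + 0.5)


def simulate_participant(
    n_items: int = 28,
    reps: int = 8,
    stickiness: float = 0.5,
    seed=0,
    value_scale: float = 1.0,
    noise_scale: float = 1.0,
    reinforcement_rate: float = 0.25,
) -> ChoiceRecord:
    """Synthetic participant with choice-induced preference change.

    Each item carries a latent value ``~ Normal(0, value_scale)``; on each
    trial the item with the larger ``value + Normal(0, noise_scale)``
    perturbation is chosen.  Choosing reinforces: the chosen item's value
    grows by ``stickiness * reinforcement_rate * k`` and the rejected item's
    shrinks by the same rule, where ``k`` counts the item's previous
    appearances.  Habit strength therefore builds over repetitions, so the
    consistency of late appearance pairs rises above the initial one — the
    learning signature the reported score measures — at a rate governed by
    ``stickiness``.  ``stickiness=0`` with ``value_scale=0`` gives
    independent coin-flip choices.
    """
    if not 0.0 <= stickiness <= 1.0:
        raise ValueError("stickiness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    schedule = build_schedule(n_items, reps, seed=rng)
    values = rng.normal(0.0, value_scale, size=n_items) if value_scale > 0 else np.zeros(n_items)
    appearances = np.zeros(n_items)
    chosen = []
    for a, b in schedule.trials:
        noise = rng.normal(0.0, noise_scale, size=2) if noise_scale > 0 else np.zeros(2)
        if values[a] + noise[0] >= values[b] + noise[1]:
            pick, reject = a, b
        else:
            pick, reject = b, a
        chosen.append(pick)
        values[pick] += stickiness * reinforcement_rate * appearances[pick]
        values[reject] -= stickiness * reinforcement_rate * appearances[reject]
        appearances[a] += 1
        appearances[b] += 1
    return ChoiceRecord(schedule=schedule, chosen=tuple(chosen))


def model_curve_vs_n(
    n_values: Sequence[int] = (2, 5, 10, 20, 50),
    lifetime: int = 10,
    lag: int = 8,
    t0: int = 2000,
    n_runs: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """Model consistency at ``t0`` vs ``t0 + lag`` as a function of reservoir size.

    Reuses the stochastic reservoir simulator (lifetime 10 and lag 8 emulate
    eight repetitions of an item under the reference protocol).  Returns a
    Series indexed by N.
    """
    out = {}
    for idx, n in enumerate(n_values):
        cfg = ReservoirConfig(n_levels=int(n), lifetime=lifetime)
        curve = decision_consistency_curve(
            cfg, t0=t0, lags=[lag], n_runs=n_runs, seed=np.random.SeedSequence([seed, idx])
        )
        out[int(n)] = float(curve.mean_consistency[0])
    return pd.Series(out, name="consistency").sort_index()


def estimate_reservoir_size(
    observed: float, curve: pd.Series | Mapping[int, float]
) -> ReservoirEstimate:
    """Invert the (non-increasing) model curve at an observed consistency.

    Piecewise-linear interpolation between grid sizes.  Observations at or
    below the 0.5 no-learning floor (or below the curve minimum) map to the
    largest grid size with status ``at-boundary``; observations above the
    curve maximum map to the smallest grid size with status ``above-curve``.
    """
    curve = pd.Series(dict(curve)).sort_index().astype(float)
    if curve.empty:
        raise ValueError("curve must contain at least one (N, consistency) point")
    ns = curve.index.to_numpy(dtype=float)
    vals = curve.to_numpy()
    if observed > vals.max():
        return ReservoirEstimate(n_hat=float(ns[int(np.argmax(vals))]), status="above-curve", curve=curve)
    if observed <= 0.5 or observed <= float(vals.min()):
        return ReservoirEstimate(n_hat=float(ns.max()), status="at-boundary", curve=curve)
    # enforce non-increasing values before inverting (Monte-Carlo jitter)
    dec_vals = np.minimum.accumulate(vals)
    n_hat = float(np.interp(observed, dec_vals[::-1], ns[::-1]))
    return ReservoirEstimate(n_hat=n_hat, status="in-range", curve=curve)


# ---------------------------------------------------------------------------
# tabular IO


def write_choice_record(record: ChoiceRecord, path: str | Path) -> None:
    """Write a record as CSV with columns ``trial,item_a,item_b,chosen``."""
    df = pd.DataFrame(
        {
            "trial": np.arange(len(record.chosen)),
            "item_a": [a for a, _ in record.schedule.trials],
            "item_b": [b for _, b in record.schedule.trials],
            "chosen": list(record.chosen),
        }
    )
    df.to_csv(path, index=False)


def read_choice_record(path: str | Path) -> ChoiceRecord:
    """Read a ``trial,item_a,item_b,chosen`` CSV; reps inferred from counts."""
    df = pd.read_csv(path).sort_values("trial")
    required = {"trial", "item_a", "item_b", "chosen"}
    if not required.issubset(df.columns):
        raise ValueError(f"choice record needs columns {sorted(required)}")
    trials = tuple(zip(df["item_a"].tolist(), df["item_b"].tolist()))
    counts = pd.concat([df["item_a"], df["item_b"]]).value_counts()
    reps = int(counts.iloc[0])
    if (counts != reps).any():
        raise ValueError("every item must appear the same number of times")
    schedule = ChoiceSchedule(n_items=len(counts), reps=reps, trials=trials)
    return ChoiceRecord(schedule=schedule, chosen=tuple(df["chosen"].tolist()))
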