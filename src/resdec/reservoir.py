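"""Discrete-cycle stochastic simulation of the local reservoir.

The local reservoir is a ladder of ``N`` lower energy levels and ``N + 1``
upper energy levels with single-occupancy (fermionic) constraints.  A decision
cycle excites one occupied lower level into a vacant upper level:

* L-arrow ``i`` (Decision L): lower level ``i`` -> upper level ``i + 1``
  (rightward excitation),
* R-arrow ``i`` (Decision R): lower level ``i`` -> upper level ``i``.

Executing an arrow empties its lower level and fills its upper level; both
recover after ``lifetime`` cycles (the vacant lower level refills, the
occupied upper level empties into the reservoir-of-the-reservoir).  While a
level is unavailable up to three arrows are disabled, which biases subsequent
excitations toward the side of the previous decision — the mechanism behind
choice-based learning (CBL).

Clock semantics
---------------
One global cycle counter.  At the start of each cycle every recovery that has
come due fires, *then* one arrow is drawn uniformly at random from the
available set and executed.  A cycle whose available-arrow set is empty
records no decision.  With ``lifetime=1`` every consumed resource recovers
before the next cycle, so the full arrow set is always available and
decisions are i.i.d. fair coin flips.

Recovery law
------------
``recovery="fixed"`` (default): a resource consumed at cycle ``c`` recovers
at exactly ``c + lifetime``.  This literal reading makes the recovery clock
rigid: when ``N`` is comparable to the lifetime the reservoir locks into
near-periodic burst dynamics whose memory persists at lags that are
multiples of the lifetime.  ``recovery="memoryless"``: each pending resource
recovers independently with probability ``1/lifetime`` per cycle (mean delay
= lifetime), the discrete-time analog of the continuous rate model in
:mod:`resdec.rate_model`; it removes the periodic locking at the price of
weaker short-lag persistence.  Both laws coincide for ``lifetime=1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DECISION_L",
    "DECISION_R",
    "NO_DECISION",
    "Arrow",
    "ReservoirConfig",
    "ReservoirState",
    "DecisionTrace",
    "ConsistencyCurve",
    "init_state",
    "available_arrows",
    "step_cycle",
    "run_trace",
    "simulate_ensemble",
    "decision_consistency_curve",
    "max_decision_consistency",
    "active_portion",
    "mean_active_portion",
    "random_walk_path",
]

#: Integer codes used in decision traces.  L/R are +/-1 so that a cumulative
#: sum of a trace is directly the random-walk position.
DECISION_L: int = 1
DECISION_R: int = -1
NO_DECISION: int = 0

_NO_TIMER = -1  # sentinel; real timers are always >= 1


class Arrow(NamedTuple):
    """An excitation path in the reservoir.

    ``kind`` is ``"L"`` or ``"R"``; ``index`` is the 1-based lower level the
    excitation starts from.  L-arrow *i* targets upper level *i + 1*,
    R-arrow *i* targets upper level *i*.
    """

    kind: str
    index: int

    @property
    def upper_target(self) -> int:
        return self.index + 1 if self.kind == "L" else self.index


@dataclass(frozen=True)
class ReservoirConfig:
    """Size, recovery lifetime and seed of a local reservoir.

    Parameters
    ----------
    n_levels
        Number of lower energy levels ``N`` (the reservoir size), >= 1.
    lifetime
        Recovery delay in cycles, >= 1.  With ``recovery="fixed"`` a level
        consumed at cycle ``c`` recovers at the start of cycle
        ``c + lifetime``; with ``recovery="memoryless"`` it recovers with
        probability ``1/lifetime`` at the start of each later cycle.
    seed
        Seed for the uniform arrow selection (and recovery draws).
    """

    n_levels: int
    lifetime: int
    seed: int = 0
    recovery: str = "fixed"

    def __post_init__(self) -> None:
        if not isinstance(self.n_levels, (int, np.integer)) or self.n_levels < 1:
            raise ValueError(f"n_levels must be an integer >= 1, got {self.n_levels!r}")
        if not isinstance(self.lifetime, (int, np.integer)) or self.lifetime < 1:
            raise ValueError(f"lifetime must be an integer >= 1, got {self.lifetime!r}")
        if self.recovery not in ("fixed", "memoryless"):
            raise ValueError(f"recovery must be 'fixed' or 'memoryless', got {self.recovery!r}")


@dataclass
class ReservoirState:
    """Mutable occupancies and recovery timers of the 2N+1 levels.

    Timer arrays hold the cycle at which the recovery fires, or -1 when no
    timer is pending.  A refill timer exists iff the lower level is vacant; a
    clear timer exists iff the upper level is occupied.
    """

    config: ReservoirConfig
    cycle: int
    lower_occupied: np.ndarray  # bool, shape (N,)
    upper_occupied: np.ndarray  # bool, shape (N+1,)
    lower_refill_cycle: np.ndarray  # int, shape (N,)
    upper_clear_cycle: np.ndarray  # int, shape (N+1,)


@dataclass(frozen=True)
class DecisionTrace:
    """Per-cycle decisions of a single run: +1 (L), -1 (R) or 0 (none)."""

    config: ReservoirConfig
    decisions: np.ndarray  # int8, shape (n_cycles,)

    def __len__(self) -> int:
        return len(self.decisions)


@dataclass(frozen=True)
class ConsistencyCurve:
    """Mean decision consistency versus lag after a reference cycle.

    ``mean_consistency[k]`` is the fraction of runs whose decision at the
    first decision-bearing cycle >= ``t0 + lags[k]`` equals the decision at
    the first decision-bearing cycle >= ``t0``.  Runs lacking either decision
    are excluded and tallied in ``n_excluded``.
    """

    t0: int
    lags: np.ndarray  # int, shape (n_lags,)
    mean_consistency: np.ndarray  # float, shape (n_lags,)
    n_runs: int
    n_excluded: np.ndarray  # int, shape (n_lags,)


# ---------------------------------------------------------------------------
# single-run API


def init_state(config: ReservoirConfig) -> ReservoirState:
    """Fresh reservoir: all lower levels occupied, all upper levels vacant."""
    n = config.n_levels
    return ReservoirState(
        config=config,
        cycle=0,
        lower_occupied=np.ones(n, dtype=bool),
        upper_occupied=np.zeros(n + 1, dtype=bool),
        lower_refill_cycle=np.full(n, _NO_TIMER, dtype=np.int64),
        upper_clear_cycle=np.full(n + 1, _NO_TIMER, dtype=np.int64),
    )


def available_arrows(state: ReservoirState) -> list[Arrow]:
    """Arrows whose source lower level is occupied and target upper vacant.

    Returned in canonical order: L1..LN, then R1..RN.  This ordering is the
    one the uniform arrow draw indexes into.
    """
    lo = state.lower_occupied
    up = state.upper_occupied
    arrows = [Arrow("L", i + 1) for i in range(len(lo)) if lo[i] and not up[i + 1]]
    arrows += [Arrow("R", i + 1) for i in range(len(lo)) if lo[i] and not up[i]]
    return arrows


def step_cycle(
    state: ReservoirState, rng: np.random.Generator
) -> tuple[ReservoirState, int]:
    """Advance the reservoir by one cycle, mutating ``state`` in place.

    Recovery timers due at the current cycle fire first; then one available
    arrow (if any) is drawn uniformly and executed.  Returns the (mutated)
    state and the decision code (+1 L, -1 R, 0 none).

    One uniform variate is consumed per cycle whether or not an arrow is
    available, which keeps the stream aligned with :func:`simulate_ensemble`.
    """
    c = state.cycle
    cfg = state.config
    n = cfg.n_levels

    if cfg.recovery == "memoryless":
        p = 1.0 / cfg.lifetime
        fire_lo = (state.lower_refill_cycle >= 0) & (rng.random(n) < p)
        fire_up = (state.upper_clear_cycle >= 0) & (rng.random(n + 1) < p)
    else:
        fire_lo = state.lower_refill_cycle == c
        fire_up = state.upper_clear_cycle == c
    state.lower_occupied[fire_lo] = True
    state.lower_refill_cycle[fire_lo] = _NO_TIMER
    state.upper_occupied[fire_up] = False
    state.upper_clear_cycle[fire_up] = _NO_TIMER

    # fixed recovery schedules an exact cycle; memoryless only marks pending
    due = c + cfg.lifetime if cfg.recovery == "fixed" else c
    arrows = available_arrows(state)
    u = rng.random()
    if arrows:
        k = min(int(u * len(arrows)), len(arrows) - 1)
        arrow = arrows[k]
        i = arrow.index - 1
        j = arrow.upper_target - 1
        state.lower_occupied[i] = False
        state.lower_refill_cycle[i] = due
        state.upper_occupied[j] = True
        state.upper_clear_cycle[j] = due
        decision = DECISION_L if arrow.kind == "L" else DECISION_R
    else:
        decision = NO_DECISION

    state.cycle = c + 1
    return state, decision


def run_trace(config: ReservoirConfig, n_cycles: int) -> DecisionTrace:
    """Simulate a single run of ``n_cycles`` consecutive decision cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(config.seed)
    state = init_state(config)
    decisions = np.empty(n_cycles, dtype=np.int8)
    for c in range(n_cycles):
        _, decisions[c] = step_cycle(state, rng)
    return DecisionTrace(config=config, decisions=decisions)


def active_portion(state: ReservoirState) -> float:
    """Fraction of the 2N arrows currently disabled (used)."""
    n = state.config.n_levels
    return (2 * n - len(available_arrows(state))) / (2 * n)


def random_walk_path(trace: DecisionTrace) -> np.ndarray:
    """Cumulative random-walk position: L steps up, R steps down, stalls hold."""
    return np.cumsum(trace.decisions, dtype=np.int64)


# ---------------------------------------------------------------------------
# vectorized ensemble engine


def simulate_ensemble(
    n_levels: int,
    lifetime: int,
    n_cycles: int,
    n_runs: int,
    seed,
    active_at: int | None = None,
    recovery: str = "fixed",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate ``n_runs`` independent reservoirs in lock-step.

    Vectorizes the per-cycle recovery/selection/execution across runs; run
    ``r`` of the ensemble follows exactly the same dynamics as
    :func:`step_cycle` driven by the ``r``-th lane of the shared uniform
    stream (for ``n_runs=1`` the trace is bit-identical to
    :func:`run_trace` with the same seed).

    Returns
    -------
    decisions : int8 array, shape (n_runs, n_cycles)
        Per-cycle decision codes.
    active : float array of shape (n_runs,), or None
        The active portion (fraction of disabled arrows) measured from the
        arrow set the cycle-``active_at`` decision is drawn from, i.e. after
        that cycle's recovery and before its excitation.
    """
    cfg = ReservoirConfig(n_levels=n_levels, lifetime=lifetime, recovery=recovery)
    n = cfg.n_levels
    rng = np.random.default_rng(seed)
    memoryless = cfg.recovery == "memoryless"
    p_recover = 1.0 / lifetime

    lower = np.ones((n_runs, n), dtype=bool)
    upper = np.zeros((n_runs, n + 1), dtype=bool)
    refill = np.full((n_runs, n), _NO_TIMER, dtype=np.int32)
    clear = np.full((n_runs, n + 1), _NO_TIMER, dtype=np.int32)
    decisions = np.zeros((n_runs, n_cycles), dtype=np.int8)
    avail = np.empty((n_runs, 2 * n), dtype=bool)
    active: np.ndarray | None = None

    for c in range(n_cycles):
        if memoryless:
            fire_lo = (refill >= 0) & (rng.random((n_runs, n)) < p_recover)
            fire_up = (clear >= 0) & (rng.random((n_runs, n + 1)) < p_recover)
        else:
            fire_lo = refill == c
            fire_up = clear == c
        lower |= fire_lo
        refill[fire_lo] = _NO_TIMER
        upper &= ~fire_up
        clear[fire_up] = _NO_TIMER

        np.logical_and(lower, ~upper[:, 1:], out=avail[:, :n])  # L-arrows
        np.logical_and(lower, ~upper[:, :n], out=avail[:, n:])  # R-arrows
        counts = avail.sum(axis=1)
        if active_at == c:
            active = (2 * n - counts) / (2 * n)

        u = rng.random(n_runs)
        k = (u * counts).astype(np.int64)
        np.minimum(k, counts - 1, out=k)  # guard the u ~ 1.0 edge
        cum = np.cumsum(avail, axis=1)
        sel = (cum <= k[:, None]).sum(axis=1)  # index of the (k+1)-th True

        rows = np.nonzero(counts > 0)[0]
        a = sel[rows]
        is_l = a < n
        i = np.where(is_l, a, a - n)
        j = np.where(is_l, i + 1, i)
        due = c if memoryless else c + lifetime
        lower[rows, i] = False
        refill[rows, i] = due
        upper[rows, j] = True
        clear[rows, j] = due
        decisions[rows, c] = np.where(is_l, DECISION_L, DECISION_R)

    return decisions, active


def _next_decision(decisions: np.ndarray) -> np.ndarray:
    """Backward-fill: entry (r, c) = decision at first decision-bearing cycle
    >= c in run r, or 0 if the run makes no further decision."""
    n_cycles = decisions.shape[1]
    rev = decisions[:, ::-1]
    pos = np.where(rev != 0, np.arange(n_cycles, dtype=np.int32)[None, :], -1)
    np.maximum.accumulate(pos, axis=1, out=pos)
    filled = np.take_along_axis(rev, np.maximum(pos, 0), axis=1)
    filled = np.where(pos >= 0, filled, 0)
    return filled[:, ::-1]


def decision_consistency_curve(
    config: ReservoirConfig,
    t0: int = 2000,
    lags: int | Sequence[int] = 100,
    n_runs: int = 10_000,
    n_cycles: int | None = None,
    seed=None,
) -> ConsistencyCurve:
    """Mean consistency between the decision at ``t0`` and at ``t0 + lag``.

    The decision "at cycle c" is read from the first decision-bearing cycle
    >= c.  ``lags`` may be an int (lags ``1..lags``) or an explicit sequence.
    ``n_cycles`` defaults to ``t0 + max(lags) + lifetime + 1`` so that a
    stalled cycle near the end of the window can still resolve; runs with no
    decision in range are excluded per lag and tallied.
    """
    lag_arr = (
        np.arange(1, lags + 1, dtype=np.int64)
        if isinstance(lags, (int, np.integer))
        else np.asarray(list(lags), dtype=np.int64)
    )
    if lag_arr.size == 0 or (lag_arr < 1).any():
        raise ValueError("lags must be integers >= 1")
    max_lag = int(lag_arr.max())
    if n_cycles is None:
        n_cycles = t0 + max_lag + config.lifetime + 1
    if t0 + max_lag > n_cycles:
        raise ValueError("t0 + max(lags) must be <= n_cycles")
    if seed is None:
        seed = config.seed

    decisions, _ = simulate_ensemble(
        config.n_levels, config.lifetime, n_cycles, n_runs, seed, recovery=config.recovery
    )
    nxt = _next_decision(decisions)
    ref = nxt[:, t0]
    mean = np.empty(lag_arr.size, dtype=float)
    excluded = np.empty(lag_arr.size, dtype=np.int64)
    for idx, lag in enumerate(lag_arr):
        later = nxt[:, t0 + lag]
        valid = (ref != 0) & (later != 0)
        excluded[idx] = n_runs - int(valid.sum())
        mean[idx] = float(np.mean(ref[valid] == later[valid])) if valid.any() else np.nan
    return ConsistencyCurve(
        t0=t0, lags=lag_arr, mean_consistency=mean, n_runs=n_runs, n_excluded=excluded
    )


def max_decision_consistency(
    config: ReservoirConfig,
    t0: int = 2000,
    max_lag: int = 50,
    n_runs: int = 10_000,
    seed=None,
) -> float:
    """Maximum of the consistency curve over lags ``1..max_lag``."""
    curve = decision_consistency_curve(
        config, t0=t0, lags=max_lag, n_runs=n_runs, seed=seed
    )
    return float(np.nanmax(curve.mean_consistency))


def mean_active_portion(
    config: ReservoirConfig,
    t0: int = 2000,
    n_runs: int = 10_000,
    seed=None,
) -> float:
    """Mean over runs of the fraction of disabled arrows at cycle ``t0``."""
    if seed is None:
        seed = config.seed
    _, active = simulate_ensemble(
        config.n_levels, config.lifetime, t0 + 1, n_runs, seed, active_at=t0,
        recovery=config.recovery,
    )
    assert active is not None
    return float(active.mean())
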