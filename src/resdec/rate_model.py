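"""Exact continuous-time Markov chain of the local reservoir.

Instead of discrete cycles with an integer lifetime, the reservoir is
described by three rates: ``gamma_in`` (a vacant lower level refills),
``gamma_up`` (per-arrow excitation from an occupied lower level into a
vacant upper level; each such excitation is a Decision L or R), and
``gamma_out`` (an occupied upper level empties).  Micro-states are the
occupation patterns of the ``2N + 1`` levels, so there are ``2**(2N+1)``
states — 8 for ``N=1`` and 32 for ``N=2``.

The generator ``G`` follows the convention ``dp/dt = G p`` with columns
summing to zero.  The steady state solves ``G p = 0`` with ``sum(p) = 1``.

Decision-transition probabilities ``P(L->L)`` etc. are obtained by a
first-passage computation on the embedded jump chain: ``h_L(s)`` is the
probability that, starting from state ``s``, the next UP-labeled transition
is a leftward excitation (IN/OUT events are non-absorbing).  Conditioning on
a steady-state Decision-L event (flux-weighted over UP_L transitions) and
reading off ``h_L`` at the landing state gives ``P(L->L)``; the imbalance
``P(L->L) - P(L->R)`` quantifies choice-based learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "RateParams",
    "MicroState",
    "LabeledTransition",
    "DecisionTransitionProbs",
    "GillespieResult",
    "DIAGRAM_STATE_ORDER",
    "enumerate_states",
    "labeled_transitions",
    "build_generator",
    "steady_state",
    "decision_transition_probs",
    "imbalance",
    "imbalance_closed_form",
    "gillespie_oracle",
]

#: Permutation mapping the conventional 8-state diagram indexing for N=1
#: (1 = empty; 2 = lower; 3 = upper-left; 4 = upper-right; 5 = lower+UL;
#: 6 = lower+UR; 7 = UL+UR; 8 = all three) onto the canonical binary order.
DIAGRAM_STATE_ORDER: tuple[int, ...] = (0, 1, 2, 4, 3, 5, 6, 7)


def _is_number(x) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating))


@dataclass(frozen=True)
class RateParams:
    """The three reservoir rates; all strictly positive.

    Entries may also be sympy symbols, in which case positivity is the
    caller's responsibility (used for symbolic generator construction).
    """

    gamma_in: float
    gamma_up: float
    gamma_out: float

    def __post_init__(self) -> None:
        for name in ("gamma_in", "gamma_up", "gamma_out"):
            v = getattr(self, name)
            if _is_number(v) and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    @property
    def is_numeric(self) -> bool:
        return all(
            _is_number(getattr(self, n))
            for n in ("gamma_in", "gamma_up", "gamma_out")
        )


class MicroState(NamedTuple):
    """Occupation pattern: ``lower[i]`` for levels 1..N, ``upper[j]`` for 1..N+1."""

    lower: tuple[bool, ...]
    upper: tuple[bool, ...]


class LabeledTransition(NamedTuple):
    """One allowed jump ``source -> target`` (canonical state indices).

    ``label`` is ``("IN", i)``, ``("OUT", j)``, ``("UP_L", i)`` or
    ``("UP_R", i)`` with 1-based level indices; UP_L targets upper ``i+1``,
    UP_R targets upper ``i``.
    """

    source: int
    target: int
    label: tuple[str, int]
    rate: object  # float or sympy expression


def enumerate_states(n_levels: int) -> list[MicroState]:
    """All ``2**(2N+1)`` occupation micro-states in canonical binary order.

    The canonical index encodes lower level ``i`` at bit ``i - 1`` and upper
    level ``j`` at bit ``N + j - 1``.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    n = n_levels
    states = []
    for code in range(2 ** (2 * n + 1)):
        lower = tuple(bool((code >> i) & 1) for i in range(n))
        upper = tuple(bool((code >> (n + j)) & 1) for j in range(n + 1))
        states.append(MicroState(lower=lower, upper=upper))
    return states


def _state_code(n: int, lower: Iterable[bool], upper: Iterable[bool]) -> int:
    code = 0
    for i, occ in enumerate(lower):
        code |= int(occ) << i
    for j, occ in enumerate(upper):
        code |= int(occ) << (n + j)
    return code


def labeled_transitions(
    n_levels: int, params: RateParams
) -> list[LabeledTransition]:
    """Every valid jump of the labeled CTMC over all micro-states."""
    n = n_levels
    g_in, g_up, g_out = params.gamma_in, params.gamma_up, params.gamma_out
    out: list[LabeledTransition] = []
    for code, st in enumerate(enumerate_states(n)):
        lower, upper = list(st.lower), list(st.upper)
        for i in range(n):  # IN(i+1): refill a vacant lower level
            if not lower[i]:
                out.append(
                    LabeledTransition(code, code | (1 << i), ("IN", i + 1), g_in)
                )
        for j in range(n + 1):  # OUT(j+1): empty an occupied upper level
            if upper[j]:
                out.append(
                    LabeledTransition(
                        code, code & ~(1 << (n + j)), ("OUT", j + 1), g_out
                    )
                )
        for i in range(n):
            if lower[i]:
                if not upper[i + 1]:  # UP_L(i+1): lower i+1 -> upper i+2
                    tgt = (code & ~(1 << i)) | (1 << (n + i + 1))
                    out.append(LabeledTransition(code, tgt, ("UP_L", i + 1), g_up))
                if not upper[i]:  # UP_R(i+1): lower i+1 -> upper i+1
                    tgt = (code & ~(1 << i)) | (1 << (n + i))
                    out.append(LabeledTransition(code, tgt, ("UP_R", i + 1), g_up))
    return out


def build_generator(
    n_levels: int, params: RateParams, order: str = "canonical"
):
    """Assemble the rate-equation generator from the labeled transitions.

    Returns ``(G, transitions)``.  ``G`` is a dense numpy array for numeric
    params or a sympy Matrix for symbolic ones; entry ``(t, s)`` for
    ``t != s`` is the total rate of ``s -> t`` and the diagonal carries the
    negative column outflow, so every column sums to zero.

    ``order="diagram"`` (N=1 only) permutes rows and columns into the 8-state
    diagram indexing of :data:`DIAGRAM_STATE_ORDER`.
    """
    transitions = labeled_transitions(n_levels, params)
    size = 2 ** (2 * n_levels + 1)
    if params.is_numeric:
        g = np.zeros((size, size), dtype=float)
        for s, t, _, rate in transitions:
            g[t, s] += rate
            g[s, s] -= rate
    else:
        import sympy

        g = sympy.zeros(size, size)
        for s, t, _, rate in transitions:
            g[t, s] += rate
            g[s, s] -= rate

    if order == "diagram":
        if n_levels != 1:
            raise ValueError("order='diagram' is defined only for n_levels=1")
        perm = list(DIAGRAM_STATE_ORDER)
        if params.is_numeric:
            g = g[np.ix_(perm, perm)]
        else:
            g = g[perm, perm]
    elif order != "canonical":
        raise ValueError(f"unknown order {order!r}")
    return g, transitions


def steady_state(generator: np.ndarray) -> np.ndarray:
    """Probability vector ``p`` with ``G p = 0``, ``sum(p) = 1``, ``p >= 0``."""
    g = np.asarray(generator, dtype=float)
    ns = scipy.linalg.null_space(g)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError(
            f"generator null space has dimension {ns.shape[1]}, expected 1"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if (p < -1e-9).any():
        raise np.linalg.LinAlgError("steady state has negative components")
    return np.clip(p, 0.0, None)


@dataclass(frozen=True)
class DecisionTransitionProbs:
    """Steady-state decision-transition probabilities of the labeled CTMC."""

    p_ll: float
    p_lr: float
    p_rl: float
    p_rr: float
    steady: np.ndarray  # canonical-order steady-state vector

    @property
    def imbalance(self) -> float:
        """``P(L->L) - P(L->R)``; positive values indicate CBL."""
        return self.p_ll - self.p_lr


def _first_passage_next_up(
    n_levels: int, params: RateParams, transitions: list[LabeledTransition]
) -> np.ndarray:
    """``h_L[s]``: probability the next UP-labeled jump from state ``s`` is UP_L."""
    size = 2 ** (2 * n_levels + 1)
    rows, cols, vals = [], [], []
    b = np.zeros(size)
    total = np.zeros(size)
    for s, t, (kind, _), rate in transitions:
        total[s] += rate
        if kind == "UP_L":
            b[s] += rate
        elif kind != "UP_R":  # IN/OUT: non-absorbing, continue from target
            rows.append(s)
            cols.append(t)
            vals.append(-rate)
    # every state has positive outflow for positive rates
    rows.extend(range(size))
    cols.extend(range(size))
    vals.extend(total)
    m = scipy.sparse.csc_matrix((vals, (rows, cols)), shape=(size, size))
    if size <= 2048:
        return scipy.linalg.solve(m.toarray(), b)
    return scipy.sparse.linalg.spsolve(m, b)


def decision_transition_probs(
    n_levels: int, params: RateParams
) -> DecisionTransitionProbs:
    """Compute ``P(L->L)``, ``P(L->R)``, ``P(R->L)``, ``P(R->R)`` exactly.

    A decision event is an UP-labeled jump at steady state; the conditional
    law of the *next* decision is read from the embedded-jump-chain
    first-passage probabilities at the landing state, weighted by the
    steady-state flux through each UP transition.
    """
    if not params.is_numeric:
        raise TypeError("decision_transition_probs requires numeric rates")
    g, transitions = build_generator(n_levels, params)
    p = steady_state(g)
    h_l = _first_passage_next_up(n_levels, params, transitions)

    flux_l = flux_r = 0.0
    num_ll = num_rl = 0.0
    for s, t, (kind, _), rate in transitions:
        if kind == "UP_L":
            w = p[s] * rate
            flux_l += w
            num_ll += w * h_l[t]
        elif kind == "UP_R":
            w = p[s] * rate
            flux_r += w
            num_rl += w * h_l[t]
    p_ll = num_ll / flux_l
    p_rl = num_rl / flux_r
    return DecisionTransitionProbs(
        p_ll=float(p_ll),
        p_lr=float(1.0 - p_ll),
        p_rl=float(p_rl),
        p_rr=float(1.0 - p_rl),
        steady=p,
    )


def imbalance(n_levels: int, params: RateParams) -> float:
    """``P(L->L) - P(L->R)`` at steady state; > 0 means CBL."""
    return decision_transition_probs(n_levels, params).imbalance


def imbalance_closed_form(params: RateParams, p) -> float:
    """Closed-form reference expression for the N=1 imbalance.

    Evaluates the reference closed form on a length-8 probability
    vector ``p`` given in the 8-state diagram order (1 = empty, 2 = lower,
    3/4 = upper-left/right, 5/6 = lower plus one upper, 7 = both uppers,
    8 = all).  Returned side by side with the first-passage imbalance for
    reconciliation; the two are *not* asserted equal (see the methods note:
    the printed expression is positive for positive rates while the N=1
    reservoir is anti-persistent).
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (8,):
        raise ValueError("p must be a length-8 vector in diagram order")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must be normalized to 1")
    gi, gu, go = params.gamma_in, params.gamma_up, params.gamma_out
    pref = gi * gu / ((gi + go) * (gu + go))
    a = (gi * go + go * (gu + go)) / (2 * (gi + go) * (gu + go))
    b_num = 2 * (2 * gi + go) * (gu + go) * go**2 + gi * go * (gi + go) ** 2
    b_den = 2 * (gi + 2 * go) * (gi + go) ** 2 * (gu + go)
    c = go / (2 * (gu + go))
    return float(
        pref
        * (
            0.5 * (p[0] + p[1])
            + a * (p[2] + p[3])
            + (b_num / b_den) * p[6]
            + c * (p[4] + p[5] + p[7])
        )
    )


@dataclass(frozen=True)
class GillespieResult:
    """Monte-Carlo estimates from an exact stochastic simulation."""

    occupation: np.ndarray  # time-weighted state occupation, canonical order
    p_ll: float
    p_rr: float
    n_l: int  # L decisions followed by another decision
    n_r: int
    n_events: int

    @property
    def imbalance(self) -> float:
        return 2.0 * self.p_ll - 1.0

    def se_p_ll(self) -> float:
        """Binomial standard error of the ``p_ll`` estimate."""
        return float(np.sqrt(self.p_ll * (1 - self.p_ll) / max(self.n_l, 1)))


def gillespie_oracle(
    n_levels: int,
    params: RateParams,
    horizon: float,
    seed,
    burn_in: float = 0.1,
) -> GillespieResult:
    """Exact stochastic simulation (Gillespie) of the labeled CTMC.

    Samples exponential waiting times and jumps proportional to rates,
    starting from the all-lower-occupied state.  Records time-weighted state
    occupation and the sequence of UP-labeled events (decisions); statistics
    ignore the first ``burn_in`` fraction of the horizon.
    """
    if not params.is_numeric:
        raise TypeError("gillespie_oracle requires numeric rates")
    size = 2 ** (2 * n_levels + 1)
    transitions = labeled_transitions(n_levels, params)
    targets: list[np.ndarray] = [np.empty(0, np.int64)] * size
    cum_rates: list[np.ndarray] = [np.empty(0)] * size
    decision_of: list[np.ndarray] = [np.empty(0, np.int8)] * size
    by_state: dict[int, list[LabeledTransition]] = {}
    for tr in transitions:
        by_state.setdefault(tr.source, []).append(tr)
    for s, trs in by_state.items():
        targets[s] = np.array([t.target for t in trs], dtype=np.int64)
        cum_rates[s] = np.cumsum([t.rate for t in trs])
        decision_of[s] = np.array(
            [1 if t.label[0] == "UP_L" else (-1 if t.label[0] == "UP_R" else 0) for t in trs],
            dtype=np.int8,
        )

    rng = np.random.default_rng(seed)
    start = _state_code(n_levels, [True] * n_levels, [False] * (n_levels + 1))
    state = start
    t = 0.0
    t_min = burn_in * horizon
    occupation = np.zeros(size)
    n_ll = n_l = n_rr = n_r = n_events = 0
    prev_decision = 0
    while t < horizon:
        cr = cum_rates[state]
        total = cr[-1]
        dt = rng.exponential(1.0 / total)
        if t >= t_min:
            occupation[state] += min(dt, horizon - t)
        t += dt
        k = int(np.searchsorted(cr, rng.random() * total, side="right"))
        d = decision_of[state][k]
        state = int(targets[state][k])
        if d != 0 and t >= t_min:
            n_events += 1
            if prev_decision == 1:
                n_l += 1
                n_ll += d == 1
            elif prev_decision == -1:
                n_r += 1
                n_rr += d == -1
            prev_decision = d
        elif d != 0:
            prev_decision = d
    occupation /= occupation.sum()
    return GillespieResult(
        occupation=occupation,
        p_ll=n_ll / max(n_l, 1),
        p_rr=n_rr / max(n_r, 1),
        n_l=n_l,
        n_r=n_r,
        n_events=n_events,
    )
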