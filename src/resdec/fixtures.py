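"""Small deterministic fixtures used by the test suite and CLI demos.

All fixtures are synthetic: generated in code, hand-checkable, and written
as plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ChoiceRecord, ChoiceSchedule
from .photon import PhotonConfig, run_photon_trace
from .reservoir import ReservoirConfig, run_trace

__all__ = [
    "toy_choice_record",
    "reservoir_trace_fixture",
    "photon_trace_fixture",
    "generate_fixtures",
]


def toy_choice_record() -> ChoiceRecord:
    """Eight items, two appearances each, eight trials; ``c_1 = 0.75``.

    Round one chooses A, C, E, G; round two repeats every pair and repeats
    each first-round choice except the (E, F) pair, where the choice flips.
    Items E and F are therefore the only inconsistent ones: 6/8 = 0.75.
    (With two appearances per item the number of inconsistent items is
    always even, so 0.75 needs at least eight items.)
    """
    trials = (
        ("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"),
        ("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"),
    )
    chosen = ("A", "C", "E", "G", "A", "C", "F", "G")
    schedule = ChoiceSchedule(n_items=8, reps=2, trials=trials)
    return ChoiceRecord(schedule=schedule, chosen=chosen)


def reservoir_trace_fixture(seed: int = 0) -> pd.DataFrame:
    """N=1, lifetime 3, 10 cycles: the single lower level empties on the
    first excitation, so cycles before its refill bear no decision."""
    trace = run_trace(ReservoirConfig(n_levels=1, lifetime=3, seed=seed), n_cycles=10)
    labels = np.array(["R", "none", "L"])  # index by decision + 1
    return pd.DataFrame(
        {"cycle": np.arange(10), "decision": labels[trace.decisions + 1]}
    )


def photon_trace_fixture(seed: int = 0) -> pd.DataFrame:
    """R=4: the pi/4 update reaches a boundary immediately, so every run
    terminates after exactly two decisions."""
    decisions = run_photon_trace(PhotonConfig(resolution=4, n_decisions=500, seed=seed))
    return pd.DataFrame({"cycle": np.arange(len(decisions)), "decision": decisions})


def generate_fixtures(kind: str, seed: int, out_dir: str | Path) -> Path:
    """Write one named fixture as CSV and return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "choice-record":
        from .behavior import write_choice_record

        path = out_dir / "choice_record.csv"
        write_choice_record(toy_choice_record(), path)
    elif kind == "reservoir-trace":
        path = out_dir / "reservoir_trace.csv"
        reservoir_trace_fixture(seed).to_csv(path, index=False)
    elif kind == "photon-trace":
        path = out_dir / "photon_trace.csv"
        photon_trace_fixture(seed).to_csv(path, index=False)
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected one of "
            "'choice-record', 'reservoir-trace', 'photon-trace'"
        )
    return path
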