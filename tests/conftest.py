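import numpy as np
import pytest

from resdec.behavior import ChoiceRecord, ChoiceSchedule


class FixedUniform:
    """rng stand-in whose ``random()`` returns a preset sequence of uniforms."""

    def __init__(self, *values: float):
        self._values = list(values)

    def random(self, size=None):
        v = self._values.pop(0)
        return np.full(size, v) if size is not None else v


@pytest.fixture
def round_repeating_record():
    """Two rounds of the same four pairings over eight items; choices follow a
    fixed preference order (A > B > ... > H), so every item's chosen/not-chosen
    indicator repeats across rounds."""
    trials = (
        ("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"),
        ("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"),
    )
    chosen = ("A", "C", "E", "G", "A", "C", "E", "G")
    return ChoiceRecord(
        schedule=ChoiceSchedule(n_items=8, reps=2, trials=trials), chosen=chosen
    )
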