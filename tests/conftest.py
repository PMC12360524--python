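"""Shared fixtures: small hand-built trial tables and simulation configs."""

import pandas as pd
import pytest

from encodelearn.trial_data import COLUMNS, TrialTable


def make_trial_frame(rows):
    """Rows of (pid, session, phase, trial, dur_ms, pair, resp, rt_s)."""
    return pd.DataFrame(rows, columns=list(COLUMNS))


@pytest.fixture
def toy_trials():
    """Eight evaluation trials of one participant at one duration.

    4 different pairs (3 answered 'different'), 4 same pairs (1 answered
    'different'): h = 0.75, f = 0.25 with no correction.
    """
    rows = []
    for i, (pair, resp) in enumerate([
        ("different", "different"), ("different", "different"),
        ("different", "different"), ("different", "same"),
        ("same", "different"), ("same", "same"),
        ("same", "same"), ("same", "same"),
    ], start=1):
        rows.append(("p01", 1, "evaluation", i, 117.0, pair, resp, 0.8))
    return TrialTable(make_trial_frame(rows))


@pytest.fixture
def small_config():
    """A scaled-down simulation config for fast end-to-end tests."""
    from encodelearn.synthetic import SimulationConfig

    return SimulationConfig(seed=7, n_participants=6, n_generalization=3,
                            trials_per_duration=20, training_trials=60)
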