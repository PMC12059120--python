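import numpy as np
import pandas as pd
import pytest

from calseq.core import TrialTable
from calseq.simulate import SimConfig, simulate_experiment

#: reduced session composition for fast end-to-end tests
SMALL_SESSIONS = {
    "sound_looming": 6,
    "sound_nonlooming": 6,
    "whisker": 10,
    "pairing": 8,
    "matched": 14,
    "mismatch": 6,
}


def make_trials(rows) -> TrialTable:
    """Build a TrialTable from a list of dicts, filling absent events."""
    defaults = {
        "sound_onset_s": np.nan,
        "sound_offset_s": np.nan,
        "stim_onset_s": np.nan,
        "intensity_pct": 80.0,
        "delay_s": 0.0,
    }
    return TrialTable(pd.DataFrame([{**defaults, **r} for r in rows]))


def whisker_trials(n: int, spacing: float = 12.0, start: float = 10.0):
    """n whisker-only trials: cue 2 s after trial start, stimulus 2 s later."""
    return make_trials(
        [
            {
                "trial_id": i,
                "session": "whisker",
                "trial_type": "whisker_only",
                "cue_onset_s": start + i * spacing + 2.0,
                "stim_onset_s": start + i * spacing + 4.0,
            }
            for i in range(n)
        ]
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One small synthetic block shared by read-only tests."""
    cfg = SimConfig(n_neurons=16, session_sizes=dict(SMALL_SESSIONS))
    rec, trials, truth = simulate_experiment(cfg, 7)
    return cfg, rec, trials, truth
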