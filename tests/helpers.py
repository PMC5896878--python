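"""Shared construction helpers for the test suite."""

import numpy as np
import pandas as pd

from clozerep.epochs import CHANNELS_22, EpochSet


def constant_epochs(value: float, n_trials: int = 3, sfreq: float = 250.0) -> EpochSet:
    """Epochs with every sample equal to ``value`` uV, standard -500..1000 span."""
    n_samples = int(round(1500.0 * sfreq / 1000.0)) + 1
    data = np.full((n_trials, len(CHANNELS_22), n_samples), float(value))
    meta = pd.DataFrame(
        {
            "lab_id": "lab1",
            "subject_id": [f"s{i}" for i in range(n_trials)],
            "item_id": 1,
            "word_type": "article",
            "cloze": 50,
            "grammatical": True,
            "subject_accuracy": 0.95,
            "experiment": "main",
        }
    )
    return EpochSet(data=data, meta=meta, channels=CHANNELS_22, sfreq=sfreq, tmin_ms=-500.0)


def ramp_epochs(sfreq: float = 250.0, n_trials: int = 2) -> EpochSet:
    """Epochs whose voltage equals the time axis in ms: v(t) = t uV."""
    ep = constant_epochs(0.0, n_trials=n_trials, sfreq=sfreq)
    ep.data[:] = ep.times[None, None, :]
    return ep
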