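import warnings

import numpy as np
import pytest

from phonation import (
    RecordingMeta,
    Waveform,
    build_feature_matrix,
    synthesize_cohort,
)
from phonation.synth import CohortConfig, SynthesisParams, synthesize_pulse_train


@pytest.fixture(scope="session")
def clean_train():
    """Unperturbed noiseless 200 Hz pulse train, 0.5 s at 48 kHz."""
    params = SynthesisParams(f0=200.0, duration=0.5, seed=1)
    return synthesize_pulse_train(params)


@pytest.fixture(scope="session")
def small_cohort_dataset():
    """Feature matrix of a reduced cohort (4 CO / 4 PD, /a/+/m/) shared by
    pipeline/stats/classification tests."""
    config = CohortConfig(
        n_controls=4, n_patients=4, phonemes=("a", "m"), duration=5.2, master_seed=7
    )
    recordings = synthesize_cohort(config)
    from phonation.pipeline import ExtractionConfig

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_matrix(
            ((RecordingMeta(r.subject_id, r.group, r.phoneme), r.waveform)
             for r in recordings),
            ExtractionConfig(phonemes=("a", "m")),
        )


def make_tone(freq=200.0, duration=0.5, sr=48000.0, amp=0.5, seed=None):
    t = np.arange(int(round(duration * sr))) / sr
    return Waveform(amp * np.sin(2 * np.pi * freq * t), sr)
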