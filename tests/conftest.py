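import numpy as np
import pandas as pd
import pytest

from dtrlearn.trial_data import ModelSpec, TreatmentCoding, TrialData

BAL = TreatmentCoding(labels=("neg", "pos"), codes=(-1.0, 1.0), allocation=(0.5, 0.5))

SCHEMA = {
    "subject_id": "subject_id",
    "z1": ["Z1"],
    "a1": "A1",
    "z2": ["Z2"],
    "rerandomized": "R",
    "a2": "A2",
    "y": "Y",
}


def make_trial(z1, a1, z2, rr, a2, y) -> TrialData:
    n = len(z1)
    frame = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "Z1": np.asarray(z1, float),
            "A1": np.asarray(a1, float),
            "Z2": np.asarray(z2, float),
            "R": np.asarray(rr, bool),
            "A2": np.asarray(a2, float),
            "Y": np.asarray(y, float),
        }
    )
    return TrialData(frame, SCHEMA, {"a1": BAL, "a2": BAL})


@pytest.fixture
def spec1() -> ModelSpec:
    return ModelSpec(stage=1, main_terms=("Z1",), effect_terms=("Z1",))


@pytest.fixture
def spec2() -> ModelSpec:
    return ModelSpec(stage=2, main_terms=("Z1", "A1", "Z2"), effect_terms=("Z1", "A1", "Z2"))


@pytest.fixture
def noiseless_trial() -> TrialData:
    """Deterministic outcome Y = 1 + 2 Z1 + A2 (3 - Z1); everybody re-randomized."""
    rng = np.random.default_rng(7)
    n = 40
    z1 = rng.normal(0, 1, n)
    a1 = 2.0 * rng.integers(0, 2, n) - 1
    z2 = rng.normal(0, 1, n)
    a2 = 2.0 * rng.integers(0, 2, n) - 1
    y = 1 + 2 * z1 + a2 * (3 - z1)
    return make_trial(z1, a1, z2, np.ones(n, bool), a2, y)
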