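import numpy as np
import pandas as pd
import pytest

from seizurekit import (
    EEGRecord,
    FEATURE_COLUMNS,
    STATE_COLUMN,
    SeizureAnnotation,
    SynthConfig,
    simulate_record,
)


@pytest.fixture
def annotated_record():
    """Synthetic 300-s record with one 100-s seizure and strong bursts."""
    cfg = SynthConfig(
        duration_s=300.0,
        seizure_intervals=((50.0, 150.0),),
        amplitude_factor=3.0,
        seed=7,
    )
    return simulate_record(cfg)


@pytest.fixture
def low_rate_record():
    """Tiny 1 Hz 2-channel record for windowing-geometry tests."""
    rng = np.random.default_rng(0)
    return EEGRecord(
        signal=rng.normal(size=(2, 120)),
        fs=1.0,
        channel_labels=["A", "B"],
        annotations=[SeizureAnnotation(30.0, 60.0)],
        record_id="tiny",
    )


def make_separable_table(n_per_class: int = 20, seed: int = 0) -> pd.DataFrame:
    """Feature table with a large clean gap in STD/Var between classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for state, std_center in (("s", 500.0), ("n", 100.0)):
        for i in range(n_per_class):
            std = rng.normal(std_center, 10.0)
            row = {c: rng.normal(0.0, 1.0) for c in FEATURE_COLUMNS}
            row["STD"] = std
            row["Var"] = std**2
            row[STATE_COLUMN] = state
            row["record_id"] = "toy"
            row["start_s"] = float(i)
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def separable_table():
    return make_separable_table()
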