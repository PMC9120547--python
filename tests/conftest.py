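import numpy as np
import pytest

from mstbp.preprocess import build_segments
from mstbp.synthetic import PhysioParams, generate_record, make_dataset


@pytest.fixture(scope="session")
def clean_record():
    """8-s noise-free record at 75 bpm, 120/80 mmHg, with annotations."""
    return generate_record(PhysioParams(duration=8.0, heart_rate=75.0))


@pytest.fixture(scope="session")
def long_record():
    """80-s noise-free record with constant 120/80 beats."""
    n = int(80 * 75 / 60)
    params = PhysioParams(
        duration=80.0,
        heart_rate=75.0,
        sbp_series=np.full(n, 120.0),
        dbp_series=np.full(n, 80.0),
    )
    return generate_record(params)


@pytest.fixture(scope="session")
def segments32():
    """32 preprocessed training segments from the synthetic generator."""
    segs = []
    for rec, _ann in make_dataset(11, seed=42):
        segs += build_segments(rec)
    assert len(segs) >= 32
    return segs[:32]
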