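import numpy as np
import pandas as pd
import pytest

from fingerqc.io_model import FingerprintMatrix, Peak, PeakTable
from fingerqc.synthetic import default_spec, generate_fingerprints


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_tables():
    """Three batches sharing five peaks at identical retention times."""
    rts = [5.0, 10.0, 15.0, 20.0, 25.0]
    tables = []
    for b, mult in zip("ABC", (1.0, 2.0, 3.0)):
        peaks = [Peak(rt, mult * (i + 1) * 10.0) for i, rt in enumerate(rts)]
        tables.append(PeakTable(b, 260, peaks))
    return tables


@pytest.fixture
def small_matrix():
    return FingerprintMatrix(
        wavelength=260,
        batch_ids=["A", "B"],
        peak_ids=["P1", "P2", "P3"],
        areas=np.array([[2.0, 4.0, 6.0], [4.0, 8.0, 12.0]]),
        retention_times=np.array([5.0, 10.0, 15.0]),
    )


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free spec: no outliers, unit scales, tiny size for speed."""
    return default_spec(
        seed=7, n_batches=4, channels=((260, 6), (330, 5)),
        content_scale_sd=0.0, peak_noise_cv=0.0, outliers={},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size seeded default dataset (23 batches, 5 channels, 2 outliers)."""
    spec = default_spec(seed=11)
    matrices, truth = generate_fingerprints(spec)
    return spec, matrices, truth


def peak_csv(path, rows):
    pd.DataFrame(rows, columns=["batch_id", "wavelength", "retention_time", "area"]).to_csv(
        path, index=False
    )
    return path
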