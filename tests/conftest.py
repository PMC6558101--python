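"""Shared fixtures and independent oracles for the test suite.

The heavy end-to-end artifacts (the default synthetic dataset, its feature
windows, and a trained model) are session-scoped so the classification,
GA, and action-level tests share one computation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from emgmotion import (
    SynthConfig,
    extract_labeled_windows,
    generate_dataset,
    train_svm,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


# --- independent oracles -----------------------------------------------------


def sampen_bruteforce(x, m: int, r: float) -> float:
    """O(L^2) pure-Python sample entropy: explicit template enumeration.

    Counts ordered pairs of distinct templates (Chebyshev distance <= r) at
    lengths m and m+1 over the T = L - m templates, independent of the
    package's vectorized path.
    """
    x = [float(v) for v in x]
    L = len(x)
    T = L - m
    b = a = 0
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if b == 0 or a == 0:
        return math.log(T * (T - 1))
    return -math.log(a / b)


def interval_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Intersection over union of two half-open sample intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


# --- shared heavy artifacts ---------------------------------------------------


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def dataset20(synth_config):
    """The default synthetic dataset: 20 trials per class, seed 1."""
    return generate_dataset(synth_config, n_per_class=20, seed=1)


@pytest.fixture(scope="session")
def dataset20_features(dataset20):
    """Active-segment feature windows of the default dataset (40 columns)."""
    pairs = [(t.recording, t.meta.motion_label) for t in dataset20]
    return extract_labeled_windows(pairs)


@pytest.fixture(scope="session")
def trained_model(dataset20_features):
    """Default-parameter SVM fit on all windows of the default dataset."""
    fm = dataset20_features
    return train_svm(fm, fm.labels)


# --- synthetic EDF fixture writer --------------------------------------------


def write_minimal_edf(
    path,
    data_uv: np.ndarray,
    fs: int,
    labels=None,
    samples_per_record=None,
    phys_absmax: float = 1000.0,
) -> None:
    """Write a minimal synthetic EDF file (16-bit, 1 s records).

    Test-only fixture generator: builds just enough of the EDF layout to
    exercise the package's reader (which delegates parsing to mne).
    ``samples_per_record`` may differ per channel to fabricate the
    unsupported mixed-rate case.
    """
    n_samples, n_ch = data_uv.shape
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    spr = samples_per_record or [int(fs)] * n_ch
    n_records = n_samples // int(fs)

    def pad(value, width):
        return str(value)[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("synthetic subject", 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 + 256 * n_ch, 8),
            pad("", 44),
            pad(n_records, 8),
            pad("1", 8),
            pad(n_ch, 4),
        ]
    )
    columns = [
        (labels, 16),
        (["synthetic"] * n_ch, 80),
        (["uV"] * n_ch, 8),
        ([-phys_absmax] * n_ch, 8),
        ([phys_absmax] * n_ch, 8),
        (["-32768"] * n_ch, 8),
        (["32767"] * n_ch, 8),
        ([""] * n_ch, 80),
        (spr, 8),
        ([""] * n_ch, 32),
    ]
    signal_header = b"".join(
        b"".join(pad(v, width) for v in values) for values, width in columns
    )
    # Quantize with the EDF physical/digital affine map so the decoder's
    # inverse lands within half a digital step of the original value.
    cal = 2 * phys_absmax / (32767 - (-32768))
    offset = -phys_absmax - cal * (-32768)
    digital = np.clip(
        np.round((data_uv - offset) / cal), -32768, 32767
    ).astype("<i2")
    body = b""
    for rec_i in range(n_records):
        for c in range(n_ch):
            body += digital[rec_i * spr[c] : (rec_i + 1) * spr[c], c].tobytes()
    with open(path, "wb") as fh:
        fh.write(header + signal_header + body)
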