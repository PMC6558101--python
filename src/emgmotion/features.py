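"""Windowed time-domain feature extraction.

Signals are framed with a 128 ms Hanning-tapered window sliding in 64 ms
steps, and five time-domain features are computed per frame per channel:

- RMS: root mean square, sqrt(1/N sum x_i^2)
- VAR: population variance, 1/N sum (x_i - mean)^2
- MAV: mean absolute value, 1/N sum |x_i|
- SSI: simple square integral (short-term energy), sum x_i^2
- WL:  waveform length, sum |x_{i+1} - x_i|

With the 8 motion channels this yields the standard 40-column feature
matrix.  A lag-4 normalized autocorrelation (AC4) is available behind the
``feature_set`` option but excluded from the default set.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigError, DomainError
from .signal_io import Recording


def feat_rms(frame: np.ndarray) -> float:
    """Root mean square of the frame."""
    frame = _check_frame(frame)
    return float(np.sqrt(np.mean(frame**2)))


def feat_var(frame: np.ndarray) -> float:
    """Population variance (1/N) of the frame."""
    frame = _check_frame(frame)
    return float(np.mean((frame - frame.mean()) ** 2))


def feat_mav(frame: np.ndarray) -> float:
    """Mean absolute value of the frame."""
    frame = _check_frame(frame)
    return float(np.mean(np.abs(frame)))


def feat_ssi(frame: np.ndarray) -> float:
    """Simple square integral: sum of squares (no 1/N)."""
    frame = _check_frame(frame)
    return float(np.sum(frame**2))


def feat_wl(frame: np.ndarray) -> float:
    """Waveform length: sum of absolute successive differences."""
    frame = _check_frame(frame)
    if frame.size < 2:
        raise DomainError("waveform length needs a frame of >= 2 samples")
    return float(np.sum(np.abs(np.diff(frame))))


def feat_ac4(frame: np.ndarray) -> float:
    """Lag-4 normalized autocorrelation coefficient.

    Returns 0 for zero-variance frames, where the ratio is undefined.
    """
    frame = _check_frame(frame)
    if frame.size <= 4:
        raise DomainError("lag-4 autocorrelation needs a frame of > 4 samples")
    centered = frame - frame.mean()
    denom = float(np.sum(centered**2))
    if denom == 0.0:
        return 0.0
    return float(np.sum(centered[:-4] * centered[4:]) / denom)


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 1 or frame.size == 0:
        raise DomainError("feature operations expect a non-empty 1-D frame")
    return frame


FEATURES: dict[str, Callable[[np.ndarray], float]] = {
    "RMS": feat_rms,
    "VAR": feat_var,
    "MAV": feat_mav,
    "SSI": feat_ssi,
    "WL": feat_wl,
    "AC4": feat_ac4,
}

DEFAULT_FEATURE_SET: tuple[str, ...] = ("RMS", "VAR", "MAV", "SSI", "WL")


@dataclasses.dataclass
class FrameSpec:
    """Framing geometry and feature selection."""

    window_ms: float = 128.0
    step_ms: float = 64.0
    taper: str = "hanning"  # or "rectangular"
    feature_set: tuple[str, ...] = DEFAULT_FEATURE_SET

    def __post_init__(self) -> None:
        if not (self.window_ms > self.step_ms > 0):
            raise ConfigError(
                f"need window_ms > step_ms > 0, got {self.window_ms}/{self.step_ms}"
            )
        if self.taper not in ("hanning", "rectangular"):
            raise ConfigError(f"unknown taper {self.taper!r}")
        self.feature_set = tuple(self.feature_set)
        if not self.feature_set:
            raise ConfigError("feature_set must be non-empty")
        unknown = [f for f in self.feature_set if f not in FEATURES]
        if unknown:
            raise ConfigError(f"unknown features {unknown}; known: {sorted(FEATURES)}")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))

    def taper_vector(self, n: int) -> np.ndarray:
        if self.taper == "hanning":
            return np.hanning(n)
        return np.ones(n)


@dataclasses.dataclass
class FeatureMatrix:
    """Windows x (channels x features) matrix with window provenance.

    Column order is channel-major: all features of channel 0, then channel
    1, ... (``<channel>_<FEATURE>`` names).  ``labels`` optionally carries a
    per-window motion label and ``trial_ids`` the originating trial.
    """

    values: np.ndarray
    window_starts: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray | None = None
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("feature values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise DomainError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if not np.isfinite(self.values).all():
            raise DomainError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def frame_signal(
    rec: Recording, spec: FrameSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tapered frames of every channel.

    Returns ``(frames, starts)`` where ``frames`` has shape
    ``(n_frames, window_samples, n_channels)`` — each frame already
    multiplied by the taper — and ``starts`` holds each frame's first
    sample index.  The trailing partial frame is discarded.
    """
    spec = spec or FrameSpec()
    win = spec.window_samples(rec.fs)
    step = spec.step_samples(rec.fs)
    if rec.n_samples < win:
        raise DomainError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"window ({win} samples)"
        )
    starts = np.arange(0, rec.n_samples - win + 1, step)
    taper = spec.taper_vector(win)[:, None]
    frames = np.stack([rec.data[s : s + win] * taper for s in starts])
    return frames, starts


def build_feature_matrix(
    rec: Recording,
    spec: FrameSpec | None = None,
    channels: Sequence[int] | None = None,
) -> FeatureMatrix:
    """Feature matrix over all frames of the selected channels.

    Default channels are the recording's motion channels (estop excluded);
    with the default spec on 8 channels this yields the 40-column layout
    (ch0_RMS, ch0_VAR, ..., ch7_WL).
    """
    spec = spec or FrameSpec()
    if channels is None:
        channels = rec.motion_channels()
    channels = list(channels)
    frames, starts = frame_signal(rec, spec)
    funcs = [FEATURES[name] for name in spec.feature_set]
    names = tuple(
        f"{rec.channel_names[c]}_{fname}"
        for c in channels
        for fname in spec.feature_set
    )
    values = np.empty((len(starts), len(channels) * len(funcs)))
    for k in range(len(starts)):
        col = 0
        for c in channels:
            frame = frames[k, :, c]
            for fn in funcs:
                values[k, col] = fn(frame)
                col += 1
    return FeatureMatrix(values=values, window_starts=starts, feature_names=names)
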