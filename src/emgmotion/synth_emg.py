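"""Synthetic multi-channel sEMG trial generator.

The generator produces the signal structure the recognition pipeline
assumes: a rest baseline, a single 1-2 s motion burst, rest again, with a
motion-class-specific pattern of relative activation across the eight
monitored muscles, plus the two dominant recording artifacts (50 Hz mains
interference and sub-1 Hz baseline drift).

The surrogate model is the standard one for interference-pattern surface
EMG: amplitude-modulated band-limited Gaussian noise.  Each channel is

    drift + line_noise + rest_noise + envelope(t) * synergy[c] * gain * carrier(t)

with ``carrier`` zero-mean unit-variance noise band-limited to the EMG band
and ``envelope`` a trapezoid over the scheduled burst.  Everything is a
pure function of ``(config, label, seed)``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .exceptions import ConfigError, DomainError, StructureError
from .signal_io import (
    DEFAULT_CHANNEL_NAMES,
    MOTION_CLASSES,
    REST_LABEL,
    Recording,
    TrialMeta,
)

#: Relative activation of the 8 motion muscles per class, in montage order
#: (trapezius, pectoralis_major, posterior_deltoid, middle_deltoid,
#: anterior_deltoid, triceps_brachii, brachioradial, biceps_brachii).
#: Hand-crafted so each class's dominant muscles follow gross anatomy:
#: anterior deltoid + pectoralis drive flexion, middle deltoid + trapezius
#: abduction, pectoralis internal rotation, posterior deltoid external
#: rotation, biceps + brachioradialis elbow flexion.  Values are arbitrary
#: but fixed, documented constants; the classifier learns this structure.
DEFAULT_SYNERGY: dict[str, tuple[float, ...]] = {
    "shoulder_flexion": (0.30, 0.60, 0.10, 0.30, 1.00, 0.15, 0.10, 0.20),
    "shoulder_abduction": (0.70, 0.10, 0.30, 1.00, 0.40, 0.10, 0.10, 0.10),
    "shoulder_internal_rotation": (0.20, 1.00, 0.10, 0.20, 0.40, 0.10, 0.10, 0.15),
    "shoulder_external_rotation": (0.30, 0.10, 1.00, 0.40, 0.10, 0.20, 0.10, 0.10),
    "elbow_flexion": (0.15, 0.10, 0.10, 0.10, 0.20, 0.15, 0.80, 1.00),
    REST_LABEL: (0.0,) * 8,
}


@dataclasses.dataclass
class SynthConfig:
    """Generator parameters.

    Amplitude defaults follow typical adult surface-EMG scales with good
    skin preparation: a ~2 uV RMS rest baseline, active bursts on the
    order of 100 uV on the dominant muscle, a 5 uV 50 Hz mains component
    and a few microvolts of slow electrode drift — artifacts present and
    worth filtering, but small enough that the rest baseline stays
    statistically stationary between the scheduled burst window and its
    flanks.  Burst and rest durations follow the acquisition protocol the
    pipeline targets (movements lasting 1-2 s embedded in rest).
    """

    fs: float = 1000.0
    n_channels: int = 8
    include_estop: bool = True
    synergy: Mapping[str, Sequence[float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SYNERGY)
    )
    burst_duration_s: tuple[float, float] = (1.0, 2.0)
    rest_padding_s: tuple[float, float] = (0.5, 1.5)
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    rest_noise_rms: float = 2.0
    burst_gain: float = 100.0
    line_noise_amp: float = 5.0
    line_noise_hz: float = 50.0
    drift_amp: float = 3.0
    drift_max_hz: float = 0.8
    envelope_rise_fraction: float = 0.15
    estop_clench_gain: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band_hz
        if not (0.0 < lo < hi < self.fs / 2):
            raise ConfigError(
                f"carrier_band_hz {self.carrier_band_hz} must lie within "
                f"(0, fs/2) = (0, {self.fs / 2})"
            )
        for name in ("rest_noise_rms", "burst_gain", "line_noise_amp",
                     "drift_amp", "estop_clench_gain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 < self.envelope_rise_fraction <= 0.5):
            raise ConfigError("envelope_rise_fraction must be in (0, 0.5]")
        missing = [c for c in MOTION_CLASSES if c not in self.synergy]
        if missing:
            raise ConfigError(f"synergy vectors missing for classes {missing}")
        for cls, vec in self.synergy.items():
            if len(vec) != self.n_channels:
                raise ConfigError(
                    f"synergy[{cls!r}] has {len(vec)} weights, expected "
                    f"{self.n_channels}"
                )
            if any(w < 0 or w > 1 for w in vec):
                raise ConfigError(f"synergy[{cls!r}] weights must be in [0, 1]")

    @property
    def total_channels(self) -> int:
        return self.n_channels + (1 if self.include_estop else 0)


@dataclasses.dataclass
class SynthTrial:
    """A generated recording plus its ground truth."""

    recording: Recording
    meta: TrialMeta
    true_burst: tuple[int, int]  # half-open [start, end) sample interval

    def __post_init__(self) -> None:
        start, end = self.true_burst
        if not (0 <= start <= end <= self.recording.n_samples):
            raise StructureError(
                f"true_burst {self.true_burst} outside recording of "
                f"{self.recording.n_samples} samples"
            )


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n)
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = scipy.signal.sosfiltfilt(sos, white)
    std = shaped.std()
    if std > 0:
        shaped = (shaped - shaped.mean()) / std
    return shaped


def _trapezoid(n: int, rise_fraction: float) -> np.ndarray:
    """Trapezoidal envelope of length ``n`` with symmetric rise/fall ramps."""
    env = np.ones(n)
    ramp = int(round(n * rise_fraction))
    if ramp > 0:
        up = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[:ramp] = up
        env[n - ramp:] = up[::-1]
    return env


def _drift(rng: np.random.Generator, t: np.ndarray, amp: float, max_hz: float) -> np.ndarray:
    """Slow baseline wander: a few random low-frequency sinusoids."""
    out = np.zeros_like(t)
    for k in range(1, 4):
        f = rng.uniform(0.05, max_hz)
        phase = rng.uniform(0, 2 * np.pi)
        out += (amp * rng.uniform(0.3, 1.0) / k) * np.sin(2 * np.pi * f * t + phase)
    return out


def generate_trial(config: SynthConfig, label: str, seed: int) -> SynthTrial:
    """Generate one labeled trial; deterministic given (config, label, seed).

    ``label`` is one of the five motion classes or ``"rest"`` (zero
    activation: the burst window is scheduled but silent, useful for
    false-positive tests of downstream stages).
    """
    if label not in config.synergy and label != REST_LABEL:
        raise DomainError(
            f"unknown motion label {label!r}; expected one of "
            f"{sorted(config.synergy)}"
        )
    synergy = np.asarray(
        config.synergy.get(label, (0.0,) * config.n_channels), dtype=float
    )
    rng = np.random.default_rng(seed)
    fs = config.fs

    burst_s = rng.uniform(*config.burst_duration_s)
    pre_s = rng.uniform(*config.rest_padding_s)
    post_s = rng.uniform(*config.rest_padding_s)
    n_pre = int(round(pre_s * fs))
    n_burst = int(round(burst_s * fs))
    n_post = int(round(post_s * fs))
    n = n_pre + n_burst + n_post
    t = np.arange(n) / fs

    envelope = np.zeros(n)
    envelope[n_pre : n_pre + n_burst] = _trapezoid(
        n_burst, config.envelope_rise_fraction
    )

    n_total = config.total_channels
    data = np.empty((n, n_total))
    for c in range(n_total):
        drift = _drift(rng, t, config.drift_amp, config.drift_max_hz)
        line = config.line_noise_amp * np.sin(
            2 * np.pi * config.line_noise_hz * t + rng.uniform(0, 2 * np.pi)
        )
        rest = config.rest_noise_rms * _bandlimited_noise(
            rng, n, fs, config.carrier_band_hz
        )
        channel = drift + line + rest
        if c < config.n_channels and synergy[c] > 0:
            carrier = _bandlimited_noise(rng, n, fs, config.carrier_band_hz)
            channel = channel + envelope * synergy[c] * config.burst_gain * carrier
        data[:, c] = channel

    names = list(DEFAULT_CHANNEL_NAMES[: config.n_channels])
    names += [f"ch{i}" for i in range(len(names), config.n_channels)]
    estop = None
    if config.include_estop:
        names.append(DEFAULT_CHANNEL_NAMES[8])
        estop = config.n_channels

    rec = Recording(
        data=data, fs=fs, channel_names=tuple(names), estop_channel=estop
    )
    meta = TrialMeta(subject_id="synth", motion_label=label, trial_index=int(seed))
    return SynthTrial(recording=rec, meta=meta, true_burst=(n_pre, n_pre + n_burst))


def child_seeds(seed: int, n: int) -> np.ndarray:
    """``n`` deterministic child seeds (< 2**31) derived from ``seed``."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def generate_dataset(
    config: SynthConfig, n_per_class: int, seed: int
) -> list[SynthTrial]:
    """Balanced dataset: ``n_per_class`` trials for each of the 5 classes.

    Trial order is class-major (all repetitions of class 0, then class 1,
    ...); child seeds are derived deterministically from ``seed``.
    """
    if n_per_class < 1:
        raise DomainError(f"n_per_class must be >= 1, got {n_per_class}")
    seeds = child_seeds(seed, 5 * n_per_class)
    trials = []
    k = 0
    for label in MOTION_CLASSES:
        for rep in range(n_per_class):
            trial = generate_trial(config, label, int(seeds[k]))
            trial.meta = TrialMeta(
                subject_id="synth", motion_label=label, trial_index=rep
            )
            trials.append(trial)
            k += 1
    return trials


def inject_estop_clench(
    trial: SynthTrial,
    config: SynthConfig,
    clench_interval: tuple[int, int],
    seed: int = 0,
) -> SynthTrial:
    """Add a fist-clench burst to the emergency-stop channel.

    A band-limited burst of RMS ``config.estop_clench_gain`` (well above the
    rest baseline) is added over ``clench_interval`` on the estop channel
    only; every other channel is untouched.  An empty interval is a no-op.
    Returns a new trial; the input is not modified.
    """
    rec = trial.recording
    if rec.estop_channel is None:
        raise StructureError("trial has no emergency-stop channel")
    start, end = clench_interval
    if start == end:
        return SynthTrial(
            recording=rec.with_data(rec.data.copy()),
            meta=trial.meta,
            true_burst=trial.true_burst,
        )
    if not (0 <= start < end <= rec.n_samples):
        raise DomainError(
            f"clench_interval {clench_interval} outside recording of "
            f"{rec.n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    n_clench = end - start
    burst = config.estop_clench_gain * _bandlimited_noise(
        rng, n_clench, rec.fs, config.carrier_band_hz
    )
    burst *= _trapezoid(n_clench, 0.1)
    data = rec.data.copy()
    data[start:end, rec.estop_channel] += burst
    return SynthTrial(
        recording=rec.with_data(data), meta=trial.meta, true_burst=trial.true_burst
    )
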