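"""Five-stage sEMG conditioning: baseline correction, Butterworth band-pass,
50 Hz notch, full-wave rectification, amplitude normalization.

All stages preserve signal length and recording metadata.  Filtering is
zero-phase (forward-backward) by default, appropriate for offline analysis
and avoiding group-delay shifts of detected activity onsets; a causal mode
is available for streaming-style use.

The band-pass upper edge defaults to 450 Hz: with the usual 1 kHz sampling
rate the nominal 500 Hz EMG band edge coincides with Nyquist and is not
realizable, so 0.9 x Nyquist preserves the intent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from .exceptions import ConfigError, DomainError
from .signal_io import Recording


@dataclasses.dataclass
class FilterSpec:
    """Filter configuration for the conditioning pipeline.

    ``order`` is the true filter order of the band-pass (an order-4
    Butterworth band-pass is realized as two second-order pole pairs); it
    must be even.  With ``zero_phase`` the filter runs forward-backward,
    doubling the effective magnitude attenuation.  The notch is a
    second-order IIR notch of quality ``notch_q``; ``notch_design =
    "bandstop"`` selects the literal alternative, a Butterworth band-stop
    of +-1 Hz around the notch frequency.
    """

    bandpass_hz: tuple[float, float] = (20.0, 450.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    order: int = 4
    zero_phase: bool = True
    notch_design: str = "iirnotch"  # or "bandstop"

    def validate(self, fs: float) -> None:
        low, high = self.bandpass_hz
        nyquist = fs / 2
        if not (0 < low < high):
            raise ConfigError(f"band-pass edges must satisfy 0 < low < high, got {self.bandpass_hz}")
        if high >= nyquist:
            raise ConfigError(
                f"band-pass high cutoff {high} Hz must be below the Nyquist "
                f"frequency fs/2 = {nyquist} Hz"
            )
        if self.order < 2 or self.order % 2:
            raise ConfigError(f"filter order must be even and >= 2, got {self.order}")
        if not (0 < self.notch_hz < nyquist):
            raise ConfigError(
                f"notch frequency {self.notch_hz} Hz must be below Nyquist {nyquist} Hz"
            )
        if self.notch_q <= 0:
            raise ConfigError("notch_q must be positive")
        if self.notch_design not in ("iirnotch", "bandstop"):
            raise ConfigError(f"unknown notch_design {self.notch_design!r}")


def _apply_sos(rec: Recording, sos: np.ndarray, zero_phase: bool) -> Recording:
    if zero_phase:
        out = scipy.signal.sosfiltfilt(sos, rec.data, axis=0)
    else:
        out = scipy.signal.sosfilt(sos, rec.data, axis=0)
    return rec.with_data(out)


def baseline_correct(rec: Recording) -> Recording:
    """Remove each channel's mean (DC offset)."""
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def bandpass_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Butterworth band-pass of ``spec.order`` applied per channel."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    sos = scipy.signal.butter(
        spec.order // 2, spec.bandpass_hz, btype="bandpass", fs=rec.fs, output="sos"
    )
    return _apply_sos(rec, sos, spec.zero_phase)


def notch_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Narrow-band rejection of the mains frequency per channel."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    if spec.notch_design == "iirnotch":
        b, a = scipy.signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
        sos = scipy.signal.tf2sos(b, a)
    else:
        sos = scipy.signal.butter(
            spec.order // 2,
            (spec.notch_hz - 1.0, spec.notch_hz + 1.0),
            btype="bandstop",
            fs=rec.fs,
            output="sos",
        )
    return _apply_sos(rec, sos, spec.zero_phase)


def rectify(rec: Recording) -> Recording:
    """Full-wave rectification: every sample replaced by its absolute value."""
    return rec.with_data(np.abs(rec.data))


def normalize_amplitude(rec: Recording, mode: str = "per_channel") -> Recording:
    """Scale a rectified (nonnegative) recording into [0, 1].

    ``mode="per_channel"`` divides each channel by its own maximum so every
    channel peaks at exactly 1 (all-zero channels stay zero).
    ``mode="global"`` divides all channels by the single largest value in
    the recording, preserving relative inter-channel amplitudes — the mode
    the recognition pipeline uses, since per-channel peaks would equalize
    every muscle's burst amplitude and discard the activation pattern that
    distinguishes the motions.
    """
    if (rec.data < 0).any():
        raise DomainError(
            "normalize_amplitude expects a rectified (nonnegative) recording"
        )
    if mode == "per_channel":
        maxima = rec.data.max(axis=0, keepdims=True)
        scale = np.where(maxima > 0, maxima, 1.0)
        return rec.with_data(rec.data / scale)
    if mode == "global":
        m = rec.data.max()
        return rec.with_data(rec.data / m if m > 0 else rec.data)
    raise ConfigError(f"unknown normalization mode {mode!r}")


def preprocess_pipeline(
    rec: Recording,
    spec: FilterSpec | None = None,
    normalize_mode: str = "global",
) -> Recording:
    """Run the five conditioning stages in order.

    baseline correction -> band-pass -> notch -> rectification ->
    amplitude normalization.  Metadata (fs, channel names, estop index) is
    preserved; output values lie in [0, 1].
    """
    spec = spec or FilterSpec()
    out = baseline_correct(rec)
    out = bandpass_filter(out, spec)
    out = notch_filter(out, spec)
    out = rectify(out)
    out = normalize_amplitude(out, mode=normalize_mode)
    return out
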