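"""Containers and I/O for multi-channel surface-EMG recordings.

A :class:`Recording` is a plain ``samples x channels`` float matrix in
microvolts plus its sampling rate and ordered channel names.  The default
montage is the nine-muscle upper-limb setup used throughout the package:
eight motion muscles plus a wrist-flexor channel reserved for the
emergency-stop clench.

CSV (samples x channels, one header row of channel names) is the canonical
on-disk format and round-trips exactly; EDF is supported read-only as a
convenience for standard biosignal interchange.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, StructureError

#: Ordered default montage: 8 motion muscles + the emergency-stop channel.
DEFAULT_CHANNEL_NAMES: tuple[str, ...] = (
    "trapezius",
    "pectoralis_major",
    "posterior_deltoid",
    "middle_deltoid",
    "anterior_deltoid",
    "triceps_brachii",
    "brachioradial",
    "biceps_brachii",
    "ulnar_flexor_carpal",
)

#: The five upper-limb motion classes the classifier distinguishes.
MOTION_CLASSES: tuple[str, ...] = (
    "shoulder_flexion",
    "shoulder_abduction",
    "shoulder_internal_rotation",
    "shoulder_external_rotation",
    "elbow_flexion",
)

#: Label for trials with no intended motion.
REST_LABEL = "rest"

#: Index of the emergency-stop channel in the default 9-channel montage.
DEFAULT_ESTOP_CHANNEL = 8


@dataclasses.dataclass
class Recording:
    """A samples x channels sEMG signal matrix in microvolts.

    Parameters
    ----------
    data
        2-D float array, shape ``(n_samples, n_channels)``.  Amplitudes are
        microvolts; no implicit unit conversion happens anywhere.
    fs
        Sampling frequency in Hz (default 1000).
    channel_names
        Ordered channel names; defaults to the 9-muscle montage truncated
        or padded (``ch<i>``) to the channel count.
    estop_channel
        Index of the safety channel, or ``None`` when the recording has no
        dedicated emergency-stop muscle.  The synthetic generator and the
        CLI set index 8 for the standard 9-channel montage.
    """

    data: np.ndarray
    fs: float = 1000.0
    channel_names: tuple[str, ...] | None = None
    estop_channel: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise StructureError(
                f"Recording data must be 2-D (samples x channels), got ndim={self.data.ndim}"
            )
        n_samples, n_channels = self.data.shape
        if n_samples < 1 or n_channels < 1:
            raise StructureError(
                f"Recording needs >=1 sample and >=1 channel, got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise StructureError("Recording contains non-finite amplitude values")
        if not (self.fs > 0):
            raise StructureError(f"Sampling rate must be positive, got fs={self.fs}")
        if self.channel_names is None:
            base = list(DEFAULT_CHANNEL_NAMES[:n_channels])
            base += [f"ch{i}" for i in range(len(base), n_channels)]
            self.channel_names = tuple(base)
        else:
            self.channel_names = tuple(str(n) for n in self.channel_names)
            if len(self.channel_names) != n_channels:
                raise StructureError(
                    f"channel_names length {len(self.channel_names)} != "
                    f"channel count {n_channels}"
                )
        if self.estop_channel is not None and not (
            0 <= int(self.estop_channel) < n_channels
        ):
            raise StructureError(
                f"estop_channel {self.estop_channel} out of range for "
                f"{n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def motion_channels(self) -> list[int]:
        """Indices of all non-estop channels, in order."""
        return [i for i in range(self.n_channels) if i != self.estop_channel]

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with replaced sample matrix, same metadata."""
        return Recording(
            data=data,
            fs=self.fs,
            channel_names=self.channel_names,
            estop_channel=self.estop_channel,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.channel_names == other.channel_names
            and self.estop_channel == other.estop_channel
            and self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
        )


@dataclasses.dataclass(frozen=True)
class TrialMeta:
    """Per-trial metadata: subject, motion label, repetition index."""

    subject_id: str
    motion_label: str
    trial_index: int = 0

    def __post_init__(self) -> None:
        allowed = set(MOTION_CLASSES) | {REST_LABEL}
        if self.motion_label not in allowed:
            raise StructureError(
                f"motion_label {self.motion_label!r} not in {sorted(allowed)}"
            )


def read_recording_csv(
    path: str | os.PathLike,
    fs: float = 1000.0,
    channel_names: Sequence[str] | None = None,
    estop_channel: int | None = None,
) -> Recording:
    """Read a samples x channels CSV into a :class:`Recording`.

    A non-numeric first row is treated as a header of channel names and
    overrides the ``channel_names`` argument.  Column order in the file is
    preserved.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise StructureError(f"{path}: empty file")
    header_tokens = [t.strip() for t in first.strip().split(",")]
    has_header = not all(_is_number(t) for t in header_tokens)

    try:
        df = pd.read_csv(
            path,
            header=0 if has_header else None,
            float_precision="round_trip",  # exact write->read inversion
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise StructureError(f"{path}: malformed CSV table: {exc}") from exc
    if has_header:
        channel_names = [str(c) for c in df.columns]

    for j, col in enumerate(df.columns):
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & ~df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at data row "
                f"{row}, column {j} ({col!r})"
            )
        if series.isna().any():
            row = int(np.flatnonzero(series.isna().to_numpy())[0])
            raise StructureError(
                f"{path}: missing value at data row {row}, column {j} "
                f"({col!r}); rows must all have the same width"
            )
        df[col] = series

    return Recording(
        data=df.to_numpy(dtype=float),
        fs=fs,
        channel_names=channel_names,
        estop_channel=estop_channel,
    )


def write_recording_csv(rec: Recording, path: str | os.PathLike) -> str:
    """Write ``rec`` as CSV: one header row of channel names, one row per sample.

    Values are serialized with full ``repr`` precision so that
    :func:`read_recording_csv` inverts this bit-exactly for float64 data.
    """
    df = pd.DataFrame(rec.data, columns=list(rec.channel_names))
    df.to_csv(path, index=False)
    return str(path)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


# --- EDF (read-only convenience) -------------------------------------------

_EDF_FIXED_HEADER = 256
_EDF_PER_SIGNAL = 216  # label..dig_max+prefilter bytes preceding samples field


def _edf_samples_per_record(path: str | os.PathLike) -> list[int]:
    """Light EDF header scan: per-signal samples-per-record counts.

    Used only to reject mixed-rate files up front with a clear error; all
    actual signal parsing is delegated to :mod:`mne`.
    """
    with open(path, "rb") as fh:
        header = fh.read(_EDF_FIXED_HEADER)
        if len(header) < _EDF_FIXED_HEADER:
            raise ParseError(f"{path}: truncated EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ParseError(f"{path}: corrupt EDF header (signal count)") from exc
        if ns < 1:
            raise ParseError(f"{path}: EDF header reports {ns} signals")
        per_signal = fh.read(ns * (_EDF_PER_SIGNAL + 8 + 32))
    offset = ns * _EDF_PER_SIGNAL
    counts = []
    for i in range(ns):
        field = per_signal[offset + 8 * i : offset + 8 * (i + 1)]
        try:
            counts.append(int(field.decode("ascii").strip()))
        except ValueError as exc:
            raise ParseError(
                f"{path}: corrupt EDF header (samples-per-record, signal {i})"
            ) from exc
    return counts


def read_recording_edf(path: str | os.PathLike) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    All channels must share one sampling rate; mixed-rate files raise
    :class:`FormatError`.  Sampling rate and channel labels come from the
    file.  MNE returns SI volts internally; amplitudes are converted back
    to microvolts to match the package-wide convention.
    """
    counts = _edf_samples_per_record(path)
    if len(set(counts)) > 1:
        raise FormatError(
            f"{path}: channels have different sampling rates "
            f"(samples per record {sorted(set(counts))}); only uniform-rate "
            "EDF files are supported"
        )
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ParseError(f"{path}: failed to parse EDF: {exc}") from exc
    data_uv = raw.get_data().T * 1e6  # volts -> microvolts
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
    )
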