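"""End-to-end orchestration: train on labeled trials, recognize motions on
new recordings with an action-level majority vote, and detect the
emergency-stop clench on the dedicated channel.

The robot side of the original control loop (trajectory execution over
TCP/IP) is replaced by an exported label stream with the same information
content: a time-ordered CSV of motion decisions and estop events, with
estop rows taking precedence at equal timestamps.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .classify import (
    EvalReport,
    GAConfig,
    SVMModel,
    SVMParams,
    cross_validate,
    decision_scores,
    ga_optimize,
    predict_windows,
    train_svm,
)
from .exceptions import DomainError, StructureError, ValidationError
from .features import FeatureMatrix, FrameSpec, build_feature_matrix
from .preprocess import FilterSpec, bandpass_filter, baseline_correct, preprocess_pipeline
from .segmentation import SampEnParams, Segment, segment_recording
from .signal_io import Recording

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Bundled stage configurations with the package defaults."""

    filter_spec: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    sampen: SampEnParams = dataclasses.field(default_factory=SampEnParams)
    frame: FrameSpec = dataclasses.field(default_factory=FrameSpec)
    normalize_mode: str = "global"
    min_segment_s: float = 0.3
    merge_gap_s: float = 0.2


@dataclasses.dataclass
class ActionDecision:
    """Majority-voted label for one detected motion segment."""

    segment: Segment
    window_votes: dict[str, int]
    label: str
    confidence: float  # winning share of window votes, in (0, 1]


@dataclasses.dataclass(frozen=True)
class EstopEvent:
    """Onset of a detected emergency-stop clench."""

    start: int
    channel: int


def windows_in_segments(
    window_starts: np.ndarray, window_len: int, segments: Sequence[Segment]
) -> np.ndarray:
    """Boolean mask of windows lying fully inside any segment."""
    starts = np.asarray(window_starts)
    mask = np.zeros(starts.shape, dtype=bool)
    for seg in segments:
        mask |= (starts >= seg.start) & (starts + window_len <= seg.end)
    return mask


def extract_labeled_windows(
    trials: Sequence[tuple[Recording, str]],
    config: PipelineConfig | None = None,
) -> FeatureMatrix:
    """Preprocess, segment and featurize labeled trials.

    Each trial contributes the feature windows lying fully inside its
    detected active segments, labeled with the trial's motion label.
    Raises with the stage name and trial index on failure.
    """
    config = config or PipelineConfig()
    blocks: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    labels: list[str] = []
    trial_ids: list[int] = []
    names: tuple[str, ...] | None = None
    for idx, (rec, label) in enumerate(trials):
        try:
            proc = preprocess_pipeline(
                rec, config.filter_spec, normalize_mode=config.normalize_mode
            )
            segments, _ = segment_recording(
                proc,
                config.sampen,
                min_duration_s=config.min_segment_s,
                merge_gap_s=config.merge_gap_s,
            )
            fm = build_feature_matrix(proc, config.frame)
        except Exception as exc:
            raise type(exc)(f"trial {idx} ({label}): {exc}") from exc
        win_len = config.frame.window_samples(rec.fs)
        mask = windows_in_segments(fm.window_starts, win_len, segments)
        if not mask.any():
            logger.warning("trial %d (%s): no active windows detected", idx, label)
            continue
        if names is None:
            names = fm.feature_names
        elif fm.feature_names != names:
            raise ValidationError(
                f"trial {idx}: feature columns differ from earlier trials"
            )
        blocks.append(fm.values[mask])
        starts.append(fm.window_starts[mask])
        labels.extend([label] * int(mask.sum()))
        trial_ids.extend([idx] * int(mask.sum()))
    if not blocks:
        raise DomainError("no active windows found in any trial")
    return FeatureMatrix(
        values=np.vstack(blocks),
        window_starts=np.concatenate(starts),
        feature_names=names,
        labels=np.asarray(labels),
        trial_ids=np.asarray(trial_ids),
    )


def train_from_trials(
    trials: Sequence[tuple[Recording, str]],
    config: PipelineConfig | None = None,
    use_ga: bool = False,
    ga_config: GAConfig | None = None,
    params: SVMParams | None = None,
    cv_repeats: int = 1,
    seed: int = 0,
) -> tuple[SVMModel, EvalReport]:
    """Full training run: windows -> (optional GA) -> SVM + CV report.

    With ``use_ga`` the (C, delta) pair comes from the genetic search;
    otherwise ``params`` (default: C = 1, gamma = 1/num_features) is used
    directly.  The report is repeated stratified 5-fold cross-validation at
    the chosen parameters; the returned model is refit on all windows.
    """
    config = config or PipelineConfig()
    fm = extract_labeled_windows(trials, config)
    y = fm.labels
    if len(set(y.tolist())) < 2:
        raise DomainError("training needs trials from at least two classes")
    if use_ga:
        ga = ga_config or GAConfig(seed=seed)
        params, history = ga_optimize(fm, y, ga)
        logger.info(
            "GA selected C=%.4g delta=%.4g (fitness %.4f)",
            params.C, params.delta, history[-1],
        )
    elif params is None:
        params = SVMParams.default_for(fm.values.shape[1])
    report = cross_validate(
        fm, y, params=params, folds=5, repeats=cv_repeats, seed=seed
    )
    model = train_svm(fm, y, params)
    return model, report


def majority_vote(
    predictions: np.ndarray,
    class_scores: np.ndarray,
    classes: Sequence[str],
) -> tuple[str, dict[str, int], float]:
    """Action label from per-window predictions.

    Returns ``(label, votes, confidence)`` where ``confidence`` is the
    winning share of window votes.  Ties are broken by the larger summed
    per-class decision score (``class_scores``: windows x classes), then by
    class order.
    """
    predictions = np.asarray(predictions)
    if predictions.size == 0:
        raise DomainError("majority_vote needs at least one window prediction")
    classes = list(classes)
    summed = np.asarray(class_scores).sum(axis=0)
    votes = {c: int((predictions == c).sum()) for c in classes}
    top = max(votes.values())
    tied = [c for c in classes if votes[c] == top]
    if len(tied) > 1:
        tied.sort(key=lambda c: -summed[classes.index(c)])
    return tied[0], votes, top / predictions.size


def recognize(
    rec: Recording,
    model: SVMModel,
    config: PipelineConfig | None = None,
) -> list[ActionDecision]:
    """Detect motion segments and majority-vote a label for each.

    Ties are broken by the larger summed per-class decision margin over the
    segment's windows, then by model class order.  A recording with no
    active segment yields an empty list.
    """
    config = config or PipelineConfig()
    proc = preprocess_pipeline(
        rec, config.filter_spec, normalize_mode=config.normalize_mode
    )
    segments, _ = segment_recording(
        proc,
        config.sampen,
        min_duration_s=config.min_segment_s,
        merge_gap_s=config.merge_gap_s,
    )
    if not segments:
        logger.info("no active segment found; returning empty decision list")
        return []
    fm = build_feature_matrix(proc, config.frame)
    win_len = config.frame.window_samples(rec.fs)
    decisions = []
    for seg in segments:
        mask = windows_in_segments(fm.window_starts, win_len, [seg])
        if not mask.any():
            continue
        block = fm.values[mask]
        pred = predict_windows(model, block)
        scores = decision_scores(model, block)
        label, votes, confidence = majority_vote(pred, scores, model.classes)
        decisions.append(
            ActionDecision(
                segment=seg, window_votes=votes, label=label, confidence=confidence
            )
        )
    return decisions


def detect_estop(
    rec: Recording,
    baseline_window_s: float = 0.5,
    k_sigma: float = 5.0,
    min_hold_ms: float = 200.0,
    rms_window_ms: float = 128.0,
) -> list[EstopEvent]:
    """Threshold detector for the emergency-stop clench.

    The estop channel is baseline-corrected and band-passed, then a sliding
    RMS (``rms_window_ms``) is compared against ``mean + k_sigma * sd`` of
    the RMS trace over the first ``baseline_window_s`` seconds.  Each
    maximal exceedance run sustained for at least ``min_hold_ms`` yields
    one event at its first sample.
    """
    if rec.estop_channel is None:
        raise StructureError("recording has no emergency-stop channel")
    n_base = int(round(baseline_window_s * rec.fs))
    if rec.n_samples < n_base or n_base < 2:
        raise DomainError(
            f"recording of {rec.n_samples} samples is shorter than the "
            f"baseline window ({n_base} samples)"
        )
    channel = Recording(
        rec.data[:, [rec.estop_channel]], fs=rec.fs, channel_names=("estop",)
    )
    filtered = bandpass_filter(baseline_correct(channel)).data[:, 0]

    n_rms = max(2, int(round(rms_window_ms * rec.fs / 1000.0)))
    kernel = np.ones(n_rms) / n_rms
    power = np.convolve(filtered**2, kernel, mode="same")
    rms = np.sqrt(np.maximum(power, 0.0))

    mu = float(rms[:n_base].mean())
    sd = float(rms[:n_base].std())
    threshold = mu + k_sigma * sd
    above = rms > threshold

    min_hold = int(round(min_hold_ms * rec.fs / 1000.0))
    events = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if (j - i + 1) >= min_hold:
                events.append(EstopEvent(start=i, channel=rec.estop_channel))
            i = j + 1
        else:
            i += 1
    return events


def export_label_stream(
    decisions: Sequence[ActionDecision],
    estops: Sequence[EstopEvent],
    path: str | os.PathLike,
    fs: float = 1000.0,
) -> str:
    """Write the time-ordered event stream as CSV.

    Columns: timestamp_s, event_type (motion | estop), label, confidence.
    Estop rows sort before motion rows at equal timestamps (safety
    precedence).
    """
    rows = []
    for d in decisions:
        rows.append(
            {
                "timestamp_s": d.segment.start / fs,
                "event_type": "motion",
                "label": d.label,
                "confidence": d.confidence,
            }
        )
    for e in estops:
        rows.append(
            {
                "timestamp_s": e.start / fs,
                "event_type": "estop",
                "label": "estop",
                "confidence": 1.0,
            }
        )
    rows.sort(key=lambda r: (r["timestamp_s"], 0 if r["event_type"] == "estop" else 1))
    df = pd.DataFrame(rows, columns=["timestamp_s", "event_type", "label", "confidence"])
    df.to_csv(path, index=False)
    return str(path)


def save_model(model: SVMModel, path: str | os.PathLike) -> str:
    """Persist a trained model as a single self-describing archive."""
    joblib.dump(
        {
            "format": "emgmotion-svm-v1",
            "params": {"C": model.params.C, "delta": model.params.delta},
            "classes": list(model.classes),
            "feature_names": (
                list(model.feature_names) if model.feature_names else None
            ),
            "pipeline": model.pipeline,
        },
        path,
    )
    return str(path)


def load_model(path: str | os.PathLike) -> SVMModel:
    """Load a model archive written by :func:`save_model`."""
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != "emgmotion-svm-v1":
        raise ValidationError(f"{path}: not an emgmotion model archive")
    return SVMModel(
        params=SVMParams(**blob["params"]),
        classes=tuple(blob["classes"]),
        feature_names=(
            tuple(blob["feature_names"]) if blob["feature_names"] else None
        ),
        pipeline=blob["pipeline"],
    )
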