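"""Whole-record prediction, channel-pair majority voting and F1 metrics.

A record is scored by running the network once per (EEG, EOG) channel
pair over the full preprocessed signal; the per-pair posteriors are fused
by summing softmax confidences per segment and taking the argmax
(majority vote).  Evaluation excludes reference positions labelled MASK
entirely and reports per-stage F1 = 2TP/(2TP+FP+FN) with an unweighted
mean, either pooled over subjects ("global") or per subject (mean ± SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._stages import MASK_CODE, N_STAGES, STAGES
from .io import Hypnogram, PSGRecord, enumerate_channel_pairs
from .model import StagePosterior, USleepNet, min_input_length

__all__ = [
    "ConfusionMatrix",
    "predict_record",
    "majority_vote",
    "f1_scores",
    "evaluate_record",
    "pooled_confusion",
    "per_subject_f1",
]


@dataclass
class ConfusionMatrix:
    """K×K counts; rows = reference stage, columns = predicted stage."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((N_STAGES, N_STAGES), dtype=np.int64))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STAGES, N_STAGES) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be K×K non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def predict_record(model: USleepNet, record: PSGRecord, period_s: float = 30.0
                   ) -> dict[tuple[str, str], StagePosterior]:
    """One posterior per EEG×EOG channel pair for a preprocessed record.

    The signal is zero-padded on the right to a multiple of the segment
    width ``i = period_s · internal_rate``; the label count is the number
    of whole segments in the original span.  Records shorter than the
    recommended minimum input length are padded with a warning.
    """
    i = model.config.segment_samples(period_s)
    pairs = enumerate_channel_pairs(record)
    out: dict[tuple[str, str], StagePosterior] = {}
    for eeg_label, eog_label in pairs:
        eeg = record.channel(eeg_label).samples
        eog = record.channel(eog_label).samples
        L = min(len(eeg), len(eog))
        T_out = L // i
        min_len = min_input_length(model.config)
        L_pad = max(int(np.ceil(L / i)) * i, i)
        if L < min_len:
            warnings.warn(
                f"record {record.subject_id!r} is shorter ({L} samples) than the "
                f"recommended minimum input length {min_len}; padding")
        x = np.zeros((1, 2, L_pad), dtype=np.float32)
        x[0, 0, :L] = eeg[:L]
        x[0, 1, :L] = eog[:L]
        probs = model.predict_proba(x, i)[0]
        T_out = max(T_out, 1) if L else 0
        out[(eeg_label, eog_label)] = StagePosterior(
            probs[:T_out], i, origin=(record.subject_id, eeg_label, eog_label))
    return out


def majority_vote(posteriors, label_frequency: float | None = None) -> Hypnogram:
    """Fuse posteriors by summing confidences per segment and arg-maxing.

    Exact ties resolve to the lowest stage index (W < N1 < N2 < N3 < REM).
    Accepts a list or the dict returned by :func:`predict_record`.
    """
    if isinstance(posteriors, dict):
        posteriors = list(posteriors.values())
    if not posteriors:
        raise ValueError("no posteriors to vote over")
    shapes = {p.values.shape for p in posteriors}
    if len(shapes) != 1:
        raise ValueError(f"posterior shapes differ: {shapes}")
    total = np.sum([p.values for p in posteriors], axis=0)
    labels = total.argmax(axis=1).astype(np.int8)  # argmax takes the first maximum
    if label_frequency is None:
        # i samples per label at the internal rate implied by the posterior
        label_frequency = 1.0 / (posteriors[0].segment_samples / 128.0)
    return Hypnogram(labels, label_frequency)


def evaluate_record(pred: Hypnogram, ref: Hypnogram) -> ConfusionMatrix:
    """Confusion matrix of one record; MASK reference positions excluded."""
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: pred {len(pred)} vs ref {len(ref)}")
    keep = ref.labels != MASK_CODE
    if not keep.any():
        warnings.warn("reference hypnogram is entirely masked; empty matrix")
    r = ref.labels[keep].astype(np.int64)
    p = np.clip(pred.labels[keep].astype(np.int64), 0, N_STAGES - 1)
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (r, p), 1)
    return ConfusionMatrix(counts)


def f1_scores(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-stage F1 and the unweighted mean over stages present.

    A stage absent from both reference and prediction (2TP+FP+FN = 0) is
    excluded from the mean; a stage present in the reference but never
    predicted correctly scores 0.
    """
    c = cm.counts
    tp = np.diag(c).astype(np.float64)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    out: dict[str, float] = {}
    present = []
    for k, stage in enumerate(STAGES):
        if denom[k] == 0:
            out[stage] = np.nan
        else:
            out[stage] = float(2 * tp[k] / denom[k])
            present.append(out[stage])
    out["mean"] = float(np.mean(present)) if present else np.nan
    return out


def pooled_confusion(cms) -> ConfusionMatrix:
    """Sum per-subject matrices into a single pooled ("global") matrix."""
    total = ConfusionMatrix()
    for cm in cms:
        total = total + cm
    return total


def per_subject_f1(cms) -> dict[str, tuple[float, float]]:
    """Per-subject mean ± SD of the stage-wise F1 scores."""
    rows = [f1_scores(cm) for cm in cms]
    out = {}
    for key in list(STAGES) + ["mean"]:
        vals = np.array([r[key] for r in rows], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[key] = (float(vals.mean()), float(vals.std(ddof=0)))
        else:
            out[key] = (np.nan, np.nan)
    return out
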