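"""PSG signal and hypnogram I/O plus signal preprocessing.

A polysomnogram is represented as a :class:`PSGRecord` — a set of channels,
each with a free-text label, a role (EEG / EOG / OTHER) inferred from the
label, and its native sampling rate.  The scored hypnogram travels
separately as a :class:`Hypnogram` of 30-s stage labels (other label
periods are supported).

Preprocessing follows the staging pipeline's conventions:

* every channel is resampled to a common internal rate (default 128 Hz)
  with polyphase filtering;
* each channel is robustly standardized over the whole recording to
  median 0 / IQR 1 and clipped at 20 IQRs from the median;
* signal outside the span of the scored hypnogram is stripped.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from . import edf as _edf
from ._stages import MASK_CODE, MASK_TOKEN, STAGES, code_of, tokens_of

__all__ = [
    "Channel",
    "PSGRecord",
    "Hypnogram",
    "PreprocessSpec",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "resample",
    "robust_scale_clip",
    "align_and_strip",
    "normalize_stages",
    "enumerate_channel_pairs",
    "preprocess",
    "infer_channel_role",
    "MissingRoleError",
    "LengthMismatchError",
]


class MissingRoleError(ValueError):
    """A record lacks the EEG or EOG channel required for staging."""


class LengthMismatchError(ValueError):
    """Hypnogram and signal spans are incompatible."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Channel:
    label: str
    role: str  # "EEG" | "EOG" | "OTHER"
    native_rate: float  # Hz
    samples: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.samples) / self.native_rate


@dataclass
class PSGRecord:
    subject_id: str
    dataset_id: str
    channels: list[Channel] = field(default_factory=list)

    @property
    def duration(self) -> float:
        """Recording span in seconds (maximum over channels)."""
        return max((c.duration for c in self.channels), default=0.0)

    def channels_with_role(self, role: str) -> list[Channel]:
        return [c for c in self.channels if c.role == role]

    @property
    def eeg_channels(self) -> list[Channel]:
        return self.channels_with_role("EEG")

    @property
    def eog_channels(self) -> list[Channel]:
        return self.channels_with_role("EOG")

    def channel(self, label: str) -> Channel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(label)

    def require_stageable(self) -> None:
        if not self.eeg_channels or not self.eog_channels:
            raise MissingRoleError(
                f"record {self.subject_id!r} needs at least one EEG and one EOG "
                f"channel; roles present: {[c.role for c in self.channels]}"
            )


@dataclass
class Hypnogram:
    """Stage label sequence at a fixed label frequency.

    ``labels`` holds integer stage codes (see :mod:`somnoseg._stages`);
    ``label_frequency`` is labels per second (1/30 Hz for standard 30-s
    epochs).
    """

    labels: np.ndarray
    label_frequency: float = 1.0 / 30.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("hypnogram labels must be one-dimensional")
        if np.any(self.labels < 0) or np.any(self.labels > MASK_CODE):
            raise ValueError("hypnogram contains out-of-vocabulary codes")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def period(self) -> float:
        """Seconds covered by one label; label i spans [i*p, (i+1)*p)."""
        return 1.0 / self.label_frequency

    @property
    def duration(self) -> float:
        return len(self.labels) * self.period

    @property
    def tokens(self) -> list[str]:
        return tokens_of(self.labels)

    @classmethod
    def from_tokens(cls, tokens, label_frequency: float = 1.0 / 30.0) -> "Hypnogram":
        return cls(np.array([code_of(t) for t in tokens], dtype=np.int8), label_frequency)


@dataclass
class PreprocessSpec:
    """Internal rate and outlier-clipping settings."""

    target_rate: float = 128.0
    clip_iqr_multiplier: float = 20.0

    def __post_init__(self):
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.clip_iqr_multiplier <= 0:
            raise ValueError("clip_iqr_multiplier must be positive")


# ---------------------------------------------------------------------------
# Channel role heuristics

_EOG_TOKENS = {"EOG", "ROC", "LOC", "E1", "E2"}
_EEG_TOKENS = {
    "EEG", "C3", "C4", "F3", "F4", "O1", "O2", "FPZ", "CZ", "FZ", "PZ", "OZ",
    "F7", "F8", "T3", "T4", "T5", "T6", "P3", "P4", "A1", "A2",
}


def infer_channel_role(label: str) -> str:
    """Guess EEG/EOG/OTHER from a free-text EDF channel label.

    EDF labels are unconstrained text ("EEG C3-M2", "ROC-A1", "EOG
    horizontal", ...), so roles are assigned by token heuristics; callers
    can override via an explicit channel map.  EOG tokens win over EEG
    tokens because EOG derivations are commonly referenced to scalp sites
    (e.g. "LOC-M2").
    """
    upper = label.upper()
    tokens = set(re.split(r"[^A-Za-z0-9]+", upper)) - {""}
    if "EOG" in upper or tokens & _EOG_TOKENS:
        return "EOG"
    if "EEG" in upper or tokens & _EEG_TOKENS:
        return "EEG"
    return "OTHER"


# ---------------------------------------------------------------------------
# EDF I/O


def read_edf(path, subject_id: str | None = None, dataset_id: str = "",
             channel_roles: dict[str, str] | None = None) -> PSGRecord:
    """Read an EDF/EDF+ file into a :class:`PSGRecord`.

    Parameters
    ----------
    channel_roles
        Optional mapping from channel label to role, overriding the label
        heuristics of :func:`infer_channel_role`.
    """
    path = Path(path)
    signals = _edf.read_edf_file(path)
    if not signals:
        raise _edf.EdfFormatError(f"{path}: no channels")
    channels = []
    for s in signals:
        role = (channel_roles or {}).get(s.label) or infer_channel_role(s.label)
        channels.append(Channel(s.label, role, s.rate, s.samples))
    return PSGRecord(subject_id or path.stem, dataset_id, channels)


def write_edf(record: PSGRecord, path) -> None:
    signals = [
        _edf.EdfSignal(c.label, c.native_rate, np.asarray(c.samples, dtype=np.float64))
        for c in record.channels
    ]
    _edf.write_edf_file(path, signals, patient=record.subject_id or "X")


# ---------------------------------------------------------------------------
# Hypnogram I/O


def read_hypnogram(path, label_frequency: float = 1.0 / 30.0) -> Hypnogram:
    """Read a hypnogram file.

    Two dialects are accepted: one stage token per line, or CSV rows of
    ``onset_sec,duration_sec,stage`` (a header row is skipped if present).
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return Hypnogram(np.empty(0, dtype=np.int8), label_frequency)
    if "," in lines[0] or (len(lines) > 1 and "," in lines[1]):
        period = 1.0 / label_frequency
        events = []
        for row in csv.reader(lines):
            if len(row) < 3:
                continue
            try:
                onset, dur = float(row[0]), float(row[1])
            except ValueError:
                continue  # header
            events.append((onset, dur, row[2].strip()))
        if not events:
            raise ValueError(f"{path}: no parsable onset,duration,stage rows")
        total = max(onset + dur for onset, dur, _ in events)
        n = int(round(total / period))
        codes = np.full(n, MASK_CODE, dtype=np.int8)
        for onset, dur, stage in events:
            i0 = int(round(onset / period))
            i1 = int(round((onset + dur) / period))
            codes[i0:i1] = code_of(stage)
        return Hypnogram(codes, label_frequency)
    return Hypnogram.from_tokens(lines, label_frequency)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    Path(path).write_text("\n".join(hyp.tokens) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing operations


def resample(record: PSGRecord, spec: PreprocessSpec | None = None) -> PSGRecord:
    """Resample every channel to ``spec.target_rate`` via polyphase filtering.

    The rational up/down factors approximate the rate ratio to ≤1e-6
    relative error; for already-matching channels this is the identity.
    """
    spec = spec or PreprocessSpec()
    out = []
    for c in record.channels:
        x = np.asarray(c.samples, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"channel {c.label!r} contains non-finite samples")
        if abs(c.native_rate - spec.target_rate) / spec.target_rate < 1e-9:
            y = x.copy()
        else:
            frac = Fraction(spec.target_rate / c.native_rate).limit_denominator(10**6)
            y = resample_poly(x, frac.numerator, frac.denominator)
        out.append(Channel(c.label, c.role, spec.target_rate, y))
    return replace(record, channels=out)


def robust_scale_clip(record: PSGRecord, spec: PreprocessSpec | None = None) -> PSGRecord:
    """Standardize each channel to median 0 / IQR 1 over the whole recording,
    then clip scaled values beyond ±``clip_iqr_multiplier``.

    A flat channel (IQR 0) is centred on its median and left unscaled, with
    a warning — a degenerate but representable input.
    """
    spec = spec or PreprocessSpec()
    out = []
    for c in record.channels:
        x = np.asarray(c.samples, dtype=np.float64)
        med = np.median(x)
        q75, q25 = np.percentile(x, [75.0, 25.0])
        iqr = q75 - q25
        if iqr <= 0:
            warnings.warn(f"channel {c.label!r} has zero IQR; centring only")
            y = x - med
        else:
            y = (x - med) / iqr
        m = spec.clip_iqr_multiplier
        out.append(Channel(c.label, c.role, c.native_rate, np.clip(y, -m, m)))
    return replace(record, channels=out)


def align_and_strip(record: PSGRecord, hyp: Hypnogram) -> tuple[PSGRecord, Hypnogram]:
    """Trim signal outside the scored hypnogram span.

    Label i covers the half-open interval [i·p, (i+1)·p) seconds.  Trailing
    signal beyond the last whole label period is stripped; a hypnogram
    longer than the signal (beyond one label period of slack) is an error.
    """
    span = hyp.duration
    if span > record.duration + hyp.period + 1e-9:
        raise LengthMismatchError(
            f"hypnogram spans {span:.1f}s but signal only {record.duration:.1f}s"
        )
    n_labels = min(len(hyp), int(np.floor(record.duration / hyp.period + 1e-9)))
    span = n_labels * hyp.period
    out = []
    for c in record.channels:
        n = int(round(span * c.native_rate))
        out.append(Channel(c.label, c.role, c.native_rate, np.asarray(c.samples)[:n]))
    return replace(record, channels=out), Hypnogram(hyp.labels[:n_labels], hyp.label_frequency)


def normalize_stages(raw_labels, label_frequency: float = 1.0 / 30.0) -> Hypnogram:
    """Map raw annotation tokens onto {W, N1, N2, N3, REM, MASK}.

    S3/S4 merge into N3; MOVEMENT, UNKNOWN and any unrecognized token
    become MASK.  The mapping is total and idempotent on its own output.
    """
    return Hypnogram.from_tokens(raw_labels, label_frequency)


def enumerate_channel_pairs(record: PSGRecord) -> list[tuple[str, str]]:
    """All (EEG label, EOG label) combinations, EEG-major in file order."""
    record.require_stageable()
    return [(e.label, o.label) for e in record.eeg_channels for o in record.eog_channels]


def preprocess(record: PSGRecord, spec: PreprocessSpec | None = None,
               hyp: Hypnogram | None = None):
    """Full pipeline: resample → robust scale/clip → (optional) strip to hypnogram.

    Returns the preprocessed record, or ``(record, hypnogram)`` when a
    hypnogram is supplied.
    """
    spec = spec or PreprocessSpec()
    rec = robust_scale_clip(resample(record, spec), spec)
    if hyp is None:
        return rec
    return align_and_strip(rec, hyp)
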