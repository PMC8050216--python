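"""High-frequency staging analysis: transition triplets and cohort
classification.

A *transition triplet* is an ordered stage sequence (s1, s2, s3) over
{W, N1, N2, N3, REM} with s1 ≠ s2 and s2 ≠ s3 — a fast excursion through
s2, e.g. (N3, W, N1).  Exactly 5·4·4 = 80 such triplets exist; their
occurrence rates, counted on the run-length-compressed label sequence of
each 1.5-h sleep segment and normalized to occurrences per hour, form a
frequency-invariant 80-dimensional feature vector.

Cohort classification follows a deliberately randomized protocol: per
repetition one random-forest hyperparameter configuration is drawn (200
trees, Gini impurity, balanced class weights, max_depth / min_samples_leaf /
min_samples_split ∈ {2..7}, max_features ∈ {sqrt, log2}), leave-one-subject-
out cross-validation is run with per-subject majority voting over 1.5-h
segments (random tie-breaks), and the unweighted two-class mean F1 is
recorded; 50 repetitions give a mean ± SD that is robust to any single
hyperparameter choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score as _sk_f1

from ._stages import MASK_CODE, N_STAGES, STAGES
from .io import Hypnogram

__all__ = [
    "TRIPLETS",
    "TripletFeatures",
    "RFProtocol",
    "DEFAULT_FREQUENCIES",
    "sleep_bounds",
    "triplet_rates",
    "classify_cohort",
    "frequency_sweep",
    "majority_class_mean_f1",
]

#: Canonical slot order: lexicographic over (s1, s2, s3) stage indices with
#: s1 ≠ s2 and s2 ≠ s3.  Exactly 80 entries.
TRIPLETS: tuple[tuple[str, str, str], ...] = tuple(
    (STAGES[a], STAGES[b], STAGES[c])
    for a, b, c in product(range(N_STAGES), repeat=3)
    if a != b and b != c
)

_TRIPLET_INDEX = {t: k for k, t in enumerate(TRIPLETS)}

#: The evaluation grid in labels per minute, from one label per 30 s up to
#: one label per sample at the internal 128 Hz rate (7680/min).
DEFAULT_FREQUENCIES: tuple[int, ...] = (
    2, 4, 8, 16, 32, 64, 128, 256, 512, 768, 1280, 1920, 3840, 7680)


@dataclass
class TripletFeatures:
    subject_id: str
    frequency: float  # labels per minute
    segment_index: int  # 1.5-h window index within the sleep period
    rates: np.ndarray  # (80,) occurrences per hour

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (len(TRIPLETS),):
            raise ValueError(f"expected {len(TRIPLETS)} feature slots")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class RFProtocol:
    n_trees: int = 200
    max_depth_range: tuple[int, ...] = tuple(range(2, 8))
    min_samples_leaf_range: tuple[int, ...] = tuple(range(2, 8))
    min_samples_split_range: tuple[int, ...] = tuple(range(2, 8))
    max_features_options: tuple[str, ...] = ("sqrt", "log2")
    repetitions: int = 50
    seed: int = 0

    def draw_hyperparameters(self, rng: np.random.Generator) -> dict:
        return {
            "n_estimators": self.n_trees,
            "criterion": "gini",
            "class_weight": "balanced",  # w_c = n / (k * n_c)
            "max_depth": int(rng.choice(self.max_depth_range)),
            "min_samples_leaf": int(rng.choice(self.min_samples_leaf_range)),
            "min_samples_split": int(rng.choice(self.min_samples_split_range)),
            "max_features": str(rng.choice(self.max_features_options)),
        }


def sleep_bounds(two_per_min: Hypnogram) -> tuple[int, int]:
    """Sleep onset / end from a 2 labels-per-minute hypnogram.

    Onset is the first non-Wake (and non-MASK) label, end the last;
    downstream analysis restricts to the inclusive index range.  A
    hypnogram with no sleep raises ``ValueError`` (subject excluded).
    """
    asleep = np.flatnonzero((two_per_min.labels != 0) & (two_per_min.labels != MASK_CODE))
    if len(asleep) == 0:
        raise ValueError("no sleep stage found; subject excluded from analysis")
    return int(asleep[0]), int(asleep[-1])


def _run_length_compress(labels: np.ndarray) -> np.ndarray:
    if len(labels) == 0:
        return labels
    keep = np.empty(len(labels), dtype=bool)
    keep[0] = True
    keep[1:] = labels[1:] != labels[:-1]
    return labels[keep]


def triplet_rates(labels: Hypnogram, subject_id: str = "", segment_hours: float = 1.5
                  ) -> list[TripletFeatures]:
    """Triplet occurrence rates per non-overlapping ``segment_hours`` window.

    ``labels`` should already be restricted to the sleep period (see
    :func:`sleep_bounds`).  Within each window, consecutive duplicate
    labels are merged and every consecutive triple (s1, s2, s3) of the
    compressed sequence with s1 ≠ s2 and s2 ≠ s3 increments its slot;
    MASK labels break the sequence.  Counts are divided by the window
    duration, giving occurrences per hour.  A trailing partial window is
    dropped.
    """
    freq_per_min = labels.label_frequency * 60.0
    window = int(round(segment_hours * 3600.0 * labels.label_frequency))
    if window < 3:
        raise ValueError("segment too short for the label frequency")
    out = []
    n_windows = len(labels) // window
    for w in range(n_windows):
        chunk = labels.labels[w * window : (w + 1) * window]
        counts = np.zeros(len(TRIPLETS), dtype=np.float64)
        # MASK splits the chunk into independent runs.
        for run in np.split(chunk, np.flatnonzero(chunk == MASK_CODE)):
            run = run[run != MASK_CODE]
            comp = _run_length_compress(run)
            for k in range(len(comp) - 2):
                a, b, c = int(comp[k]), int(comp[k + 1]), int(comp[k + 2])
                if a != b and b != c:
                    counts[_TRIPLET_INDEX[(STAGES[a], STAGES[b], STAGES[c])]] += 1
        out.append(TripletFeatures(subject_id, freq_per_min, w, counts / segment_hours))
    return out


def features_to_frame(features: dict[str, list["TripletFeatures"]]) -> pd.DataFrame:
    """Flatten per-subject features into a table with one named column per
    triplet slot (``W>N1>W`` etc.), suitable for CSV export."""
    names = [">".join(t) for t in TRIPLETS]
    rows = []
    for sid, feats in features.items():
        for f in feats:
            row = {"subject": sid, "segment": f.segment_index, "frequency": f.frequency}
            row.update(dict(zip(names, f.rates)))
            rows.append(row)
    return pd.DataFrame(rows)


def majority_class_mean_f1(n_majority: int, n_minority: int) -> float:
    """Mean two-class F1 of a constant majority-class predictor:
    (2·n_maj/(2·n_maj + n_min) + 0) / 2."""
    return 0.5 * (2.0 * n_majority / (2.0 * n_majority + n_minority))


def classify_cohort(features: dict[str, list[TripletFeatures]],
                    labels: dict[str, int],
                    protocol: RFProtocol | None = None) -> np.ndarray:
    """Leave-one-subject-out cohort classification.

    Parameters
    ----------
    features
        Per-subject lists of 1.5-h segment feature vectors.
    labels
        Per-subject class (0 = control, 1 = case).

    Returns the vector of per-repetition unweighted two-class mean F1
    scores (length ``protocol.repetitions``).
    """
    protocol = protocol or RFProtocol()
    rng = np.random.default_rng(protocol.seed)
    subjects = [s for s in features if features[s]]
    for s in features:
        if not features[s]:
            warnings.warn(f"subject {s!r} has no 1.5-h segments; excluded")
    y_subj = np.array([labels[s] for s in subjects])
    if len(np.unique(y_subj)) < 2 or min(np.bincount(y_subj)) < 2:
        raise ValueError("need at least 2 subjects in each class")
    X_by_subj = {s: np.stack([f.rates for f in features[s]]) for s in subjects}

    scores = np.empty(protocol.repetitions)
    for rep in range(protocol.repetitions):
        params = protocol.draw_hyperparameters(rng)
        predictions = np.empty(len(subjects), dtype=int)
        for held in range(len(subjects)):
            X_train = np.concatenate(
                [X_by_subj[s] for k, s in enumerate(subjects) if k != held])
            y_train = np.concatenate(
                [np.full(len(X_by_subj[s]), y_subj[k])
                 for k, s in enumerate(subjects) if k != held])
            clf = RandomForestClassifier(
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1, **params)
            clf.fit(X_train, y_train)
            seg_pred = clf.predict(X_by_subj[subjects[held]])
            votes = np.bincount(seg_pred, minlength=2)
            if votes[0] == votes[1]:
                predictions[held] = int(rng.integers(2))  # random tie-break
            else:
                predictions[held] = int(votes.argmax())
        scores[rep] = _sk_f1(y_subj, predictions, average="macro", zero_division=0)
    return scores


def frequency_sweep(model, cohort, labels: dict[str, int],
                    frequencies=DEFAULT_FREQUENCIES,
                    protocol: RFProtocol | None = None,
                    period_anchor_per_min: float = 2.0,
                    segment_hours: float = 1.5) -> pd.DataFrame:
    """Classification performance across output label frequencies.

    ``cohort`` maps subject ids to preprocessed :class:`PSGRecord`s.  For
    each subject the 2/min majority-voted prediction fixes the sleep
    bounds; for each requested frequency the majority-voted labels inside
    those bounds are converted to triplet features and classified.
    Returns a table with columns ``frequency``, ``mean_f1``, ``sd_f1``.
    """
    from .inference import majority_vote, predict_record  # local import: cycle

    protocol = protocol or RFProtocol()
    rate = model.config.internal_rate
    for f in frequencies:
        if (rate * 60.0) % f:
            raise ValueError(f"{f}/min does not give a whole sample count at {rate} Hz")

    bounds: dict[str, tuple[float, float]] = {}
    for subject, record in cohort.items():
        hyp2 = majority_vote(predict_record(model, record, period_s=60.0 / period_anchor_per_min))
        try:
            a, b = sleep_bounds(hyp2)
        except ValueError:
            warnings.warn(f"subject {subject!r} shows no sleep; excluded")
            continue
        p = hyp2.period
        bounds[subject] = (a * p, (b + 1) * p)  # seconds

    rows = []
    for f in frequencies:
        period_s = 60.0 / f
        feats: dict[str, list[TripletFeatures]] = {}
        for subject, (t0, t1) in bounds.items():
            hyp = majority_vote(predict_record(model, cohort[subject], period_s=period_s))
            i0, i1 = int(round(t0 / period_s)), int(round(t1 / period_s))
            restricted = Hypnogram(hyp.labels[i0:i1], hyp.label_frequency)
            feats[subject] = triplet_rates(restricted, subject_id=subject,
                                           segment_hours=segment_hours)
        scores = classify_cohort(feats, labels, protocol)
        rows.append({"frequency": f, "mean_f1": float(scores.mean()),
                     "sd_f1": float(scores.std(ddof=0))})
    return pd.DataFrame(rows)
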