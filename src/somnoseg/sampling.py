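"""Training batch composition and signal augmentations.

Batch elements are drawn through a four-level hierarchy:

1. **Dataset** — with probability ``P(D) = α/N + (1−α)·size_D/Σsize``,
   a convex blend of uniform-over-datasets and proportional-to-size
   sampling (``size`` = number of PSG records).  α = 0.5 weighs cohorts
   and individual records equally.
2. **Record** — uniform within the dataset.
3. **Channel pair** — one EEG and one EOG channel, uniform over the
   record's montage.
4. **Segment** — class-balanced placement: a stage is drawn uniformly
   from {W, N1, N2, N3, REM}, an epoch carrying that stage is drawn
   uniformly, and the T-epoch window is shifted so the anchor epoch sits
   at a uniform position inside it.  This guarantees rare stages are
   visited even though the remaining T−1 epochs stay imbalanced.

Augmentation replaces, per element and independently, (a) with
probability 0.1 a contiguous block covering a log-uniform fraction in
[0.001, 0.3] of one channel, and (b) with probability 0.1 one entire
channel, by Gaussian noise N(μ̂, σ²=0.01) centred on the element's
empirical signal mean.  Labels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stages import MASK_CODE, N_STAGES
from .io import Hypnogram, PSGRecord, enumerate_channel_pairs

__all__ = [
    "DatasetCollection",
    "SegmentBatch",
    "AugmentSpec",
    "dataset_probabilities",
    "sample_batch_element",
    "sample_batch",
    "augment",
]


@dataclass
class DatasetCollection:
    """Named datasets of (record, hypnogram) pairs with a mixing weight α."""

    datasets: list[tuple[str, list[tuple[PSGRecord, Hypnogram]]]]
    alpha: float = 0.5

    def __post_init__(self):
        if not self.datasets:
            raise ValueError("collection must contain at least one dataset")
        if any(not records for _, records in self.datasets):
            raise ValueError("every dataset must be non-empty")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(records) for _, records in self.datasets])

    @property
    def dataset_ids(self) -> list[str]:
        return [d for d, _ in self.datasets]


@dataclass
class SegmentBatch:
    """A batch of (T·i)-sample two-channel windows with per-epoch labels."""

    signals: np.ndarray  # (B, 2, T*i) float32
    labels: np.ndarray  # (B, T) int8
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_predictions(self) -> int:
        """Stage predictions produced per training step on this batch."""
        return int(self.labels.size)


@dataclass
class AugmentSpec:
    p_partial: float = 0.1
    fraction_range: tuple[float, float] = (0.001, 0.3)
    p_channel: float = 0.1
    noise_variance: float = 0.01

    def __post_init__(self):
        if not (0 <= self.p_partial <= 1 and 0 <= self.p_channel <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("fraction bounds must lie within (0, 1]")


def dataset_probabilities(collection: DatasetCollection) -> np.ndarray:
    """P(D) = α·(1/N) + (1−α)·size_D/Σ size (sums to 1 by construction)."""
    sizes = collection.sizes.astype(np.float64)
    n = len(sizes)
    return collection.alpha / n + (1.0 - collection.alpha) * sizes / sizes.sum()


def _segment_samples(record: PSGRecord, hyp: Hypnogram) -> int:
    rate = record.channels[0].native_rate
    i = hyp.period * rate
    return int(round(i))


def sample_batch_element(collection: DatasetCollection, T: int, i: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw one training window through the four-level hierarchy.

    Returns ``(signals (2, T·i) float32, labels (T,) int8, provenance)``.
    Records shorter than T epochs are left-aligned, zero-padded in signal
    and MASK-padded in labels, flagged ``padded`` in provenance.
    """
    probs = dataset_probabilities(collection)
    d = int(rng.choice(len(probs), p=probs))
    dataset_id, records = collection.datasets[d]
    r = int(rng.integers(len(records)))
    record, hyp = records[r]
    pairs = enumerate_channel_pairs(record)
    eeg_label, eog_label = pairs[int(rng.integers(len(pairs)))]
    labels = hyp.labels
    n_epochs = len(labels)
    i_rec = _segment_samples(record, hyp)
    if i_rec != i:
        raise ValueError(
            f"record {record.subject_id!r} has {i_rec} samples per epoch, expected {i}; "
            "preprocess the collection to the model's internal rate first")

    # Class-balanced anchor: draw a stage, redraw up to 5 times if absent,
    # otherwise fall back to uniform temporal placement.
    anchor = anchor_stage = None
    for _ in range(5):
        stage = int(rng.integers(N_STAGES))
        pool = np.flatnonzero(labels == stage)
        if len(pool):
            anchor = int(pool[int(rng.integers(len(pool)))])
            anchor_stage = stage
            break
    padded = n_epochs < T
    if anchor is None:
        start = int(rng.integers(max(n_epochs - T, 0) + 1))
    else:
        # Anchor lands at a uniform offset inside the window, clamped to
        # keep the window inside the record.
        start = anchor - int(rng.integers(T))
        start = min(max(start, 0), max(n_epochs - T, 0))

    eeg = record.channel(eeg_label).samples
    eog = record.channel(eog_label).samples
    sig = np.zeros((2, T * i), dtype=np.float32)
    lab = np.full(T, MASK_CODE, dtype=np.int8)
    n_take = min(T, n_epochs - start)
    s0 = start * i
    sig[0, : n_take * i] = eeg[s0 : s0 + n_take * i]
    sig[1, : n_take * i] = eog[s0 : s0 + n_take * i]
    lab[:n_take] = labels[start : start + n_take]
    prov = {
        "dataset": dataset_id,
        "subject": record.subject_id,
        "pair": (eeg_label, eog_label),
        "start_epoch": start,
        "anchor_stage": anchor_stage,
        "anchor_epoch": anchor,
        "padded": padded,
    }
    return sig, lab, prov


def sample_batch(collection: DatasetCollection, batch_size: int, T: int, i: int,
                 rng: np.random.Generator) -> SegmentBatch:
    sigs, labs, prov = [], [], []
    for _ in range(batch_size):
        s, l, p = sample_batch_element(collection, T, i, rng)
        sigs.append(s)
        labs.append(l)
        prov.append(p)
    return SegmentBatch(np.stack(sigs), np.stack(labs), prov)


def augment(batch: SegmentBatch, spec: AugmentSpec, rng: np.random.Generator) -> SegmentBatch:
    """Apply the two noise augmentations in place and return the batch."""
    B, C, L = batch.signals.shape
    sd = float(np.sqrt(spec.noise_variance))
    lo, hi = spec.fraction_range
    for b in range(B):
        mu = float(batch.signals[b].mean())
        if rng.random() < spec.p_partial:
            ch = int(rng.integers(C))
            frac = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            n = max(1, int(round(frac * L)))
            start = int(rng.integers(L - n + 1))
            batch.signals[b, ch, start : start + n] = rng.normal(mu, sd, n)
        if rng.random() < spec.p_channel:
            ch = int(rng.integers(C))
            batch.signals[b, ch] = rng.normal(mu, sd, L)
    return batch
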