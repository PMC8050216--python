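"""End-to-end training with masked cross-entropy and early stopping.

One gradient step processes a batch of ``batch_size`` windows of ``T``
30-s segments each (the full-scale defaults 64 × 35 yield 2240 stage
predictions per step).  The loss is the unweighted cross-entropy averaged
over unmasked segment positions; segments labelled MASK are seen by the
network but contribute nothing to the loss or its gradient.  Training
stops after ``patience`` epochs without validation-loss improvement and
the best-validation parameters are retained.

Full-scale defaults follow the published protocol (η = 1e-7, 443 steps
per epoch, patience 100); :meth:`TrainSpec.desk_scale` returns a profile
sized for minutes-long CPU runs on synthetic cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._stages import MASK_CODE
from .inference import evaluate_record, f1_scores, pooled_confusion
from .io import Hypnogram
from .model import StagePosterior, USleepNet
from .nn import masked_softmax_xent
from .sampling import AugmentSpec, DatasetCollection, augment, sample_batch

logger = logging.getLogger(__name__)

__all__ = ["TrainSpec", "TrainResult", "masked_cross_entropy", "train"]


@dataclass
class TrainSpec:
    batch_size: int = 64
    T: int = 35
    period_s: float = 30.0
    learning_rate: float = 1e-7
    steps_per_epoch: int = 443
    patience: int = 100
    max_epochs: int = 10_000
    seed: int = 0
    augment: AugmentSpec | None = None

    def __post_init__(self):
        if min(self.batch_size, self.T, self.steps_per_epoch, self.max_epochs) < 1:
            raise ValueError("all counts must be positive")
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")

    @property
    def predictions_per_step(self) -> int:
        return self.batch_size * self.T

    @property
    def window_seconds(self) -> float:
        return self.T * self.period_s

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainSpec":
        """A profile sized for CPU smoke runs on synthetic cohorts."""
        spec = cls(batch_size=8, T=9, learning_rate=1e-4, steps_per_epoch=50,
                   patience=10, max_epochs=30)
        return replace(spec, **overrides)


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict
    best_epoch: int
    model: USleepNet


def masked_cross_entropy(posteriors, labels) -> float:
    """Mean −log p(true stage) over non-MASK positions.

    ``posteriors`` may be a (B, T, K) / (T, K) probability array or a
    :class:`StagePosterior`; ``labels`` the matching integer codes.
    Returns 0.0 (with a warning) when every position is masked.
    """
    if isinstance(posteriors, StagePosterior):
        posteriors = posteriors.values
    p = np.asarray(posteriors, dtype=np.float64)
    y = np.asarray(labels)
    if p.ndim == 2:
        p, y = p[None], y[None]
    valid = y != MASK_CODE
    if not valid.any():
        warnings.warn("all positions masked; loss is 0 by convention")
        return 0.0
    safe = np.where(valid, y, 0)
    picked = np.take_along_axis(p, safe[..., None], axis=-1)[..., 0]
    return float(-np.log(np.maximum(picked[valid], 1e-12)).mean())


def _validation_metrics(model: USleepNet, collection: DatasetCollection, i: int):
    """Pooled validation loss and per-dataset mean F1 (first channel pair)."""
    losses, weights = [], []
    per_dataset_f1 = {}
    for dataset_id, records in collection.datasets:
        cms = []
        for record, hyp in records:
            eeg = record.eeg_channels[0].samples
            eog = record.eog_channels[0].samples
            L = min(len(eeg), len(hyp) * i)
            T = L // i
            if T == 0:
                continue
            x = np.stack([eeg[: T * i], eog[: T * i]])[None].astype(np.float32)
            probs = model.predict_proba(x, i)[0]
            y = hyp.labels[:T]
            if np.any(y != MASK_CODE):
                losses.append(masked_cross_entropy(probs, y))
                weights.append(int((y != MASK_CODE).sum()))
            pred = Hypnogram(probs.argmax(axis=1).astype(np.int8), hyp.label_frequency)
            cms.append(evaluate_record(pred, Hypnogram(y, hyp.label_frequency)))
        if cms:
            per_dataset_f1[dataset_id] = f1_scores(pooled_confusion(cms))["mean"]
    if not losses:
        return np.nan, per_dataset_f1
    return float(np.average(losses, weights=weights)), per_dataset_f1


def train(model: USleepNet, collection: DatasetCollection, spec: TrainSpec,
          val_collection: DatasetCollection | None = None) -> TrainResult:
    """Train ``model`` on ``collection`` under ``spec``.

    The collection must already be preprocessed to the model's internal
    rate.  With no validation collection, early stopping is disabled (a
    warning is emitted) and training runs to ``max_epochs``.
    """
    rng = np.random.default_rng(spec.seed)
    i = model.config.segment_samples(spec.period_s)
    optimizer = model.make_optimizer(spec.learning_rate)
    if val_collection is None:
        warnings.warn("no validation collection: early stopping disabled")

    rows = []
    best_loss = np.inf
    best_state = model.state_arrays()
    best_epoch = 0
    stale = 0
    for epoch in range(1, spec.max_epochs + 1):
        epoch_losses = []
        for _ in range(spec.steps_per_epoch):
            batch = sample_batch(collection, spec.batch_size, spec.T, i, rng)
            if spec.augment is not None:
                batch = augment(batch, spec.augment, rng)
            optimizer.zero_grad()
            z, _ = model.forward(batch.signals, i, train=True)
            loss, dz = masked_softmax_xent(z, batch.labels, MASK_CODE)
            model.backward(dz)
            optimizer.step()
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))

        val_loss, val_f1 = (np.nan, {})
        if val_collection is not None:
            val_loss, val_f1 = _validation_metrics(model, val_collection, i)
        row = {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        row.update({f"val_f1_{d}": v for d, v in val_f1.items()})
        rows.append(row)
        logger.info("epoch %d train_loss=%.4f val_loss=%s", epoch, train_loss, val_loss)

        if val_collection is not None and np.isfinite(val_loss):
            if val_loss < best_loss - 1e-12:
                best_loss, best_state, best_epoch, stale = (
                    val_loss, model.state_arrays(), epoch, 0)
            else:
                stale += 1
                if stale >= spec.patience:
                    break
        else:
            best_state, best_epoch = model.state_arrays(), epoch

    if val_collection is not None:
        model.load_state_arrays(best_state)
    return TrainResult(pd.DataFrame(rows), best_state, best_epoch, model)
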