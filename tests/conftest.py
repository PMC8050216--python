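"""Shared fixtures: small synthetic records and collections.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import somnoseg as ss


def make_cohort_records(n_subjects: int, epochs: int, montage, native_rate: float,
                        dataset_id: str, seed: int, mask_rate: float = 0.02):
    """Generate preprocessed (record, hypnogram) pairs at 128 Hz."""
    rng = np.random.default_rng(seed)
    spec = ss.CohortSpec(
        n_subjects=n_subjects, montage=tuple(montage), native_rate=native_rate,
        record_hours=epochs * 30.0 / 3600.0, mask_rate=mask_rate,
        dataset_id=dataset_id)
    out = []
    for s in range(n_subjects):
        rec, hyp = ss.generate_record(spec, rng, f"{dataset_id}-{s:03d}")
        rec = ss.robust_scale_clip(ss.resample(rec))
        out.append((rec, hyp))
    return out


@pytest.fixture(scope="session")
def four_channel_record():
    """One 256 Hz record with 2 EEG + 2 EOG channels and its hypnogram."""
    records = make_cohort_records(1, 12, ("C3-M2", "C4-M1", "ROC-M1", "LOC-M2"),
                                  256.0, "quad", seed=7)
    return records[0]


@pytest.fixture(scope="session")
def small_collection():
    """Two heterogeneous datasets (sizes 4 and 2) preprocessed to 128 Hz."""
    a = make_cohort_records(4, 12, ("C3-M2", "ROC-M1"), 128.0, "dsA", seed=11)
    b = make_cohort_records(2, 12, ("Fpz-Cz", "EOG horizontal"), 128.0, "dsB", seed=12)
    return ss.DatasetCollection([("dsA", a), ("dsB", b)])


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained network usable on short inputs."""
    return ss.build_model(ss.ModelConfig(depth=4, base_filters=3), seed=5)
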