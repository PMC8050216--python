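"""Batch composition hierarchy and augmentations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somnoseg as ss
from somnoseg._stages import MASK_CODE
from tests.conftest import make_cohort_records

I_128 = 3840  # samples per 30-s epoch at 128 Hz


class TestDatasetProbabilities:
    def test_pure_size_weighting(self):
        coll = _collection_with_sizes([100, 10], alpha=0.0)
        p = ss.dataset_probabilities(coll)
        assert p[0] / p[1] == pytest.approx(10.0)

    def test_pure_uniform(self):
        coll = _collection_with_sizes([100, 10, 3], alpha=1.0)
        assert np.allclose(ss.dataset_probabilities(coll), 1 / 3)

    def test_blended_value(self):
        coll = _collection_with_sizes([100, 10], alpha=0.5)
        p = ss.dataset_probabilities(coll)
        assert np.allclose(p, [0.5 * 0.5 + 0.5 * 100 / 110,
                               0.5 * 0.5 + 0.5 * 10 / 110])

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=6),
           st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, sizes, alpha):
        coll = _collection_with_sizes(sizes, alpha=alpha)
        assert ss.dataset_probabilities(coll).sum() == pytest.approx(1.0)


def _collection_with_sizes(sizes, alpha):
    """Datasets whose record lists only need a length (probabilities only)."""
    datasets = [(f"d{k}", [object()] * n) for k, n in enumerate(sizes)]
    return ss.DatasetCollection(datasets, alpha=alpha)


@pytest.fixture(scope="module")
def sampler_collection():
    a = make_cohort_records(3, 10, ("C3-M2", "C4-M1", "ROC-M1", "LOC-M2"),
                            128.0, "sa", seed=21)
    b = make_cohort_records(2, 10, ("Fpz-Cz", "EOG horizontal"), 128.0, "sb", seed=22)
    return ss.DatasetCollection([("sa", a), ("sb", b)])


class TestSampleBatchElement:
    def test_window_contains_anchor_class(self, sampler_collection):
        rng = np.random.default_rng(0)
        for _ in range(200):
            sig, lab, prov = ss.sample_batch_element(sampler_collection, 4, I_128, rng)
            assert sig.shape == (2, 4 * I_128)
            assert lab.shape == (4,)
            if prov["anchor_stage"] is not None:
                assert prov["anchor_stage"] in lab

    def test_channel_pairs_uniform(self, sampler_collection):
        rng = np.random.default_rng(1)
        quad = ss.DatasetCollection([("sa", sampler_collection.datasets[0][1])])
        counts = {}
        n = 2000
        for _ in range(n):
            _, _, prov = ss.sample_batch_element(quad, 2, I_128, rng)
            counts[prov["pair"]] = counts.get(prov["pair"], 0) + 1
        assert len(counts) == 4
        se = np.sqrt(0.25 * 0.75 / n)
        for c in counts.values():
            assert abs(c / n - 0.25) < 4 * se

    def test_short_record_padded(self):
        records = make_cohort_records(1, 3, ("C3-M2", "ROC-M1"), 128.0, "tiny",
                                      seed=23, mask_rate=0.0)
        coll = ss.DatasetCollection([("tiny", records)])
        rng = np.random.default_rng(2)
        sig, lab, prov = ss.sample_batch_element(coll, 5, I_128, rng)
        assert prov["padded"]
        assert np.all(lab[3:] == MASK_CODE)
        assert np.all(sig[:, 3 * I_128 :] == 0.0)

    def test_rate_mismatch_rejected(self):
        records = make_cohort_records(1, 3, ("C3-M2", "ROC-M1"), 128.0, "x", seed=1)
        coll = ss.DatasetCollection([("x", records)])
        with pytest.raises(ValueError, match="samples per epoch"):
            ss.sample_batch_element(coll, 2, 3000, np.random.default_rng(0))

    def test_seeded_determinism(self, sampler_collection):
        b1 = ss.sample_batch(sampler_collection, 6, 3, I_128, np.random.default_rng(99))
        b2 = ss.sample_batch(sampler_collection, 6, 3, I_128, np.random.default_rng(99))
        assert np.array_equal(b1.signals, b2.signals)
        assert np.array_equal(b1.labels, b2.labels)
        assert b1.provenance == b2.provenance

    def test_anchor_class_balanced(self):
        """Each stage anchors ~1/5 of draws on a record containing all 5."""
        rng = np.random.default_rng(3)
        records = make_cohort_records(1, 60, ("C3-M2", "ROC-M1"), 128.0, "all5",
                                      seed=24, mask_rate=0.0)
        hyp = records[0][1]
        if len(np.unique(hyp.labels)) < 5:  # ensure the premise holds
            hyp.labels[:5] = np.arange(5)
        coll = ss.DatasetCollection([("all5", records)])
        n = 1500
        counts = np.zeros(5)
        for _ in range(n):
            _, _, prov = ss.sample_batch_element(coll, 3, I_128, rng)
            counts[prov["anchor_stage"]] += 1
        se = np.sqrt(0.2 * 0.8 / n)
        assert np.all(np.abs(counts / n - 0.2) < 4 * se)


class TestAugment:
    def _batch(self, n=32, T=2, i=256, seed=0):
        rng = np.random.default_rng(seed)
        sig = rng.normal(3.0, 1.0, (n, 2, T * i)).astype(np.float32)
        lab = rng.integers(0, 5, (n, T)).astype(np.int8)
        return ss.SegmentBatch(sig.copy(), lab.copy()), sig, lab

    def test_zero_probability_is_identity(self):
        batch, sig, lab = self._batch()
        spec = ss.AugmentSpec(p_partial=0.0, p_channel=0.0)
        out = ss.augment(batch, spec, np.random.default_rng(1))
        assert np.array_equal(out.signals, sig)
        assert np.array_equal(out.labels, lab)

    def test_labels_never_touched(self):
        batch, _, lab = self._batch()
        spec = ss.AugmentSpec(p_partial=1.0, p_channel=1.0)
        out = ss.augment(batch, spec, np.random.default_rng(2))
        assert np.array_equal(out.labels, lab)

    def test_whole_channel_noise_moments(self):
        batch, sig, _ = self._batch(n=64, T=4, i=512)
        mu_hat = batch.signals.mean(axis=(1, 2)).copy()
        spec = ss.AugmentSpec(p_partial=0.0, p_channel=1.0)
        out = ss.augment(batch, spec, np.random.default_rng(3))
        replaced = 0
        for b in range(64):
            for ch in range(2):
                if not np.array_equal(out.signals[b, ch], sig[b, ch]):
                    replaced += 1
                    x = out.signals[b, ch]
                    n = x.size
                    assert abs(x.mean() - mu_hat[b]) < 4 * 0.1 / np.sqrt(n)
                    assert abs(x.var() - 0.01) < 5 * 0.01 * np.sqrt(2 / n)
        assert replaced == 64  # exactly one channel per element at p=1

    def test_partial_block_is_contiguous_single_channel(self):
        batch, sig, _ = self._batch(n=16, T=2, i=512, seed=5)
        spec = ss.AugmentSpec(p_partial=1.0, p_channel=0.0)
        out = ss.augment(batch, spec, np.random.default_rng(4))
        L = sig.shape[-1]
        lo, hi = spec.fraction_range
        for b in range(16):
            changed = [ch for ch in range(2)
                       if not np.array_equal(out.signals[b, ch], sig[b, ch])]
            assert len(changed) == 1
            diff = np.flatnonzero(out.signals[b, changed[0]] != sig[b, changed[0]])
            run = diff[-1] - diff[0] + 1
            assert run <= int(round(hi * L)) + 1
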