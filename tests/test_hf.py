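"""Transition-triplet features and the cohort classification protocol."""

from itertools import product

import numpy as np
import pytest

import somnoseg as ss
from somnoseg._stages import MASK_CODE, STAGES
from somnoseg.hf import TRIPLETS, TripletFeatures, _TRIPLET_INDEX


class TestTripletVocabulary:
    def test_exhaustive_enumeration_oracle(self):
        # independent enumeration of all 125 ordered triples
        oracle = [
            (a, b, c)
            for a in STAGES for b in STAGES for c in STAGES
            if a != b and b != c
        ]
        assert len(oracle) == 80
        assert list(TRIPLETS) == oracle

    def test_serialization_preserves_slot_identity(self, tmp_path):
        """CSV export names every slot; reloading keeps values per triplet."""
        import pandas as pd

        rng = np.random.default_rng(9)
        feats = {"s1": [TripletFeatures("s1", 2.0, 0, rng.uniform(0, 5, 80))]}
        frame = ss.features_to_frame(feats)
        path = tmp_path / "f.csv"
        frame.to_csv(path, index=False)
        back = pd.read_csv(path)
        for k, t in enumerate(TRIPLETS):
            assert back.loc[0, ">".join(t)] == pytest.approx(feats["s1"][0].rates[k])

    def test_slot_order_is_stable_bijection(self):
        assert len(_TRIPLET_INDEX) == 80
        assert TRIPLETS[0] == ("W", "N1", "W")
        assert TRIPLETS[-1] == ("REM", "N3", "REM")
        for k, t in enumerate(TRIPLETS):
            assert _TRIPLET_INDEX[t] == k


class TestSleepBounds:
    def test_first_and_last_sleep_stage(self):
        hyp = ss.normalize_stages(["W", "W", "N1", "N2", "W", "REM", "W"],
                                  label_frequency=1 / 30)
        assert ss.sleep_bounds(hyp) == (2, 5)

    def test_all_wake_excluded(self):
        hyp = ss.normalize_stages(["W"] * 8, label_frequency=1 / 30)
        with pytest.raises(ValueError, match="excluded"):
            ss.sleep_bounds(hyp)

    def test_no_leading_trailing_wake_full_range(self):
        hyp = ss.normalize_stages(["N1", "N2", "REM"], label_frequency=1 / 30)
        assert ss.sleep_bounds(hyp) == (0, 2)

    def test_mask_is_not_sleep(self):
        hyp = ss.normalize_stages(["MOVEMENT", "W", "N2", "W"], label_frequency=1 / 30)
        assert ss.sleep_bounds(hyp) == (2, 2)


def _hyp_2pm(tokens):
    """Hypnogram at 2 labels/min (the 30-s scoring rate)."""
    return ss.normalize_stages(tokens, label_frequency=1 / 30.0)


class TestTripletRates:
    def test_hand_enumerated_counts(self):
        # 1.5 h at 2/min = 180 labels; compressed sequence is [W,N1,W,N1]
        tokens = ["W", "N1", "W"] + ["N1"] * 177
        feats = ss.triplet_rates(_hyp_2pm(tokens), subject_id="s1")
        assert len(feats) == 1
        rates = feats[0].rates
        per_hour = 1 / 1.5
        assert rates[_TRIPLET_INDEX[("W", "N1", "W")]] == pytest.approx(per_hour)
        assert rates[_TRIPLET_INDEX[("N1", "W", "N1")]] == pytest.approx(per_hour)
        assert rates.sum() == pytest.approx(2 * per_hour)

    def test_constant_sequence_is_zero_vector(self):
        feats = ss.triplet_rates(_hyp_2pm(["N2"] * 180))
        assert np.all(feats[0].rates == 0.0)

    def test_trailing_partial_window_dropped(self):
        feats = ss.triplet_rates(_hyp_2pm(["W", "N1"] * 150))  # 2.5 h
        assert len(feats) == 1

    def test_frequency_invariance_of_rates(self):
        """Upsampling labels k-fold at k-fold frequency leaves rates unchanged."""
        base = ["W", "N1", "W", "N2", "N3", "W", "N1"] + ["N2"] * 173
        lo = ss.triplet_rates(_hyp_2pm(base))
        hi_tokens = [t for t in base for _ in range(4)]  # 8 labels/min
        hi = ss.triplet_rates(ss.normalize_stages(hi_tokens, label_frequency=4 / 30.0))
        assert len(lo) == len(hi) == 1
        assert np.allclose(lo[0].rates, hi[0].rates)

    def test_mask_breaks_runs(self):
        # W N1 [MASK] W N1 W : without the break this would count (N1,W,N1)
        tokens = ["W", "N1", "MOVEMENT", "W", "N1", "W"] + ["N2"] * 174
        rates = ss.triplet_rates(_hyp_2pm(tokens))[0].rates
        assert rates[_TRIPLET_INDEX[("N1", "W", "N1")]] == 0.0
        assert rates[_TRIPLET_INDEX[("W", "N1", "W")]] == pytest.approx(1 / 1.5)


def _feature_cohort(rng, n_control, n_case, separation, segments=4):
    """Synthetic per-subject feature lists with a controllable group shift."""
    features, labels = {}, {}
    for group, n, shift in (("c", n_control, 0.0), ("o", n_case, separation)):
        for s in range(n):
            sid = f"{group}{s}"
            labels[sid] = 0 if group == "c" else 1
            features[sid] = [
                TripletFeatures(sid, 2.0, k,
                                np.abs(rng.normal(1.0 + shift, 0.3, len(TRIPLETS))))
                for k in range(segments)
            ]
    return features, labels


class TestClassifyCohort:
    def test_separable_populations_score_one(self):
        rng = np.random.default_rng(0)
        features, labels = _feature_cohort(rng, 6, 8, separation=8.0)
        scores = ss.classify_cohort(features, labels,
                                    ss.RFProtocol(repetitions=3, seed=0))
        assert np.all(scores == 1.0)

    def test_majority_class_baseline_closed_form(self):
        assert ss.majority_class_mean_f1(55, 25) == pytest.approx(0.40740740, abs=1e-6)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        features, labels = _feature_cohort(rng, 4, 5, separation=2.0)
        a = ss.classify_cohort(features, labels, ss.RFProtocol(repetitions=2, seed=3))
        b = ss.classify_cohort(features, labels, ss.RFProtocol(repetitions=2, seed=3))
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        features, labels = _feature_cohort(rng, 3, 3, separation=1.0)
        with pytest.raises(ValueError):
            ss.classify_cohort(features, {k: 1 for k in labels},
                               ss.RFProtocol(repetitions=1))

    def test_hyperparameters_drawn_from_stated_ranges(self):
        protocol = ss.RFProtocol()
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = protocol.draw_hyperparameters(rng)
            assert p["n_estimators"] == 200
            assert p["criterion"] == "gini" and p["class_weight"] == "balanced"
            assert p["max_depth"] in range(2, 8)
            assert p["min_samples_leaf"] in range(2, 8)
            assert p["min_samples_split"] in range(2, 8)
            assert p["max_features"] in ("sqrt", "log2")


class TestFrequencyGrid:
    def test_grid_has_14_entries_up_to_sample_rate(self):
        assert len(ss.DEFAULT_FREQUENCIES) == 14
        assert ss.DEFAULT_FREQUENCIES[0] == 2
        assert ss.DEFAULT_FREQUENCIES[-1] == 7680  # one label per 128 Hz sample

    def test_every_grid_frequency_gives_whole_samples(self):
        for f in ss.DEFAULT_FREQUENCIES:
            assert (128 * 60) % f == 0

    def test_frequency_sweep_on_tiny_cohort(self, tiny_model):
        """End-to-end sweep wiring on a small cohort and two frequencies."""
        import warnings

        from tests.conftest import make_cohort_records

        recs = make_cohort_records(24, 12, ("C3-M2", "ROC-M1"), 128.0, "sw",
                                   seed=51, mask_rate=0.0)
        # apply the pipeline's own exclusion rule up front: subjects whose
        # (untrained) 2/min prediction shows no sleep cannot enter the sweep
        cohort = {}
        for rec, _ in recs:
            hyp2 = ss.majority_vote(ss.predict_record(tiny_model, rec, period_s=30.0))
            try:
                a, b = ss.sleep_bounds(hyp2)
            except ValueError:
                continue
            if b - a + 1 < 3:  # sleep period too short for even one window
                continue
            cohort[rec.subject_id] = rec
            if len(cohort) == 4:
                break
        assert len(cohort) == 4
        labels = {sid: k % 2 for k, sid in enumerate(cohort)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = ss.frequency_sweep(
                tiny_model, cohort, labels, frequencies=(2, 4),
                protocol=ss.RFProtocol(repetitions=1, seed=0), segment_hours=0.025)
        assert list(table["frequency"]) == [2, 4]
        assert table["mean_f1"].between(0, 1).all()

    def test_non_integer_segment_width_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="whole sample"):
            ss.frequency_sweep(tiny_model, {}, {}, frequencies=(7,))
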