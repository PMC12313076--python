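"""Dataset generator: labeling rule, exact counts, determinism, traces."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgaug.fixtures import (
    CLASS_ORDER,
    CTG_FEATURES,
    FixtureConfig,
    generate_dataset,
    generate_trace,
    is_reassuring,
    label_case,
    records_to_frame,
    sample_case,
)


class TestIsReassuring:
    @pytest.mark.parametrize("feature,value,expected", [
        ("fhr_baseline", 140, True),
        ("fhr_baseline", 110, True),     # endpoints inclusive
        ("fhr_baseline", 160, True),
        ("fhr_baseline", 109.9, False),
        ("fhr_baseline", 160.1, False),
        ("baseline_variability", 5, True),
        ("baseline_variability", 25, True),
        ("baseline_variability", 4.9, False),
        ("baseline_variability", 26, False),
        ("accelerations", 2, True),
        ("accelerations", 1, False),
        ("accelerations", 0, False),
        ("deceleration", "none", True),
        ("deceleration", "early", True),
        ("deceleration", "variable", True),
        ("deceleration", "regular", False),
        ("deceleration", "late", False),
        ("deceleration", "prolonged", False),
    ])
    def test_threshold_semantics(self, feature, value, expected):
        assert is_reassuring(feature, value) is expected

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown CTG feature"):
            is_reassuring("uterine_contractions", 3)

    def test_unknown_deceleration_category_rejected(self):
        with pytest.raises(ValueError, match="deceleration"):
            is_reassuring("deceleration", "sinusoidal")


class TestLabelCase:
    @pytest.mark.parametrize("fhr,bv,accel,decel,expected", [
        (140, 10, 2, "none", "normal"),
        (100, 10, 2, "none", "suspicious"),     # one non-reassuring
        (140, 3, 2, "none", "suspicious"),
        (170, 3, 0, "late", "pathological"),    # four non-reassuring
        (100, 3, 2, "none", "pathological"),    # exactly two
    ])
    def test_rule(self, fhr, bv, accel, decel, expected):
        assert label_case(fhr, bv, accel, decel) == expected

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            label_case(140, 10, 2, None)

    def test_exhaustive_pattern_enumeration(self):
        """Brute-force oracle: of the 2^4 reassuring patterns, 1 is normal,
        4 suspicious, 11 pathological, and label_case agrees on each."""
        reassuring_values = {
            "fhr_baseline": 140, "baseline_variability": 10,
            "accelerations": 3, "deceleration": "early",
        }
        non_reassuring_values = {
            "fhr_baseline": 90, "baseline_variability": 30,
            "accelerations": 0, "deceleration": "prolonged",
        }
        counts = {"normal": 0, "suspicious": 0, "pathological": 0}
        for pattern in itertools.product([True, False], repeat=4):
            values = [
                reassuring_values[f] if ok else non_reassuring_values[f]
                for f, ok in zip(CTG_FEATURES, pattern)
            ]
            n_bad = sum(not ok for ok in pattern)
            expected = ("normal" if n_bad == 0
                        else "suspicious" if n_bad == 1 else "pathological")
            assert label_case(*values) == expected
            counts[expected] += 1
        assert counts == {"normal": 1, "suspicious": 4, "pathological": 11}


class TestSampleCase:
    @pytest.mark.parametrize("label,expected_bad", [
        ("normal", {0}), ("suspicious", {1}), ("pathological", {2, 3, 4}),
    ])
    def test_non_reassuring_count_matches_label(self, label, expected_bad, rng):
        for _ in range(50):
            record = sample_case(label, rng)
            bad = sum(
                not is_reassuring(f, getattr(record, f)) for f in CTG_FEATURES
            )
            assert bad in expected_bad
            assert record.label == label
            assert label_case(*(getattr(record, f) for f in CTG_FEATURES)) == label

    def test_clinical_features_within_normal_ranges(self, rng):
        config = FixtureConfig()
        for label in CLASS_ORDER:
            record = sample_case(label, rng, config)
            for name, (lo, hi) in config.clinical_ranges.items():
                assert lo <= getattr(record, name) <= hi

    def test_overlapping_ranges_rejected(self, rng):
        config = FixtureConfig(bv_non_reassuring=((0.0, 10.0), (25.5, 40.0)))
        with pytest.raises(ValueError, match="overlap"):
            sample_case("suspicious", rng, config)


class TestGenerateDataset:
    def test_default_counts_match_reference_distribution(self):
        split = generate_dataset(FixtureConfig(seed=1))
        totals = {cls: 0 for cls in CLASS_ORDER}
        for record in split.train + split.validation:
            totals[record.label] += 1
        assert totals == {"normal": 27_930, "suspicious": 970, "pathological": 500}
        test_totals = {cls: 0 for cls in CLASS_ORDER}
        for record in split.test:
            test_totals[record.label] += 1
        assert test_totals == {"normal": 12_222, "suspicious": 265, "pathological": 113}
        assert len(split.train) + len(split.validation) + len(split.test) == 42_000

    def test_validation_carved_at_configured_fraction(self):
        split = generate_dataset(FixtureConfig(
            train_counts={"normal": 100, "suspicious": 10, "pathological": 10},
            test_counts={"normal": 0, "suspicious": 0, "pathological": 0},
            validation_fraction=0.2, seed=3))
        assert len(split.validation) == 24  # 20 + 2 + 2
        assert len(split.train) == 96
        assert len(split.test) == 0

    def test_empty_config_gives_empty_splits(self):
        split = generate_dataset(FixtureConfig(
            train_counts={}, test_counts={}, seed=0))
        assert split.train == [] and split.validation == [] and split.test == []

    def test_every_label_consistent_with_rule(self):
        config = FixtureConfig(
            train_counts={"normal": 10, "suspicious": 5, "pathological": 5},
            test_counts={}, seed=7)
        split = generate_dataset(config)
        assert len(split.train) + len(split.validation) == 20
        for record in split.train + split.validation:
            derived = label_case(*(getattr(record, f) for f in CTG_FEATURES))
            assert derived == record.label

    def test_label_consistency_at_scale(self):
        config = FixtureConfig(
            train_counts={"normal": 4000, "suspicious": 3000, "pathological": 3000},
            test_counts={}, seed=5)
        split = generate_dataset(config)
        records = split.train + split.validation
        assert len(records) == 10_000
        for record in records:
            assert label_case(*(getattr(record, f) for f in CTG_FEATURES)) == record.label

    def test_same_seed_byte_identical(self):
        config = FixtureConfig(
            train_counts={"normal": 50, "suspicious": 10, "pathological": 5},
            test_counts={"normal": 20, "suspicious": 4, "pathological": 2}, seed=9)
        a = generate_dataset(config)
        b = generate_dataset(config)
        frame_a = records_to_frame(a.train + a.validation + a.test)
        frame_b = records_to_frame(b.train + b.validation + b.test)
        assert frame_a.to_csv(index=False) == frame_b.to_csv(index=False)


class TestGenerateTrace:
    def _case(self, **kw):
        defaults = dict(bp_systolic=120.0, bp_diastolic=80.0, maternal_hr=75.0,
                        spo2=97.0, temperature=98.0, fhr_baseline=140.0,
                        baseline_variability=10.0, accelerations=2,
                        deceleration="none", label="normal")
        defaults.update(kw)
        from ctgaug.fixtures import CaseRecord
        return CaseRecord(**defaults)

    def test_sample_count_is_duration_times_rate(self, rng):
        trace = generate_trace(self._case(), duration=600, sampling_rate=4.0,
                               rng=rng)
        assert trace.n == 2400

    def test_zero_missing_rate_gives_no_missing(self, rng):
        trace = generate_trace(self._case(), missing_rate=0.0, rng=rng)
        assert not np.isnan(trace.s0).any()

    def test_missing_rate_hit_exactly_and_first_sample_observed(self, rng):
        trace = generate_trace(self._case(), duration=600, missing_rate=0.1,
                               rng=rng)
        assert int(np.isnan(trace.s0).sum()) == 240
        assert not np.isnan(trace.s0[0])

    def test_invalid_arguments_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_trace(self._case(), duration=0, rng=rng)
        with pytest.raises(ValueError):
            generate_trace(self._case(), missing_rate=1.0, rng=rng)


@settings(max_examples=30, derandomize=True)
@given(
    fhr=st.floats(60, 210), bv=st.floats(0, 40), accel=st.integers(0, 6),
    decel=st.sampled_from(["none", "early", "variable", "regular", "late", "prolonged"]),
)
def test_label_case_matches_feature_count_oracle(fhr, bv, accel, decel):
    bad = sum([
        not (110 <= fhr <= 160),
        not (5 <= bv <= 25),
        accel < 2,
        decel in ("regular", "late", "prolonged"),
    ])
    expected = "normal" if bad == 0 else "suspicious" if bad == 1 else "pathological"
    assert label_case(fhr, bv, accel, decel) == expected
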