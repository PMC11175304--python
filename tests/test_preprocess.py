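import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from etongue.preprocess import (
    DegenerateScanError,
    MissingSensorError,
    PairingError,
    RangeStats,
    SequenceScan,
    build_instances,
    equalize_ranges,
    feature_matrix,
    fit_range_stats,
    normalize_to_first,
    prepare_dataset,
    prepare_raw,
    subsample,
    to_sequence,
)
from etongue.syndata import generate_dataset
from tests.conftest import scaled_config


def seq(values, sensor="CNP", scan_index=0, mid="m", cultivar="perino", eid="e0"):
    return SequenceScan(
        values=np.asarray(values, dtype=float), sensor=sensor, cultivar=cultivar,
        electrode_id=eid, scan_index=scan_index, measurement_id=mid,
    )


class TestToSequence:
    def test_order_preserving_copy(self, small_dataset):
        scan = small_dataset[0].scans[0]
        s = to_sequence(scan)
        assert s.values.size == scan.current.size
        np.testing.assert_array_equal(s.values, scan.current)
        # order sensitivity: the reversed trace is a different sequence
        rev = scan.current[::-1]
        assert not np.array_equal(s.values, rev)

    def test_provenance_preserved(self, small_dataset):
        scan = small_dataset[0].scans[1]
        s = to_sequence(scan)
        assert (s.sensor, s.cultivar, s.scan_index) == (
            scan.sensor, scan.cultivar, scan.scan_index
        )


class TestNormalizeToFirst:
    def test_first_scan_is_identity(self):
        scans = [seq([1.0, 5.0, 3.0], scan_index=0), seq([0.0, 9.0], scan_index=1)]
        out = normalize_to_first(scans)
        np.testing.assert_array_equal(out[0].values, scans[0].values)

    def test_hand_computed_affine_map(self):
        # first scan spans [10, 20]; s = [0, 1, 2] must map to [10, 15, 20]
        scans = [seq([10.0, 20.0], scan_index=0),
                 seq([0.0, 1.0, 2.0], scan_index=1)]
        out = normalize_to_first(scans)
        np.testing.assert_allclose(out[1].values, [10.0, 15.0, 20.0])

    @given(hnp.arrays(np.float64, st.integers(2, 30),
                      elements=st.floats(-100, 100, width=32)))
    @settings(max_examples=50, deadline=None)
    def test_output_range_pinned_to_first_scan(self, values):
        if values.max() == values.min():
            values = values + np.linspace(0, 1, values.size)  # avoid degenerate
        scans = [seq([2.0, -3.0, 7.0], scan_index=0), seq(values, scan_index=1)]
        out = normalize_to_first(scans)
        assert out[1].values.min() == pytest.approx(-3.0, abs=1e-9)
        assert out[1].values.max() == pytest.approx(7.0, abs=1e-9)

    def test_constant_scan_rejected_with_identity(self):
        scans = [seq([0.0, 1.0], scan_index=0), seq([4.0, 4.0], scan_index=1)]
        with pytest.raises(DegenerateScanError, match="scan 1"):
            normalize_to_first(scans)


class TestRangeStats:
    def test_extrema_of_a_union(self):
        stats = fit_range_stats([
            seq(np.arange(6.0)), seq(np.arange(2.0, 10.0)),
            seq([0.5, 1.0], sensor="GNP"),
        ])
        assert stats.ranges["CNP"] == (0.0, 9.0)
        assert stats.ranges["GNP"] == (0.5, 1.0)

    def test_single_scan_gives_its_own_extrema(self):
        stats = fit_range_stats([seq([3.0, -1.0, 2.0])])
        assert stats.ranges["CNP"] == (-1.0, 3.0)

    def test_interval_grows_with_nested_training_sets(self):
        scans = [seq(np.array([2.0, 5.0])), seq(np.array([1.0, 6.0])),
                 seq(np.array([-2.0, 9.0]))]
        intervals = [fit_range_stats(scans[: i + 1]).ranges["CNP"]
                     for i in range(3)]
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            assert lo2 <= lo1 and hi2 >= hi1

    def test_missing_sensor_error(self):
        with pytest.raises(MissingSensorError, match="PEDOT"):
            fit_range_stats([seq([0.0, 1.0])], sensors=("CNP", "PEDOT"))

    def test_degenerate_stats_rejected(self):
        with pytest.raises(DegenerateScanError):
            RangeStats(ranges={"CNP": (1.0, 1.0)})


class TestEqualizeRanges:
    STATS = RangeStats(ranges={"CNP": (0.0, 10.0), "GNP": (0.0, 5.0),
                               "PEDOT": (-1.0, 1.0)})

    def test_hand_computed_map(self):
        triple = {"CNP": seq([1.0, 2.0]), "GNP": seq([0.0, 2.5, 5.0], sensor="GNP")}
        out = equalize_ranges(triple, self.STATS)
        np.testing.assert_allclose(out["GNP"].values, [0.0, 5.0, 10.0])

    def test_reference_scan_unchanged(self):
        cnp = seq([1.0, 2.0, 3.0])
        out = equalize_ranges({"CNP": cnp, "PEDOT": seq([0.0, 0.5], sensor="PEDOT")},
                              self.STATS)
        assert out["CNP"] is cnp

    def test_training_envelope_maps_to_reference_envelope(self):
        # a GNP scan spanning the fitted GNP envelope lands on the CNP envelope
        out = equalize_ranges(
            {"CNP": seq([0.0, 1.0]), "GNP": seq([0.0, 5.0], sensor="GNP")},
            self.STATS,
        )
        assert out["GNP"].values[0] == pytest.approx(0.0, abs=1e-12)
        assert out["GNP"].values[-1] == pytest.approx(10.0, rel=1e-12)

    def test_missing_fitted_sensor(self):
        stats = RangeStats(ranges={"CNP": (0.0, 1.0)})
        with pytest.raises(MissingSensorError):
            equalize_ranges(
                {"CNP": seq([0.0, 1.0]), "GNP": seq([0.0, 1.0], sensor="GNP")}, stats
            )


class TestSubsample:
    def test_hand_computed_window_means(self):
        np.testing.assert_allclose(
            subsample(np.array([1.0, 2, 3, 4, 5, 6]), 2), [1.5, 3.5, 5.5]
        )

    def test_k_one_is_identity(self):
        values = np.array([3.0, -1.0, 4.0])
        np.testing.assert_array_equal(subsample(values, 1), values)

    @pytest.mark.parametrize("n,k,expected", [(28000, 35, 800), (27650, 35, 790),
                                              (7, 3, 2)])
    def test_floor_length_and_remainder_discarded(self, n, k, expected):
        out = subsample(np.arange(float(n)), k)
        assert out.size == expected

    def test_window_longer_than_scan_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            subsample(np.arange(5.0), 6)

    @given(
        hnp.arrays(np.float64, st.integers(4, 60),
                   elements=st.floats(-1e3, 1e3, width=32)),
        st.integers(1, 8),
        st.floats(-5, 5, width=16),
        st.floats(-5, 5, width=16),
    )
    @settings(max_examples=60, deadline=None)
    def test_commutes_with_affine_maps(self, values, k, a, b):
        if k > values.size:
            k = values.size
        lhs = subsample(a * values + b, k)
        rhs = a * subsample(values, k) + b
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


class TestBuildInstances:
    def test_instance_count_is_scans_over_three(self, small_dataset, small_prep):
        instances = build_instances(small_dataset, k=35)
        n_scans = sum(len(m.scans) for m in small_dataset)
        assert len(instances) == n_scans // 3 == small_prep.n_instances

    def test_feature_length_is_sum_of_block_floors(self, small_dataset):
        instances = build_instances(small_dataset, k=35)
        # 700//35 + 665//35 + 630//35
        assert instances[0].features.size == 20 + 19 + 18
        assert instances[0].block_lengths == {"CNP": 20, "GNP": 19, "PEDOT": 18}

    def test_permutation_invariance(self, small_dataset):
        instances = build_instances(small_dataset, k=35)
        shuffled = build_instances(list(reversed(small_dataset)), k=35)
        assert [i.group_key for i in instances] == [i.group_key for i in shuffled]
        for a, b in zip(instances, shuffled):
            np.testing.assert_array_equal(a.features, b.features)

    def test_missing_sensor_measurement_is_a_pairing_error(self, small_dataset):
        broken = [m for m in small_dataset if m.measurement_id != next(
            m.measurement_id for m in small_dataset if m.sensor == "GNP"
        )]
        with pytest.raises(PairingError):
            build_instances(broken, k=35)

    def test_fast_path_matches_canonical_pipeline(self, small_dataset, small_prep):
        instances = build_instances(small_dataset, k=35)
        X_fast, _ = feature_matrix(small_prep)
        X_slow = np.vstack([inst.features for inst in instances])
        np.testing.assert_allclose(X_fast, X_slow, rtol=1e-9, atol=1e-9)

    def test_stats_fitted_on_training_rows_only(self, small_prep):
        X_all, _ = feature_matrix(small_prep)
        idx = np.arange(0, small_prep.n_instances, 2)
        X_train_fit, stats_train = feature_matrix(small_prep, idx)
        for sensor in ("CNP", "GNP", "PEDOT"):
            expected = (
                float(small_prep.scan_extrema[sensor][idx, 0].min()),
                float(small_prep.scan_extrema[sensor][idx, 1].max()),
            )
            assert stats_train.ranges[sensor] == expected
        # the reference (CNP) block never depends on the fitted stats
        np.testing.assert_array_equal(X_all[:, :20], X_train_fit[:, :20])

    def test_equalized_training_extrema_match_reference_exactly(self, small_dataset):
        from etongue.preprocess import _group_triples, _normalized_sequences

        normalized = _normalized_sequences(small_dataset)
        stats = fit_range_stats(normalized, ("CNP", "GNP", "PEDOT"))
        groups = _group_triples(normalized, ("CNP", "GNP", "PEDOT"))
        eq = [equalize_ranges(groups[key], stats) for key in sorted(groups)]
        for sensor in ("GNP", "PEDOT"):
            lo = min(t[sensor].values.min() for t in eq)
            hi = max(t[sensor].values.max() for t in eq)
            assert lo == pytest.approx(stats.ranges["CNP"][0], abs=1e-12)
            assert hi == pytest.approx(stats.ranges["CNP"][1], rel=1e-12)


class TestRawBaseline:
    def test_truncated_rectangular_blocks(self, small_dataset):
        prep = prepare_raw(small_dataset)
        assert not prep.equalize
        assert prep.block_lengths() == {"CNP": 700, "GNP": 665, "PEDOT": 630}
        X, _ = feature_matrix(prep)
        assert X.shape == (prep.n_instances, 700 + 665 + 630)

    def test_raw_currents_untouched(self, small_dataset):
        prep = prepare_raw(small_dataset)
        m = next(m for m in small_dataset if m.sensor == "CNP")
        row = prep.keys.index((m.cultivar, m.electrode_id, 0))
        np.testing.assert_array_equal(
            prep.blocks["CNP"][row], m.scans[0].current[:700]
        )
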