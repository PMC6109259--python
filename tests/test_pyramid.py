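"""Aggregation arithmetic, zoom-level computation, and importance downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genotiles.coords import AbsInterval, Assembly, GenomePosition
from genotiles.io import AnnotationRecord, ContactRecord
from genotiles.pyramid import (
    MatrixLevel,
    SignalLevel,
    aggregate_matrix,
    aggregate_signal,
    assign_importance,
    bin_contacts,
    build_matrix_pyramid,
    compute_max_zoom,
    downsample_annotations,
    mean_values,
)


def brute_force_max_zoom(g, r0, tile_bins):
    """Independent oracle: smallest k with tile_bins * r0 * 2**k >= g."""
    k = 0
    while tile_bins * r0 * 2**k < g:
        k += 1
    return k


class TestComputeMaxZoom:
    def test_genome_exactly_one_tile(self):
        assert compute_max_zoom(256 * 1000, 1000, 256) == 0

    def test_human_genome_at_1kb_reaches_16_384_mb_bins(self):
        # 1 K, 2 K, 4 K, ... doubling sequence must end at 16.384 M
        z = compute_max_zoom(3_100_000_000, 1000, 256)
        assert 1000 * 2**z == 16_384_000

    def test_one_extra_base_needs_one_doubling(self):
        g = 256 * 1000 + 1
        assert compute_max_zoom(g, 1000, 256) == brute_force_max_zoom(g, 1000, 256) == 1

    @settings(derandomize=True, max_examples=200)
    @given(g=st.integers(1, 10**10), r0=st.integers(1, 10**6))
    def test_matches_brute_force_and_coverage_bounds(self, g, r0):
        z = compute_max_zoom(g, r0, 256)
        assert z == brute_force_max_zoom(g, r0, 256)
        assert 256 * r0 * 2**z >= g
        if z > 0:
            assert 256 * r0 * 2 ** (z - 1) < g


def _contact(assembly, a, b):
    return ContactRecord(assembly.from_absolute(a), assembly.from_absolute(b))


class TestBinContacts:
    def test_same_bin_lands_on_diagonal_once(self, toy_assembly):
        level = bin_contacts([_contact(toy_assembly, 10, 20)], toy_assembly, 100)
        dense = level.dense()
        assert dense[0, 0] == 1
        assert dense.sum() == 1

    def test_cross_bin_is_symmetric(self, toy_assembly):
        level = bin_contacts([_contact(toy_assembly, 10, 150)], toy_assembly, 100)
        dense = level.dense()
        assert dense[0, 1] == dense[1, 0] == 1
        assert dense.sum() == 2

    def test_bad_bin_size_rejected(self, toy_assembly):
        with pytest.raises(ValueError):
            bin_contacts([], toy_assembly, 0)

    def test_binning_coarser_equals_one_aggregation(self, toy_assembly):
        # direct-binning oracle on random contacts
        rng = np.random.default_rng(7)
        pos = rng.integers(0, toy_assembly.total_length, size=(200, 2))
        contacts = [_contact(toy_assembly, a, b) for a, b in pos]
        fine = bin_contacts(contacts, toy_assembly, 50)
        np.testing.assert_array_equal(
            aggregate_matrix(fine).dense(), bin_contacts(contacts, toy_assembly, 100).dense()
        )


class TestAggregateMatrix:
    def test_off_diagonal_coarse_entry_is_full_block_sum(self):
        # contacts confined to bins {0,1} x {2,3}: no diagonal folding
        dense = np.zeros((4, 4))
        dense[0, 2], dense[0, 3], dense[1, 2], dense[1, 3] = 1.0, 2.0, 3.0, 4.0
        dense = dense + dense.T
        out = aggregate_matrix(MatrixLevel.from_dense(dense, 10))
        assert out.dense()[0, 1] == 10.0 == out.dense()[1, 0]
        assert out.bin_size_bp == 20

    def test_diagonal_fold_counts_each_contact_once(self):
        # one contact between adjacent bins 0 and 1 becomes a same-bin
        # contact at the coarser level, not a doubled diagonal entry
        level = MatrixLevel.from_dense(np.array([[1.0, 2.0], [2.0, 4.0]]), 10)
        out = aggregate_matrix(level)
        np.testing.assert_array_equal(out.dense(), [[7.0]])
        assert out.total_mass() == level.total_mass() == 7.0

    def test_all_zero_stays_zero(self):
        out = aggregate_matrix(MatrixLevel.from_dense(np.zeros((4, 4)), 10))
        assert out.dense().sum() == 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            MatrixLevel.from_dense(np.array([[1.0, 2.0], [3.0, 4.0]]), 10)

    @pytest.mark.parametrize("n", [8, 7])  # even and odd trailing bin
    def test_k_fold_aggregation_equals_direct_binning(self, n):
        rng = np.random.default_rng(n)
        a = rng.integers(0, 5, size=(n, n)).astype(float)
        dense = np.triu(a) + np.triu(a, 1).T  # random symmetric
        assembly = Assembly([("c", n * 10)])
        contacts, counts = [], dense.copy()
        for i in range(n):
            for j in range(i, n):
                for _ in range(int(counts[i, j])):
                    contacts.append(_contact(assembly, i * 10 + 1, j * 10 + 1))
        for k in (1, 2, 3):
            level = bin_contacts(contacts, assembly, 10)
            for _ in range(k):
                level = aggregate_matrix(level)
            oracle = bin_contacts(contacts, assembly, 10 * 2**k)
            np.testing.assert_array_equal(level.dense(), oracle.dense())

    def test_mass_conserved_across_a_pyramid(self, toy_assembly):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, toy_assembly.total_length, size=(300, 2))
        pyr = build_matrix_pyramid(
            [_contact(toy_assembly, a, b) for a, b in pos], toy_assembly, 100, tile_bins=8
        )
        masses = {pyr.levels[z].total_mass() for z in range(pyr.max_zoom + 1)}
        assert len(masses) == 1


class TestAggregateSignal:
    def test_pairwise_sums(self):
        level = SignalLevel(10, [1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], 1)
        out = aggregate_signal(level)
        np.testing.assert_array_equal(out.sums, [3.0, 7.0])
        np.testing.assert_array_equal(out.nan_counts, [0, 0])
        assert out.values_per_bin == 2 and out.bin_size_bp == 20

    def test_missing_values_are_counted_not_summed(self):
        level = SignalLevel(10, [1.0, 0.0], [0, 1], 1)  # [1, missing]
        out = aggregate_signal(level)
        assert out.sums[0] == 1.0 and out.nan_counts[0] == 1

    def test_odd_trailing_bin_partner_is_all_missing(self):
        level = SignalLevel(10, [1.0, 2.0, 5.0], [0, 0, 0], 1)
        out = aggregate_signal(level)
        np.testing.assert_array_equal(out.sums, [3.0, 5.0])
        np.testing.assert_array_equal(out.nan_counts, [0, 1])

    @settings(derandomize=True, max_examples=100)
    @given(
        n=st.integers(1, 40),
        seed=st.integers(0, 2**16),
        levels=st.integers(1, 5),
    )
    def test_sum_and_missing_count_conserved(self, n, seed, levels):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n)
        missing = rng.random(n) < 0.3
        level = SignalLevel(4, np.where(missing, 0.0, values), missing.astype(int), 1)
        total_sum = level.sums.sum()
        total_nonmissing = n - missing.sum()
        for _ in range(levels):
            level = aggregate_signal(level)
            assert level.sums.sum() == pytest.approx(total_sum)
            assert level.n_bins * level.values_per_bin - level.nan_counts.sum() == total_nonmissing


class TestMeanValues:
    def test_divides_by_non_missing_count(self):
        level = SignalLevel(40, [6.0], [2], 4)
        assert mean_values(level)[0] == 3.0

    def test_all_missing_bin_is_missing(self):
        level = SignalLevel(40, [0.0], [4], 4)
        assert np.isnan(mean_values(level)[0])

    def test_constant_signal_stays_constant_at_every_zoom(self):
        rng = np.random.default_rng(5)
        c = 2.75
        missing = rng.random(37) < 0.4
        level = SignalLevel(4, np.where(missing, 0.0, c), missing.astype(int), 1)
        for _ in range(6):
            means = mean_values(level)
            ok = ~np.isnan(means)
            assert np.allclose(means[ok], c)
            level = aggregate_signal(level)


class TestAssignImportance:
    def test_area_strategy_uses_rectangle_area(self):
        rec = AnnotationRecord(AbsInterval(0, 10), "r", None, AbsInterval(100, 120))
        (out,) = assign_importance([rec], "area")
        assert out.importance == 200.0

    def test_area_strategy_uses_interval_length_for_1d(self):
        (out,) = assign_importance([AnnotationRecord(AbsInterval(5, 30), "r")], "area")
        assert out.importance == 25.0

    def test_user_column_passes_through(self):
        rec = AnnotationRecord(AbsInterval(0, 10), "r", 42.0)
        assert assign_importance([rec], "column") == [rec]

    def test_missing_user_column_is_error(self):
        with pytest.raises(ValueError, match="importance"):
            assign_importance([AnnotationRecord(AbsInterval(0, 10), "r")], "column")

    def test_random_strategy_reproducible_under_seed(self):
        recs = [AnnotationRecord(AbsInterval(i, i + 1), str(i)) for i in range(10)]
        a = assign_importance(recs, "random", seed=11)
        b = assign_importance(recs, "random", seed=11)
        c = assign_importance(recs, "random", seed=12)
        assert a == b
        assert a != c


GEOM = dict(base_resolution_bp=10, max_zoom=4, tile_bins=16)  # tile at z: 16*10*2^(4-z)


class TestDownsampleAnnotations:
    def test_top_k_by_importance_within_one_tile(self):
        recs = [
            AnnotationRecord(AbsInterval(0, 5), "a", 9.0),
            AnnotationRecord(AbsInterval(10, 15), "b", 5.0),
            AnnotationRecord(AbsInterval(20, 25), "c", 3.0),
        ]
        level = downsample_annotations(recs, 0, 2, **GEOM)
        assert level.retained == {0: (0, 1)}

    def test_capacity_zero_is_empty(self):
        recs = [AnnotationRecord(AbsInterval(0, 5), "a", 9.0)]
        assert downsample_annotations(recs, 0, 0, **GEOM).retained == {}

    @staticmethod
    def _brute_force(recs, zoom, capacity):
        t_w = GEOM["tile_bins"] * GEOM["base_resolution_bp"] * 2 ** (GEOM["max_zoom"] - zoom)
        out = {}
        n_tiles = 2**zoom
        for t in range(n_tiles):
            lo, hi = t * t_w, (t + 1) * t_w
            hits = [
                i
                for i, r in enumerate(recs)
                if r.extent.start < hi and r.extent.end > lo
            ]
            hits.sort(key=lambda i: (-recs[i].importance, recs[i].extent.start, recs[i].label))
            if hits[:capacity]:
                out[t] = tuple(hits[:capacity])
        return out

    def test_matches_brute_force_per_tile_top_k(self):
        rng = np.random.default_rng(21)
        g = GEOM["tile_bins"] * GEOM["base_resolution_bp"] * 2 ** GEOM["max_zoom"]
        recs = []
        for i in range(120):
            s = int(rng.integers(0, g - 10))
            e = int(s + rng.integers(1, 200))
            recs.append(AnnotationRecord(AbsInterval(s, min(e, g)), f"r{i}", float(rng.integers(0, 8))))
        for zoom in range(GEOM["max_zoom"] + 1):
            level = downsample_annotations(recs, zoom, 4, **GEOM)
            assert level.retained == self._brute_force(recs, zoom, 4)

    def test_monotone_containment_across_zooms(self):
        rng = np.random.default_rng(22)
        g = GEOM["tile_bins"] * GEOM["base_resolution_bp"] * 2 ** GEOM["max_zoom"]
        recs = [
            AnnotationRecord(
                AbsInterval(s := int(rng.integers(0, g - 10)), s + int(rng.integers(1, 500))),
                f"r{i}",
                float(rng.integers(0, 5)),
            )
            for i in range(80)
        ]
        levels = {z: downsample_annotations(recs, z, 3, **GEOM) for z in range(GEOM["max_zoom"] + 1)}
        for z in range(GEOM["max_zoom"]):
            t_w_fine = GEOM["tile_bins"] * GEOM["base_resolution_bp"] * 2 ** (GEOM["max_zoom"] - z - 1)
            for coarse_tile, kept in levels[z].retained.items():
                for i in kept:
                    r = recs[i]
                    first = max(int(r.extent.start) // t_w_fine, 2 * coarse_tile)
                    last = min((int(r.extent.end) - 1) // t_w_fine, 2 * coarse_tile + 1)
                    for t in range(first, last + 1):
                        assert i in levels[z + 1].retained.get(t, ()), (z, i, t)
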