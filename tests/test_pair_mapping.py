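"""Distance matrix, greedy delete-min pairing, and the randomized null."""

import warnings

import numpy as np
import pytest
from scipy.stats import ks_2samp

from tetherlink.distance_stats import ks_critical_value
from tetherlink.errors import ParameterError
from tetherlink.pair_mapping import (
    build_distance_matrix,
    field_extent_from_table,
    greedy_pair,
    pair_all_micrographs,
    randomize_coordinates,
)
from tetherlink.star_io import ParticleRecord, ParticleTable

from conftest import random_table


def brute_force_delete_min(matrix):
    """Literal oracle: materialize, scan for the minimum, shrink the matrix.

    Keeps explicit row/column index bookkeeping instead of masking, so it
    shares no code path with the implementation under test.
    """
    rows = list(range(len(matrix)))
    cols = list(range(len(matrix[0]) if len(matrix) else 0))
    out = []
    while rows and cols:
        best = None
        for i in rows:
            for j in cols:
                if best is None or matrix[i][j] < matrix[best[0]][best[1]]:
                    best = (i, j)
        i, j = best
        out.append((i, j, float(matrix[i][j])))
        rows.remove(i)
        cols.remove(j)
    return out


def simple_table(points_by_mic, population="x", apix=1.0):
    records = [
        ParticleRecord(mic, x, y, pixel_size_A=apix)
        for mic, pts in points_by_mic.items()
        for x, y in pts
    ]
    return ParticleTable(records=records, population=population)


class TestBuildDistanceMatrix:
    def test_3_4_5_triangle(self):
        m = build_distance_matrix([(0, 0)], [(3, 4)])
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(5.0)

    def test_two_by_one(self):
        m = build_distance_matrix([(0, 0), (1, 0)], [(0, 0)])
        assert np.allclose(m, [[0.0], [1.0]])

    def test_hand_computed_two_by_two(self):
        m = build_distance_matrix([(1, 0), (-5, 0)], [(0, 0), (3, 0)])
        assert np.allclose(m, [[1, 2], [5, 8]])

    @pytest.mark.parametrize("b, a, shape", [([], [(1, 1)], (0, 1)), ([(1, 1)], [], (1, 0)), ([], [], (0, 0))])
    def test_empty_inputs(self, b, a, shape):
        assert build_distance_matrix(b, a).shape == shape


class TestGreedyPair:
    def test_single_entry(self):
        assert greedy_pair(np.array([[5.0]])) == [(0, 0, 5.0)]

    def test_greedy_not_optimal(self):
        # the optimal assignment would cost 2 + 5; delete-min picks 1 then 8
        assert greedy_pair(np.array([[1.0, 2.0], [5.0, 8.0]])) == [
            (0, 0, 1.0),
            (1, 1, 8.0),
        ]

    def test_tie_break_row_then_column(self):
        assert greedy_pair(np.array([[1.0, 1.0], [2.0, 3.0]])) == [
            (0, 0, 1.0),
            (1, 1, 3.0),
        ]

    def test_zero_extent(self):
        assert greedy_pair(np.zeros((0, 3))) == []

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            shape = rng.integers(1, 7, size=2)
            m = rng.uniform(0, 100, size=shape)
            assert greedy_pair(m) == brute_force_delete_min(m.tolist())

    def test_invariants_on_random_matrices(self, rng):
        for _ in range(200):
            shape = rng.integers(0, 9, size=2)
            m = rng.uniform(0, 1000, size=shape)
            pairs = greedy_pair(m)
            assert len(pairs) == min(shape)
            assert len({r for r, _, _ in pairs}) == len(pairs)
            assert len({c for _, c, _ in pairs}) == len(pairs)
            dists = [d for _, _, d in pairs]
            assert all(a <= b for a, b in zip(dists, dists[1:]))

    def test_permutation_equivariance(self, rng):
        # distinct entries: permuting rows/cols then mapping indices back
        # yields the same multiset of distances
        m = rng.permutation(np.arange(30, dtype=float)).reshape(5, 6)
        perm_r = rng.permutation(5)
        perm_c = rng.permutation(6)
        base = {d for _, _, d in greedy_pair(m)}
        permuted = {d for _, _, d in greedy_pair(m[np.ix_(perm_r, perm_c)])}
        assert base == permuted


class TestPairAllMicrographs:
    def test_single_shared_pair(self):
        tb = simple_table({"m1": [(0.0, 0.0)]})
        ta = simple_table({"m1": [(7.0, 0.0)]})
        result = pair_all_micrographs(tb, ta)
        assert result.pooled_distances_A == pytest.approx([7.0])

    def test_pooling_concatenates_micrographs(self):
        tb = simple_table({"m1": [(0, 0), (10, 0)], "m2": [(0, 0)]})
        ta = simple_table({"m1": [(1, 0), (18, 0)], "m2": [(7, 0)]})
        result = pair_all_micrographs(tb, ta)
        assert result.n_pairs == 3
        assert sorted(result.pairs_by_micrograph) == ["m1", "m2"]

    def test_disjoint_micrographs_warn_and_skip(self):
        tb = simple_table({"m2": [(0, 0)]})
        ta = simple_table({"m1": [(0, 0)]})
        with pytest.warns(UserWarning, match="no micrograph ids"):
            result = pair_all_micrographs(tb, ta)
        assert result.n_pairs == 0
        assert sorted(result.skipped_micrographs) == ["m1", "m2"]

    def test_partial_overlap_counts_skips(self):
        tb = simple_table({"m1": [(0, 0)], "m2": [(0, 0)]})
        ta = simple_table({"m1": [(3, 4)], "m3": [(0, 0)]})
        result = pair_all_micrographs(tb, ta)
        assert result.pooled_distances_A == pytest.approx([5.0])
        assert sorted(result.skipped_micrographs) == ["m2", "m3"]


class TestRandomizeCoordinates:
    def test_empty_table(self):
        assert len(randomize_coordinates(ParticleTable(), 100, 100, 0)) == 0

    def test_counts_preserved(self, rng):
        table = random_table(rng, n_records=200, n_micrographs=7)
        null = randomize_coordinates(table, 5000, 4000, seed=3)
        orig = {m: len(g) for m, g in table.groups().items()}
        assert {m: len(g) for m, g in null.groups().items()} == orig

    def test_bounds_and_determinism(self, rng):
        table = random_table(rng, n_records=1000, n_micrographs=20)
        a = randomize_coordinates(table, 3000, 2000, seed=11)
        b = randomize_coordinates(table, 3000, 2000, seed=11)
        for mic in a.micrograph_ids():
            pos = a.positions(mic)
            assert np.all(pos[:, 0] >= 0) and np.all(pos[:, 0] < 3000)
            assert np.all(pos[:, 1] >= 0) and np.all(pos[:, 1] < 2000)
            assert np.array_equal(pos, b.positions(mic))

    def test_nonpositive_field_rejected(self, rng):
        table = random_table(rng, n_records=5)
        with pytest.raises(ParameterError):
            randomize_coordinates(table, -1.0, 100.0, seed=0)

    def test_data_derived_extents_warn(self, rng):
        table = random_table(rng, n_records=50)
        with pytest.warns(UserWarning, match="deriving"):
            null = randomize_coordinates(table, seed=0)
        w, h = field_extent_from_table(table)
        for mic in null.micrograph_ids():
            pos = null.positions(mic)
            assert np.all(pos[:, 0] < w) and np.all(pos[:, 1] < h)

    def test_two_seeds_statistically_indistinguishable(self, rng):
        """Pooled null distances from independent seeds share one distribution."""
        table_a = random_table(rng, 200, n_micrographs=20, population="tauA")
        table_b = random_table(rng, 200, n_micrographs=20, population="tauB")
        ok = 0
        for rep in range(100):
            d = []
            for seed in (2 * rep, 2 * rep + 1):
                na = randomize_coordinates(table_a, 4000, 4000, seed=seed)
                nb = randomize_coordinates(table_b, 4000, 4000, seed=seed + 7_000_001)
                d.append(pair_all_micrographs(nb, na).pooled_distances_A)
            stat = ks_2samp(d[0], d[1]).statistic
            ok += stat < ks_critical_value(len(d[0]), len(d[1]), alpha=0.01)
        assert ok >= 95
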