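"""Centroid lattice, distance bias, and relative positional bias oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatioseg.autodiff import Tensor
from spatioseg.biasing import (
    PatchGrid,
    RpeTables,
    compute_hausdorff_bias,
    compute_rpe_bias,
    make_centroids,
)


def brute_force_distance_bias(h, w, eps):
    """Independent double-loop implementation of the normalized negated distances."""
    cents = [(k // w, k % w) for k in range(h * w)]
    n = len(cents)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.hypot(cents[i][0] - cents[j][0], cents[i][1] - cents[j][1])
    return -d / (d.max() + eps)


class TestCentroids:
    def test_single_patch(self):
        np.testing.assert_array_equal(make_centroids(PatchGrid(1, 1)), [[0, 0]])

    def test_row_major_enumeration(self):
        np.testing.assert_array_equal(
            make_centroids(PatchGrid(2, 2)), [[0, 0], [0, 1], [1, 0], [1, 1]]
        )

    def test_rectangular_grid_last_coordinate(self):
        cents = make_centroids(PatchGrid(2, 3))
        assert len(cents) == 6
        np.testing.assert_array_equal(cents[-1], [1, 2])
        # div/mod oracle over every token
        for k, (y, x) in enumerate(cents):
            assert (y, x) == (k // 3, k % 3)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            PatchGrid(0, 3)


class TestDistanceBias:
    def test_single_patch_is_zero_matrix(self):
        np.testing.assert_array_equal(
            compute_hausdorff_bias(PatchGrid(1, 1)).matrix, [[0.0]]
        )

    def test_two_patches(self):
        m = compute_hausdorff_bias(PatchGrid(1, 2), epsilon=1e-8).matrix
        assert m[0, 0] == m[1, 1] == 0.0
        np.testing.assert_allclose(m[0, 1], -1.0 / (1.0 + 1e-8))

    def test_2x2_adjacent_and_diagonal(self):
        m = compute_hausdorff_bias(PatchGrid(2, 2), epsilon=1e-12).matrix
        np.testing.assert_allclose(m[0, 1], -1.0 / np.sqrt(2.0), atol=1e-9)
        np.testing.assert_allclose(m[0, 3], -1.0, atol=1e-9)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_hausdorff_bias(PatchGrid(2, 2), epsilon=0.0)

    @given(
        h=st.integers(1, 8), w=st.integers(1, 8),
        eps=st.floats(1e-12, 1e-2),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, h, w, eps):
        got = compute_hausdorff_bias(PatchGrid(h, w), epsilon=eps).matrix
        expected = brute_force_distance_bias(h, w, eps)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @given(h=st.integers(1, 8), w=st.integers(1, 8))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_sign_diagonal(self, h, w):
        m = compute_hausdorff_bias(PatchGrid(h, w)).matrix
        np.testing.assert_allclose(m, m.T, atol=0)
        assert np.all(m <= 0) and np.all(m >= -1.0)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_strictly_decreasing_with_distance(self):
        grid = PatchGrid(5, 5)
        m = compute_hausdorff_bias(grid).matrix
        cents = make_centroids(grid).astype(float)
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        for i in range(grid.n_tokens):
            order = np.argsort(d[i])
            dist_sorted = d[i][order]
            bias_sorted = m[i][order]
            strict = dist_sorted[1:] > dist_sorted[:-1]
            assert np.all(bias_sorted[1:][strict] < bias_sorted[:-1][strict])


def brute_force_rpe(ht, wt, h, w, max_rel):
    """Triple-loop reference for the relative positional bias."""
    n = h * w
    heads = ht.shape[1]
    out = np.zeros((heads, n, n))
    s = max_rel - 1
    for k in range(heads):
        for i in range(n):
            for j in range(n):
                yi, xi = i // w, i % w
                yj, xj = j // w, j % w
                out[k, i, j] = ht[yi - yj + s, k] + wt[xi - xj + s, k]
    return out


class TestRpeBias:
    def test_zero_tables_give_zero_bias(self):
        tables = RpeTables.create(max_relative_position=4, num_heads=2)
        out = compute_rpe_bias(tables, PatchGrid(3, 4))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_hand_indexed_1x2_grid(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([-0.5, 0.7, 1.1])
        tables = RpeTables(
            height_table=Tensor(a[:, None], requires_grad=True),
            width_table=Tensor(b[:, None], requires_grad=True),
            max_relative_position=2,
        )
        out = compute_rpe_bias(tables, PatchGrid(1, 2)).data[0]
        # dy always 0 -> a[1]; dx in {0,-1;+1,0} -> shifted lookup
        expected = np.array([[a[1] + b[1], a[1] + b[0]], [a[1] + b[2], a[1] + b[1]]])
        np.testing.assert_allclose(out, expected)

    @given(h=st.integers(1, 5), w=st.integers(1, 5), heads=st.integers(1, 3),
           seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, h, w, heads, seed):
        rng = np.random.default_rng(seed)
        max_rel = max(h, w)
        tables = RpeTables.create(max_rel, heads, rng=rng)
        got = compute_rpe_bias(tables, PatchGrid(h, w)).data
        expected = brute_force_rpe(
            tables.height_table.data, tables.width_table.data, h, w, max_rel
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_translation_invariance_3x3(self):
        rng = np.random.default_rng(0)
        tables = RpeTables.create(3, 2, rng=rng)
        grid = PatchGrid(3, 3)
        out = compute_rpe_bias(tables, grid).data
        cents = make_centroids(grid)
        n = grid.n_tokens
        for i in range(n):
            for j in range(n):
                for i2 in range(n):
                    for j2 in range(n):
                        if np.array_equal(cents[i] - cents[j], cents[i2] - cents[j2]):
                            np.testing.assert_allclose(out[:, i, j], out[:, i2, j2])

    def test_grid_exceeding_capacity_raises(self):
        tables = RpeTables.create(max_relative_position=3, num_heads=1)
        with pytest.raises(IndexError, match="max_relative_position"):
            compute_rpe_bias(tables, PatchGrid(4, 2))
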