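"""Spatial bias structures injected into self-attention.

Two complementary priors are added to raw attention scores before the
softmax:

* a **static distance bias**: the negated, max-normalized Euclidean distance
  between every pair of patch centroids on the token lattice, so geometrically
  close patches receive larger (less negative) score offsets;
* a **learnable 2D relative positional bias**: per-head lookup tables indexed
  by the vertical and horizontal offset between two patches.

Both are square ``N x N`` structures over the row-major token order of an
``H x W`` patch grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .autodiff import Tensor, gather_rows

__all__ = [
    "PatchGrid",
    "make_centroids",
    "HausdorffBias",
    "compute_hausdorff_bias",
    "RpeTables",
    "compute_rpe_bias",
    "relative_index_arrays",
]


@dataclass(frozen=True)
class PatchGrid:
    """An ``height x width`` lattice of patch tokens, row-major order."""

    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError(f"grid dimensions must be positive, got {self.height}x{self.width}")

    @property
    def n_tokens(self) -> int:
        return self.height * self.width


def make_centroids(grid: PatchGrid) -> np.ndarray:
    """(N, 2) integer centroid coordinates (row, col) in row-major token order.

    Token ``k`` sits at ``(k // width, k % width)``.  Centroids are lattice
    coordinates; the distance bias normalizes by the maximum pairwise
    distance, so any uniform spatial scale cancels.
    """
    ks = np.arange(grid.n_tokens)
    return np.stack([ks // grid.width, ks % grid.width], axis=1)


@dataclass(frozen=True)
class HausdorffBias:
    """Static pairwise-centroid distance bias: symmetric, non-positive, zero diagonal."""

    matrix: np.ndarray
    epsilon: float


def compute_hausdorff_bias(grid: PatchGrid, epsilon: float = 1e-8) -> HausdorffBias:
    """Distance bias ``B[i, j] = -||p_i - p_j|| / (max(D) + epsilon)``.

    ``D`` is the full pairwise Euclidean distance matrix between patch
    centroids.  Dividing by ``max(D) + epsilon`` maps entries into ``[-1, 0]``;
    for a single-token grid ``max(D) = 0`` and the bias is the zero matrix.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    p = make_centroids(grid).astype(np.float64)
    diff = p[:, None, :] - p[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    matrix = -d / (d.max() + epsilon)
    return HausdorffBias(matrix=matrix, epsilon=epsilon)


@lru_cache(maxsize=64)
def _cached_bias(height: int, width: int, epsilon: float) -> HausdorffBias:
    return compute_hausdorff_bias(PatchGrid(height, width), epsilon)


def cached_hausdorff_bias(grid: PatchGrid, epsilon: float = 1e-8) -> HausdorffBias:
    """Memoized variant: each encoder stage reuses one bias for its fixed grid."""
    return _cached_bias(grid.height, grid.width, epsilon)


@dataclass
class RpeTables:
    """Learnable height/width bias tables for 2D relative positional encoding.

    Each table has shape ``(2*max_relative_position - 1, num_heads)`` so every
    offset in ``[-(max_relative_position-1), max_relative_position-1]`` maps to
    a row after adding the shift ``max_relative_position - 1``.
    """

    height_table: Tensor
    width_table: Tensor
    max_relative_position: int

    @classmethod
    def create(
        cls,
        max_relative_position: int,
        num_heads: int,
        rng: np.random.Generator | None = None,
        init_scale: float = 0.02,
    ) -> "RpeTables":
        if max_relative_position < 1:
            raise ValueError("max_relative_position must be >= 1")
        size = 2 * max_relative_position - 1
        if rng is None:
            ht = np.zeros((size, num_heads))
            wt = np.zeros((size, num_heads))
        else:
            ht = rng.normal(0.0, init_scale, (size, num_heads))
            wt = rng.normal(0.0, init_scale, (size, num_heads))
        return cls(
            height_table=Tensor(ht, requires_grad=True),
            width_table=Tensor(wt, requires_grad=True),
            max_relative_position=max_relative_position,
        )

    @property
    def num_heads(self) -> int:
        return self.height_table.shape[1]


@lru_cache(maxsize=64)
def relative_index_arrays(height: int, width: int, max_relative_position: int):
    """Shifted (N, N) lookup indices ``(dy + S, dx + S)`` with ``S = max_rel - 1``."""
    grid = PatchGrid(height, width)
    if max_relative_position < max(height, width):
        raise IndexError(
            f"grid {height}x{width} exceeds table capacity: "
            f"max_relative_position={max_relative_position} must be >= {max(height, width)}"
        )
    p = make_centroids(grid)
    shift = max_relative_position - 1
    dy = p[:, None, 0] - p[None, :, 0] + shift
    dx = p[:, None, 1] - p[None, :, 1] + shift
    return dy, dx


@lru_cache(maxsize=64)
def _rpe_onehot(height: int, width: int, max_relative_position: int):
    """Cached one-hot lookup matrices (N*N, table_rows) for height and width offsets.

    Turns the table lookup into a matmul so the backward pass is a BLAS call
    rather than a scatter-add over N^2 indices.
    """
    dy, dx = relative_index_arrays(height, width, max_relative_position)
    rows = 2 * max_relative_position - 1
    n2 = dy.size
    oh = np.zeros((n2, rows))
    oh[np.arange(n2), dy.ravel()] = 1.0
    ow = np.zeros((n2, rows))
    ow[np.arange(n2), dx.ravel()] = 1.0
    return oh, ow


def compute_rpe_bias(tables: RpeTables, grid: PatchGrid) -> Tensor:
    """Assemble the per-head relative positional bias tensor ``(num_heads, N, N)``.

    Entry ``(k, i, j)`` is ``height_table[y_i - y_j + S, k] + width_table[x_i -
    x_j + S, k]`` and therefore depends only on the head and the relative
    offset between tokens i and j.  Gradients flow back into both tables.
    """
    from .autodiff import matmul

    oh, ow = _rpe_onehot(grid.height, grid.width, tables.max_relative_position)
    n = grid.n_tokens
    bh = matmul(Tensor(oh), tables.height_table)  # (N*N, heads)
    bw = matmul(Tensor(ow), tables.width_table)
    flat = bh + bw
    return flat.reshape(n, n, tables.num_heads).transpose(2, 0, 1)
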