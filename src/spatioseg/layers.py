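"""Transformer building blocks with spatial biasing.

Four components:

* :func:`adaptive_patch_embed` — strided convolutional patch projection with a
  learnable per-patch importance scalar, followed by layer normalization;
* :func:`hausdorff_multi_head_attention` — full multi-head self-attention
  whose pre-softmax scores are offset by the static centroid-distance bias and
  the learnable relative positional bias;
* :func:`mix_ffn` — feed-forward block whose expanded features are reshaped
  to 2D and passed through a per-channel (depthwise) 3x3 convolution;
* :class:`TransformerEncoderLayer` — pre-norm residual composition of the
  attention and feed-forward sublayers.

All arrays are channels-last; token sequences are ``(batch, N, embed_dim)``
in row-major grid order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .biasing import HausdorffBias, PatchGrid, RpeTables, compute_rpe_bias

__all__ = [
    "TokenSequence",
    "PatchEmbedParams",
    "adaptive_patch_embed",
    "AttentionParams",
    "biased_attention_scores",
    "hausdorff_multi_head_attention",
    "MixFfnParams",
    "mix_ffn",
    "TransformerEncoderLayer",
]


@dataclass
class TokenSequence:
    """(batch, N, embed_dim) token values paired with their patch grid."""

    values: Tensor
    grid: PatchGrid

    def __post_init__(self):
        if self.values.shape[1] != self.grid.n_tokens:
            raise ValueError(
                f"token count {self.values.shape[1]} != grid N {self.grid.n_tokens}"
            )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


# ---------------------------------------------------------------------------
# adaptive patch embedding
# ---------------------------------------------------------------------------

@dataclass
class PatchEmbedParams:
    """Strided conv projection + per-patch weight + layer norm parameters.

    ``patch_weight`` holds one learnable scalar per output patch, initialized
    to ones, broadcast over the channel axis; it lets the model amplify or
    suppress whole spatial locations at tokenization time.
    """

    kernel_size: int
    stride: int
    padding: int
    proj_weight: Tensor  # (kernel*kernel*C_in, embed_dim)
    proj_bias: Tensor  # (embed_dim,)
    patch_weight: Tensor  # (N,)
    ln_gamma: Tensor  # (embed_dim,)
    ln_beta: Tensor  # (embed_dim,)
    # small enough that per-token scale invariance of the normalization holds
    # to well under 1e-6 for unit-scale features
    ln_eps: float = 1e-8

    @classmethod
    def create(
        cls,
        in_channels: int,
        embed_dim: int,
        n_patches: int,
        kernel_size: int,
        stride: int,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> "PatchEmbedParams":
        rng = rng or np.random.default_rng(0)
        fan_in = kernel_size * kernel_size * in_channels
        return cls(
            kernel_size=kernel_size,
            stride=stride,
            padding=padding,
            proj_weight=Tensor(_glorot(rng, fan_in, embed_dim), requires_grad=True),
            proj_bias=Tensor(np.zeros(embed_dim), requires_grad=True),
            patch_weight=Tensor(np.ones(n_patches), requires_grad=True),
            ln_gamma=Tensor(np.ones(embed_dim), requires_grad=True),
            ln_beta=Tensor(np.zeros(embed_dim), requires_grad=True),
        )

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.proj_weight": self.proj_weight,
            f"{prefix}.proj_bias": self.proj_bias,
            f"{prefix}.patch_weight": self.patch_weight,
            f"{prefix}.ln_gamma": self.ln_gamma,
            f"{prefix}.ln_beta": self.ln_beta,
        }


def adaptive_patch_embed(image, params: PatchEmbedParams) -> TokenSequence:
    """Project patches to tokens, weight each token, and layer-normalize.

    ``image`` is ``(batch, H, W, C_in)``.  The conv projection is an im2col
    patch extraction followed by a dense map to ``embed_dim``; the resulting
    row-major token ``t`` is multiplied by the scalar ``patch_weight[t]``
    before normalization over the channel axis.
    """
    image = ad.as_tensor(image)
    _, H, W, _ = image.shape
    Ho = (H + 2 * params.padding - params.kernel_size) // params.stride + 1
    Wo = (W + 2 * params.padding - params.kernel_size) // params.stride + 1
    grid = PatchGrid(Ho, Wo)
    if params.patch_weight.shape[0] != grid.n_tokens:
        raise ValueError(
            f"patch_weight has {params.patch_weight.shape[0]} entries but the "
            f"output grid {Ho}x{Wo} needs N={grid.n_tokens}"
        )
    cols = ad.extract_patches(image, params.kernel_size, params.stride, params.padding)
    tokens = cols @ params.proj_weight + params.proj_bias  # (B, N, E)
    weighted = tokens * params.patch_weight.reshape(1, grid.n_tokens, 1)
    normed = ad.layer_norm(weighted, params.ln_gamma, params.ln_beta, params.ln_eps)
    return TokenSequence(values=normed, grid=grid)


# ---------------------------------------------------------------------------
# biased multi-head attention
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    num_heads: int
    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    bq: Tensor
    bk: Tensor
    bv: Tensor
    bo: Tensor

    @classmethod
    def create(
        cls, embed_dim: int, num_heads: int, rng: np.random.Generator | None = None
    ) -> "AttentionParams":
        if embed_dim % num_heads:
            raise ValueError(f"embed_dim {embed_dim} not divisible by num_heads {num_heads}")
        rng = rng or np.random.default_rng(0)

        def w():
            return Tensor(_glorot(rng, embed_dim, embed_dim), requires_grad=True)

        def b():
            return Tensor(np.zeros(embed_dim), requires_grad=True)

        return cls(num_heads, w(), w(), w(), w(), b(), b(), b(), b())

    @property
    def head_dim(self) -> int:
        return self.wq.shape[0] // self.num_heads

    @property
    def scale(self) -> float:
        return self.head_dim ** -0.5

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.wq": self.wq, f"{prefix}.wk": self.wk,
            f"{prefix}.wv": self.wv, f"{prefix}.wo": self.wo,
            f"{prefix}.bq": self.bq, f"{prefix}.bk": self.bk,
            f"{prefix}.bv": self.bv, f"{prefix}.bo": self.bo,
        }


def biased_attention_scores(scores, hbias: HausdorffBias | None, rpe) -> Tensor:
    """Add the distance bias and the per-head RPE bias to raw attention scores.

    ``scores`` is ``(batch, heads, N, N)``; the distance bias broadcasts over
    batch and head, the RPE bias over batch.  Either bias may be ``None``.
    """
    scores = ad.as_tensor(scores)
    n = scores.shape[-1]
    out = scores
    if hbias is not None:
        if hbias.matrix.shape != (n, n):
            raise ValueError(f"distance bias {hbias.matrix.shape} incompatible with N={n}")
        out = out + Tensor(hbias.matrix[None, None])
    if rpe is not None:
        rpe = ad.as_tensor(rpe)
        if rpe.shape[-2:] != (n, n) or rpe.shape[0] != scores.shape[1]:
            raise ValueError(
                f"RPE bias {rpe.shape} incompatible with scores {scores.shape}"
            )
        out = out + rpe.reshape((1,) + tuple(rpe.shape))
    return out


def _split_heads(x: Tensor, num_heads: int) -> Tensor:
    B, N, E = x.shape
    return x.reshape(B, N, num_heads, E // num_heads).transpose(0, 2, 1, 3)


def hausdorff_multi_head_attention(
    x: TokenSequence,
    params: AttentionParams,
    hbias: HausdorffBias | None = None,
    rpe=None,
    return_probs: bool = False,
):
    """Full self-attention over all N tokens with additive spatial biases.

    Scaled dot-product scores ``S = QK^T / sqrt(d)`` are offset by
    :func:`biased_attention_scores` before the softmax over keys, so rows of
    the attention probabilities remain probability vectors while spatially
    nearby (or positionally favoured) tokens receive more mass.
    """
    v = x.values
    q = _split_heads(v @ params.wq + params.bq, params.num_heads)
    k = _split_heads(v @ params.wk + params.bk, params.num_heads)
    val = _split_heads(v @ params.wv + params.bv, params.num_heads)
    scores = (q @ k.transpose(0, 1, 3, 2)) * params.scale
    scores = biased_attention_scores(scores, hbias, rpe)
    probs = ad.softmax(scores, axis=-1)
    ctx = probs @ val  # (B, h, N, d)
    B, h, N, d = ctx.shape
    merged = ctx.transpose(0, 2, 1, 3).reshape(B, N, h * d)
    out = merged @ params.wo + params.bo
    seq = TokenSequence(values=out, grid=x.grid)
    if return_probs:
        return seq, probs
    return seq


# ---------------------------------------------------------------------------
# MixFFN
# ---------------------------------------------------------------------------

@dataclass
class MixFfnParams:
    """Expansion, depthwise 3x3 kernel, inner layer norm, and projection."""

    fc1_weight: Tensor  # (embed_dim, C_exp)
    fc1_bias: Tensor
    dw_kernel: Tensor  # (3, 3, C_exp)
    ln_gamma: Tensor
    ln_beta: Tensor
    fc2_weight: Tensor  # (C_exp, embed_dim)
    fc2_bias: Tensor
    ln_eps: float = 1e-6

    @classmethod
    def create(
        cls, embed_dim: int, expansion: int = 4, rng: np.random.Generator | None = None
    ) -> "MixFfnParams":
        rng = rng or np.random.default_rng(0)
        c_exp = embed_dim * expansion
        # identity-centred depthwise init: centre tap 1 keeps early training stable
        kernel = np.zeros((3, 3, c_exp))
        kernel[1, 1, :] = 1.0
        kernel += rng.normal(0.0, 0.02, kernel.shape)
        return cls(
            fc1_weight=Tensor(_glorot(rng, embed_dim, c_exp), requires_grad=True),
            fc1_bias=Tensor(np.zeros(c_exp), requires_grad=True),
            dw_kernel=Tensor(kernel, requires_grad=True),
            ln_gamma=Tensor(np.ones(c_exp), requires_grad=True),
            ln_beta=Tensor(np.zeros(c_exp), requires_grad=True),
            fc2_weight=Tensor(_glorot(rng, c_exp, embed_dim), requires_grad=True),
            fc2_bias=Tensor(np.zeros(embed_dim), requires_grad=True),
        )

    @property
    def expanded_channels(self) -> int:
        return self.fc1_weight.shape[1]

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.fc1_weight": self.fc1_weight, f"{prefix}.fc1_bias": self.fc1_bias,
            f"{prefix}.dw_kernel": self.dw_kernel,
            f"{prefix}.ln_gamma": self.ln_gamma, f"{prefix}.ln_beta": self.ln_beta,
            f"{prefix}.fc2_weight": self.fc2_weight, f"{prefix}.fc2_bias": self.fc2_bias,
        }


def mix_ffn(x: TokenSequence, params: MixFfnParams) -> TokenSequence:
    """fc1 -> GELU -> reshape to 2D -> depthwise 3x3 -> flatten -> LN -> fc2.

    The depthwise step applies one 3x3 filter per expanded channel (zero
    'same' padding, cross-correlation convention) so each channel learns local
    spatial structure without cross-channel mixing.
    """
    B, N, _ = x.values.shape
    H, W = x.grid.height, x.grid.width
    u = ad.gelu(x.values @ params.fc1_weight + params.fc1_bias)
    c_exp = params.expanded_channels
    u_spatial = u.reshape(B, H, W, c_exp)
    u_dw = ad.depthwise_conv3x3(u_spatial, params.dw_kernel)
    u_flat = u_dw.reshape(B, N, c_exp)
    u_norm = ad.layer_norm(u_flat, params.ln_gamma, params.ln_beta, params.ln_eps)
    out = u_norm @ params.fc2_weight + params.fc2_bias
    return TokenSequence(values=out, grid=x.grid)


# ---------------------------------------------------------------------------
# encoder layer
# ---------------------------------------------------------------------------

@dataclass
class TransformerEncoderLayer:
    """Pre-norm residual block: x + Attn(LN(x)); then y + MixFFN(LN(y)).

    Owns its attention/FFN parameters and RPE tables; the static distance
    bias is supplied per call because it is shared by every layer of a stage.
    """

    attn: AttentionParams
    ffn: MixFfnParams
    rpe_tables: RpeTables
    ln1_gamma: Tensor
    ln1_beta: Tensor
    ln2_gamma: Tensor
    ln2_beta: Tensor
    ln_eps: float = 1e-6

    @classmethod
    def create(
        cls,
        embed_dim: int,
        num_heads: int,
        max_relative_position: int,
        expansion: int = 4,
        rng: np.random.Generator | None = None,
    ) -> "TransformerEncoderLayer":
        rng = rng or np.random.default_rng(0)
        return cls(
            attn=AttentionParams.create(embed_dim, num_heads, rng),
            ffn=MixFfnParams.create(embed_dim, expansion, rng),
            rpe_tables=RpeTables.create(max_relative_position, num_heads, rng),
            ln1_gamma=Tensor(np.ones(embed_dim), requires_grad=True),
            ln1_beta=Tensor(np.zeros(embed_dim), requires_grad=True),
            ln2_gamma=Tensor(np.ones(embed_dim), requires_grad=True),
            ln2_beta=Tensor(np.zeros(embed_dim), requires_grad=True),
        )

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        out = self.attn.parameters(f"{prefix}.attn")
        out.update(self.ffn.parameters(f"{prefix}.ffn"))
        out.update(
            {
                f"{prefix}.rpe_height": self.rpe_tables.height_table,
                f"{prefix}.rpe_width": self.rpe_tables.width_table,
                f"{prefix}.ln1_gamma": self.ln1_gamma, f"{prefix}.ln1_beta": self.ln1_beta,
                f"{prefix}.ln2_gamma": self.ln2_gamma, f"{prefix}.ln2_beta": self.ln2_beta,
            }
        )
        return out

    def __call__(self, x: TokenSequence, hbias: HausdorffBias | None) -> TokenSequence:
        rpe = compute_rpe_bias(self.rpe_tables, x.grid)
        h = ad.layer_norm(x.values, self.ln1_gamma, self.ln1_beta, self.ln_eps)
        attn_out = hausdorff_multi_head_attention(
            TokenSequence(h, x.grid), self.attn, hbias, rpe
        )
        y = x.values + attn_out.values
        h2 = ad.layer_norm(y, self.ln2_gamma, self.ln2_beta, self.ln_eps)
        ffn_out = mix_ffn(TokenSequence(h2, x.grid), self.ffn)
        return TokenSequence(values=y + ffn_out.values, grid=x.grid)
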