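"""Contracts of the patch embedding, biased attention, MixFFN and encoder layer."""

import numpy as np
import pytest

from spatioseg import autodiff as ad
from spatioseg.autodiff import Tensor
from spatioseg.biasing import PatchGrid, RpeTables, compute_hausdorff_bias, compute_rpe_bias
from spatioseg.layers import (
    AttentionParams,
    MixFfnParams,
    PatchEmbedParams,
    TokenSequence,
    TransformerEncoderLayer,
    adaptive_patch_embed,
    biased_attention_scores,
    hausdorff_multi_head_attention,
    mix_ffn,
)


def _embed_params(in_ch=3, dim=4, n=16, kernel=2, stride=2, rng=None):
    return PatchEmbedParams.create(in_ch, dim, n, kernel, stride, rng=rng)


class TestAdaptivePatchEmbed:
    def test_unit_patch_weight_is_identity_weighting(self, rng):
        """patch_weight initialized to ones leaves the conv+norm output untouched."""
        params = _embed_params(rng=rng)
        img = rng.uniform(0, 1, (2, 8, 8, 3))
        out = adaptive_patch_embed(img, params)
        # manual conv + layer norm, no weighting step
        cols = ad.extract_patches(Tensor(img), 2, 2)
        tokens = (cols @ params.proj_weight + params.proj_bias).data
        mu = tokens.mean(-1, keepdims=True)
        var = tokens.var(-1, keepdims=True)
        expected = (tokens - mu) / np.sqrt(var + params.ln_eps)
        np.testing.assert_allclose(out.values.data, expected, atol=1e-12)
        assert out.grid == PatchGrid(4, 4)

    def test_scaling_one_patch_is_invisible_after_layer_norm(self, rng):
        """Doubling one token's pre-norm vector cannot change its normalized output."""
        params = _embed_params(rng=rng)
        img = rng.uniform(0, 1, (1, 8, 8, 3))
        base = adaptive_patch_embed(img, params).values.data
        params.patch_weight.data[0] = 2.0
        scaled = adaptive_patch_embed(img, params).values.data
        np.testing.assert_allclose(scaled[0, 0], base[0, 0], atol=1e-6)
        np.testing.assert_allclose(scaled, base, atol=1e-6)

    def test_constant_prenorm_vector_normalizes_to_zero(self):
        """A token whose channels are all equal has zero-variance numerator ~ 0."""
        params = _embed_params(in_ch=1, dim=4, n=4, kernel=2, stride=2)
        params.proj_weight.data[:] = 1.0  # every channel gets the same patch sum
        img = np.ones((1, 4, 4, 1))
        out = adaptive_patch_embed(img, params).values.data
        np.testing.assert_allclose(out, 0.0, atol=1e-2)

    def test_patch_weight_length_mismatch_raises(self, rng):
        params = _embed_params(n=9, rng=rng)  # wrong N for an 8x8/stride-2 image
        with pytest.raises(ValueError, match="N=16"):
            adaptive_patch_embed(rng.uniform(0, 1, (1, 8, 8, 3)), params)


class TestBiasedScores:
    def test_no_biases_is_identity(self, rng):
        s = rng.normal(size=(2, 2, 4, 4))
        out = biased_attention_scores(Tensor(s), None, None)
        np.testing.assert_array_equal(out.data, s)

    def test_distance_bias_softmax_matches_hand_values(self):
        """Zero scores on a 1x3 grid: bias (0,-0.5,-1) gives the hand softmax."""
        grid = PatchGrid(1, 3)
        hbias = compute_hausdorff_bias(grid, epsilon=1e-8)
        s = Tensor(np.zeros((1, 1, 3, 3)))
        probs = ad.softmax(biased_attention_scores(s, hbias, None), axis=-1).data
        np.testing.assert_allclose(
            probs[0, 0, 0], [0.5064, 0.3071, 0.1863], atol=1e-3
        )

    def test_rpe_only_adds_bias_exactly(self, rng):
        grid = PatchGrid(2, 2)
        tables = RpeTables.create(2, 1, rng=rng)
        rpe = compute_rpe_bias(tables, grid)
        s = Tensor(np.zeros((1, 1, 4, 4)))
        out = biased_attention_scores(s, None, rpe)
        np.testing.assert_allclose(out.data[0], rpe.data, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        s = Tensor(np.zeros((1, 1, 4, 4)))
        hbias = compute_hausdorff_bias(PatchGrid(1, 3))
        with pytest.raises(ValueError):
            biased_attention_scores(s, hbias, None)


def _zero_qk_attention_params(dim, heads=1):
    params = AttentionParams.create(dim, heads, rng=np.random.default_rng(0))
    params.wq.data[:] = 0.0
    params.wk.data[:] = 0.0
    params.wv.data[:] = np.eye(dim)
    params.bv.data[:] = 0.0
    params.wo.data[:] = np.eye(dim)
    params.bo.data[:] = 0.0
    return params


class TestAttention:
    def test_uniform_attention_averages_values(self, rng):
        """Zero query/key projections and no biases give the mean of all tokens."""
        dim = 4
        params = _zero_qk_attention_params(dim)
        x = TokenSequence(Tensor(rng.normal(size=(2, 6, dim))), PatchGrid(2, 3))
        out = hausdorff_multi_head_attention(x, params).values.data
        expected = np.repeat(x.values.data.mean(axis=1, keepdims=True), 6, axis=1)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_distance_bias_weights_nearer_tokens(self, rng):
        """On a 1x3 grid the output is the hand-derived probability-weighted mean."""
        dim = 2
        params = _zero_qk_attention_params(dim)
        grid = PatchGrid(1, 3)
        vals = rng.normal(size=(1, 3, dim))
        hbias = compute_hausdorff_bias(grid, epsilon=1e-8)
        out = hausdorff_multi_head_attention(
            TokenSequence(Tensor(vals), grid), params, hbias
        ).values.data
        w = np.array([0.50648028, 0.30719589, 0.18632382])  # softmax(0,-.5,-1)
        np.testing.assert_allclose(out[0, 0], (w[:, None] * vals[0]).sum(0), atol=1e-6)

    @pytest.mark.parametrize("use_hbias,use_rpe", [(False, False), (True, False),
                                                   (False, True), (True, True)])
    def test_attention_rows_are_probability_vectors(self, rng, use_hbias, use_rpe):
        dim, heads = 8, 2
        grid = PatchGrid(3, 4)
        params = AttentionParams.create(dim, heads, rng=rng)
        hbias = compute_hausdorff_bias(grid) if use_hbias else None
        rpe = (
            compute_rpe_bias(RpeTables.create(4, heads, rng=rng), grid)
            if use_rpe
            else None
        )
        x = TokenSequence(Tensor(rng.normal(size=(2, 12, dim))), grid)
        _, probs = hausdorff_multi_head_attention(
            x, params, hbias, rpe, return_probs=True
        )
        np.testing.assert_allclose(probs.data.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("h,w", [(2, 2), (4, 3), (6, 6)])
    def test_locality_probabilities_decrease_with_distance(self, h, w):
        """With zero scores and no RPE, attention strictly prefers nearer tokens."""
        from spatioseg.biasing import make_centroids

        grid = PatchGrid(h, w)
        hbias = compute_hausdorff_bias(grid)
        probs = ad.softmax(
            biased_attention_scores(
                Tensor(np.zeros((1, 1, grid.n_tokens, grid.n_tokens))), hbias, None
            ),
            axis=-1,
        ).data[0, 0]
        cents = make_centroids(grid).astype(float)
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        for i in range(grid.n_tokens):
            order = np.argsort(d[i], kind="stable")
            ds, ps = d[i][order], probs[i][order]
            strict = ds[1:] > ds[:-1]
            assert np.all(ps[1:][strict] < ps[:-1][strict])

    def test_head_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AttentionParams.create(embed_dim=6, num_heads=4)


class TestMixFfn:
    def test_identity_kernel_makes_depthwise_step_identity(self, rng):
        c = 3
        x = rng.normal(size=(1, 4, 5, c))
        kernel = np.zeros((3, 3, c))
        kernel[1, 1, :] = 1.0
        out = ad.depthwise_conv3x3(Tensor(x), Tensor(kernel)).data
        np.testing.assert_array_equal(out, x)

    def test_impulse_response_is_point_reflected_kernel(self, rng):
        """Cross-correlating a centered impulse reproduces the kernel rotated 180 deg."""
        k = rng.normal(size=(3, 3, 1))
        x = np.zeros((1, 5, 5, 1))
        x[0, 2, 2, 0] = 1.0
        out = ad.depthwise_conv3x3(Tensor(x), Tensor(k)).data
        np.testing.assert_allclose(out[0, 1:4, 1:4, 0], k[::-1, ::-1, 0], atol=1e-12)
        assert np.all(out[0, 0] == 0) and np.all(out[0, 4] == 0)

    def test_depthwise_channel_independence(self, rng):
        """Perturbing input channel c changes only output channel c (exactly)."""
        c = 4
        kernel = Tensor(rng.normal(size=(3, 3, c)))
        x0 = rng.normal(size=(1, 5, 5, c))
        base = ad.depthwise_conv3x3(Tensor(x0), kernel).data
        for ch in range(c):
            xp = x0.copy()
            xp[0, 2, 3, ch] += 1.0
            out = ad.depthwise_conv3x3(Tensor(xp), kernel).data
            diff = out - base
            others = np.delete(diff, ch, axis=-1)
            np.testing.assert_array_equal(others, 0.0)
            assert np.abs(diff[..., ch]).max() > 0

    def test_full_block_shape_and_grid_preserved(self, rng):
        params = MixFfnParams.create(embed_dim=6, expansion=2, rng=rng)
        x = TokenSequence(Tensor(rng.normal(size=(2, 12, 6))), PatchGrid(3, 4))
        out = mix_ffn(x, params)
        assert out.values.shape == (2, 12, 6)
        assert out.grid == x.grid


class TestEncoderLayer:
    def _zero_layer(self, dim, heads, max_rel):
        layer = TransformerEncoderLayer.create(dim, heads, max_rel, rng=np.random.default_rng(3))
        for name, p in layer.parameters("l").items():
            p.data[:] = 0.0
        # layer norms must stay affine-neutral for the residual path
        layer.ln1_gamma.data[:] = 1.0
        layer.ln2_gamma.data[:] = 1.0
        layer.ffn.ln_gamma.data[:] = 1.0
        return layer

    def test_zero_weights_make_layer_identity(self, rng):
        grid = PatchGrid(2, 3)
        layer = self._zero_layer(4, 1, 3)
        x = TokenSequence(Tensor(rng.normal(size=(2, 6, 4))), grid)
        out = layer(x, compute_hausdorff_bias(grid))
        np.testing.assert_allclose(out.values.data, x.values.data, atol=1e-12)

    def test_shape_preserved_for_random_config(self, rng):
        grid = PatchGrid(4, 4)
        layer = TransformerEncoderLayer.create(8, 2, 4, rng=rng)
        x = TokenSequence(Tensor(rng.normal(size=(3, 16, 8))), grid)
        out = layer(x, compute_hausdorff_bias(grid))
        assert out.values.shape == x.values.shape

    def test_stacked_layers_deterministic_across_runs(self):
        grid = PatchGrid(3, 3)

        def run():
            rng = np.random.default_rng(99)
            layers = [TransformerEncoderLayer.create(4, 2, 3, rng=rng) for _ in range(2)]
            x = TokenSequence(
                Tensor(np.random.default_rng(1).normal(size=(1, 9, 4))), grid
            )
            hb = compute_hausdorff_bias(grid)
            for layer in layers:
                x = layer(x, hb)
            return x.values.data

        np.testing.assert_array_equal(run(), run())
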