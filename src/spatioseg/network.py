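"""Hierarchical encoder + all-MLP decoder segmentation model.

The encoder is a stack of stages; each stage runs an adaptive patch embedding
(strided conv + learnable per-patch weight + layer norm) followed by a number
of biased transformer encoder layers, producing one feature map per stage at
strictly decreasing spatial resolution.  The decoder linearly projects every
stage map to a common width, bilinearly upsamples all of them to the finest
grid, concatenates, fuses with a linear layer, projects to class logits and
upsamples to the input resolution.  Softmax is applied only at prediction
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .biasing import PatchGrid, cached_hausdorff_bias
from .layers import (
    PatchEmbedParams,
    TokenSequence,
    TransformerEncoderLayer,
    adaptive_patch_embed,
)

__all__ = ["ModelConfig", "SegmentationModel", "build_model", "count_parameters"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Per-stage lists must all have the same length.  The default mirrors a
    B0-family footprint: four stages with strides 4/2/2/2, widths
    32/64/160/256, heads 1/2/5/8, two layers per stage, expansion 4.
    ``kernel_sizes`` defaults to the strides (non-overlapping patches); set a
    larger kernel with matching ``paddings`` for overlapped embedding.
    """

    input_size: tuple[int, int, int] = (256, 256, 3)
    num_classes: int = 4
    strides: tuple[int, ...] = (4, 2, 2, 2)
    kernel_sizes: tuple[int, ...] | None = None
    paddings: tuple[int, ...] | None = None
    embed_dims: tuple[int, ...] = (32, 64, 160, 256)
    depths: tuple[int, ...] = (2, 2, 2, 2)
    num_heads: tuple[int, ...] = (1, 2, 5, 8)
    expansions: tuple[int, ...] = (4, 4, 4, 4)
    decoder_dim: int = 256
    bias_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.kernel_sizes is None:
            self.kernel_sizes = tuple(self.strides)
        if self.paddings is None:
            self.paddings = tuple(0 for _ in self.strides)
        lists = {
            "strides": self.strides,
            "kernel_sizes": self.kernel_sizes,
            "paddings": self.paddings,
            "embed_dims": self.embed_dims,
            "depths": self.depths,
            "num_heads": self.num_heads,
            "expansions": self.expansions,
        }
        lengths = {k: len(v) for k, v in lists.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"per-stage lists have inconsistent lengths: {lengths}")
        for dims, heads in zip(self.embed_dims, self.num_heads):
            if dims % heads:
                raise ValueError(f"embed_dim {dims} not divisible by num_heads {heads}")

    @property
    def n_stages(self) -> int:
        return len(self.strides)

    def stage_grids(self) -> list[PatchGrid]:
        h, w = self.input_size[0], self.input_size[1]
        grids = []
        for k, s, p in zip(self.kernel_sizes, self.strides, self.paddings):
            if (h + 2 * p - k) % s or (w + 2 * p - k) % s:
                raise ValueError(
                    f"stage input {h}x{w} not divisible by kernel {k} stride {s} pad {p}"
                )
            h = (h + 2 * p - k) // s + 1
            w = (w + 2 * p - k) // s + 1
            grids.append(PatchGrid(h, w))
        return grids

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("input_size", "strides", "kernel_sizes", "paddings", "embed_dims",
                    "depths", "num_heads", "expansions"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class SegmentationModel:
    """Built model exposing ``encode`` / ``decode`` / ``forward`` / ``predict``."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.grids = config.stage_grids()
        self.stages: list[dict] = []
        in_ch = config.input_size[2]
        for s in range(config.n_stages):
            grid = self.grids[s]
            embed = PatchEmbedParams.create(
                in_channels=in_ch,
                embed_dim=config.embed_dims[s],
                n_patches=grid.n_tokens,
                kernel_size=config.kernel_sizes[s],
                stride=config.strides[s],
                padding=config.paddings[s],
                rng=rng,
            )
            max_rel = max(grid.height, grid.width)
            layers = [
                TransformerEncoderLayer.create(
                    embed_dim=config.embed_dims[s],
                    num_heads=config.num_heads[s],
                    max_relative_position=max_rel,
                    expansion=config.expansions[s],
                    rng=rng,
                )
                for _ in range(config.depths[s])
            ]
            hbias = cached_hausdorff_bias(grid, config.bias_epsilon)
            self.stages.append({"embed": embed, "layers": layers, "hbias": hbias})
            in_ch = config.embed_dims[s]
        # all-MLP decoder
        dd = config.decoder_dim
        self.dec_proj_w = []
        self.dec_proj_b = []
        for s in range(config.n_stages):
            c = config.embed_dims[s]
            limit = np.sqrt(6.0 / (c + dd))
            self.dec_proj_w.append(Tensor(rng.uniform(-limit, limit, (c, dd)), requires_grad=True))
            self.dec_proj_b.append(Tensor(np.zeros(dd), requires_grad=True))
        fused_in = dd * config.n_stages
        limit = np.sqrt(6.0 / (fused_in + dd))
        self.fuse_w = Tensor(rng.uniform(-limit, limit, (fused_in, dd)), requires_grad=True)
        self.fuse_b = Tensor(np.zeros(dd), requires_grad=True)
        limit = np.sqrt(6.0 / (dd + config.num_classes))
        self.cls_w = Tensor(rng.uniform(-limit, limit, (dd, config.num_classes)), requires_grad=True)
        self.cls_b = Tensor(np.zeros(config.num_classes), requires_grad=True)

    # -- parameter access --------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for s, stage in enumerate(self.stages):
            out.update(stage["embed"].parameters(f"stage{s}.embed"))
            for i, layer in enumerate(stage["layers"]):
                out.update(layer.parameters(f"stage{s}.layer{i}"))
        for s in range(self.config.n_stages):
            out[f"decoder.proj{s}_w"] = self.dec_proj_w[s]
            out[f"decoder.proj{s}_b"] = self.dec_proj_b[s]
        out["decoder.fuse_w"] = self.fuse_w
        out["decoder.fuse_b"] = self.fuse_b
        out["decoder.cls_w"] = self.cls_w
        out["decoder.cls_b"] = self.cls_b
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            p.data[...] = state[k]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, weights_path, config_path) -> "SegmentationModel":
        config = ModelConfig.from_yaml(config_path)
        model = cls(config)
        with np.load(weights_path) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model

    # -- forward pieces ----------------------------------------------------
    def encode(self, images) -> list[TokenSequence]:
        """One token sequence (feature map) per stage; stage s+1 consumes stage s."""
        images = ad.as_tensor(images)
        expected = self.config.input_size
        if images.shape[1:] != tuple(expected):
            raise ValueError(f"input shape {images.shape[1:]} != configured {expected}")
        feats: list[TokenSequence] = []
        x = images
        for stage in self.stages:
            seq = adaptive_patch_embed(x, stage["embed"])
            for layer in stage["layers"]:
                seq = layer(seq, stage["hbias"])
            feats.append(seq)
            B = seq.values.shape[0]
            x = seq.values.reshape(B, seq.grid.height, seq.grid.width, seq.values.shape[2])
        return feats

    def decode(self, features: list[TokenSequence]) -> Tensor:
        """All-MLP fusion of multi-scale features into per-pixel class logits."""
        if not features:
            raise ValueError("decode requires at least one feature map")
        target = features[0].grid
        upsampled = []
        for s, seq in enumerate(features):
            B = seq.values.shape[0]
            proj = seq.values @ self.dec_proj_w[s] + self.dec_proj_b[s]
            spatial = proj.reshape(B, seq.grid.height, seq.grid.width, self.config.decoder_dim)
            upsampled.append(ad.bilinear_resize(spatial, target.height, target.width))
        fused = ad.concat(upsampled, axis=-1) @ self.fuse_w + self.fuse_b
        logits = fused @ self.cls_w + self.cls_b
        H, W, _ = self.config.input_size
        return ad.bilinear_resize(logits, H, W)

    def forward(self, images) -> Tensor:
        """Logits ``(batch, H, W, num_classes)`` at input resolution."""
        return self.decode(self.encode(images))

    def predict_probs(self, images) -> np.ndarray:
        return ad.softmax(self.forward(images), axis=-1).data

    def predict(self, images) -> np.ndarray:
        """Integer label masks ``(batch, H, W)`` by per-pixel argmax."""
        return np.argmax(self.forward(images).data, axis=-1).astype(np.int64)


def build_model(config: ModelConfig) -> SegmentationModel:
    """Deterministic construction: same config + seed gives identical weights."""
    return SegmentationModel(config)


def count_parameters(model: SegmentationModel, itemize: bool = False):
    """Exact count of trainable scalars; optionally itemize the spatial additions.

    The itemized report lists the per-stage ``patch_weight`` entries (one per
    patch) and the per-layer RPE table sizes (``2*(2*max_rel-1)*num_heads``),
    the additions this architecture makes on top of a plain SegFormer.
    """
    params = model.parameters()
    total = int(sum(p.data.size for p in params.values()))
    if not itemize:
        return total
    items: dict[str, int] = {}
    for name, p in params.items():
        if name.endswith("patch_weight") or ".rpe_" in name:
            items[name] = int(p.data.size)
    return total, items
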