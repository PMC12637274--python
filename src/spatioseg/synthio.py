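"""Synthetic image/mask generator and file I/O.

The generator emulates the structure of annotated cervigrams: a large
elliptical anatomical region (label 1) on a dark background (label 0), a
smaller elliptical region nested strictly inside it (label 2), and zero to
three irregular lesion blobs (label 3) contained in the outer region, each
with a distinct base colour, smooth illumination variation and pixel noise.
It also provides the mask-synchronized augmentation suite (geometric ops
applied identically to image and mask, photometric ops to the image only)
and PNG round-trip I/O.

No claim of photo-realism is made; the generator exists so the full pipeline
can be exercised and benchmarked without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from skimage import transform as sktransform

__all__ = [
    "Ellipse",
    "SceneSpec",
    "SamplePair",
    "GenerationError",
    "sample_scene",
    "render_scene",
    "generate_sample",
    "generate_dataset",
    "augment",
    "AUGMENT_OPS",
    "write_pair",
    "read_pair",
    "MASK_PALETTE",
]

N_CLASSES = 4
LABEL_BACKGROUND, LABEL_CERVIX, LABEL_COLUMNAR, LABEL_LESION = 0, 1, 2, 3

# base colours (RGB in [0,1]); lesions pale, mimicking acetowhite response
_BASE_COLOURS = np.array(
    [
        [0.22, 0.18, 0.24],  # background
        [0.78, 0.52, 0.52],  # outer (cervix) region
        [0.62, 0.30, 0.32],  # nested (columnar) region
        [0.88, 0.84, 0.78],  # lesion
    ]
)

# indexed-PNG palette for masks (only for viewing; labels are the pixel values)
MASK_PALETTE = [0, 0, 0, 200, 120, 120, 60, 180, 90, 255, 210, 60]

LESION_COUNT_PROBS = (0.30, 0.35, 0.25, 0.10)
MIN_CLASS_FRACTION = 0.01
MAX_ATTEMPTS = 100


class GenerationError(RuntimeError):
    """Raised when no feasible scene is found within the attempt budget."""


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (along angle, perpendicular)
    angle: float  # radians

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dy = rows - self.center[0]
        dx = cols - self.center[1]
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Concrete geometry and photometry of one synthetic scene."""

    image_size: int
    cervix: Ellipse
    columnar: Ellipse
    lesions: tuple[np.ndarray, ...]  # each (K, 2) polygon vertices (row, col)
    colours: np.ndarray  # (4, 3) per-label base colours
    noise_sd: float
    shading: float  # radial illumination falloff strength
    seed: int  # seeds the rendering noise


@dataclass
class SamplePair:
    """Aligned image ((H, W, 3) float in [0,1]) and integer label mask (H, W)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} misaligned"
            )


def _lesion_polygon(rng: np.random.Generator, center, r0: float, k: int = 24) -> np.ndarray:
    """Irregular blob: a circle with smooth low-frequency radial perturbation."""
    theta = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    pert = np.zeros(k)
    for freq in (2, 3, 5):
        pert += rng.uniform(0.0, 0.18) * np.sin(freq * theta + rng.uniform(0, 2 * np.pi))
    r = r0 * (1.0 + pert)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return np.column_stack([rows, cols])


def _rasterize(spec: SceneSpec) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    S = spec.image_size
    rows, cols = np.mgrid[0:S, 0:S].astype(float)
    mask = np.zeros((S, S), dtype=np.int64)
    cervix_mask = spec.cervix.contains(rows, cols)
    mask[cervix_mask] = LABEL_CERVIX
    col_mask = spec.columnar.contains(rows, cols)
    mask[col_mask] = LABEL_COLUMNAR
    for poly in spec.lesions:
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(S, S))
        lesion = np.zeros((S, S), dtype=bool)
        lesion[rr, cc] = True
        mask[lesion & cervix_mask] = LABEL_LESION  # lesions clipped to the outer region
    return mask


def sample_scene(
    rng: np.random.Generator,
    image_size: int = 256,
    n_lesions: int | None = None,
    noise_sd: float = 0.03,
) -> SceneSpec:
    """Draw scene geometry satisfying the containment and area invariants.

    The nested region must rasterize strictly inside the outer region and
    every non-background class must cover at least 1% of the pixels (the
    lesion class only when lesions were requested); infeasible draws are
    rejected, up to :data:`MAX_ATTEMPTS`.
    """
    S = image_size
    for _ in range(MAX_ATTEMPTS):
        count = (
            int(rng.choice(4, p=LESION_COUNT_PROBS)) if n_lesions is None else n_lesions
        )
        center = (S / 2 + rng.uniform(-0.05, 0.05) * S, S / 2 + rng.uniform(-0.05, 0.05) * S)
        cervix = Ellipse(
            center=center,
            axes=(rng.uniform(0.30, 0.40) * S, rng.uniform(0.26, 0.36) * S),
            angle=rng.uniform(0, np.pi),
        )
        columnar = Ellipse(
            center=(center[0] + rng.uniform(-0.03, 0.03) * S,
                    center[1] + rng.uniform(-0.03, 0.03) * S),
            axes=(cervix.axes[0] * rng.uniform(0.35, 0.55),
                  cervix.axes[1] * rng.uniform(0.35, 0.55)),
            angle=rng.uniform(0, np.pi),
        )
        rows, cols = np.mgrid[0:S, 0:S].astype(float)
        cervix_mask = cervix.contains(rows, cols)
        col_mask = columnar.contains(rows, cols)
        if not (col_mask <= cervix_mask).all():
            continue
        lesions = []
        interior = np.argwhere(cervix_mask & ~col_mask)
        for _ in range(count):
            if len(interior) == 0:
                break
            c = interior[rng.integers(len(interior))].astype(float)
            r0 = rng.uniform(0.07, 0.12) * S
            lesions.append(_lesion_polygon(rng, c, r0))
        colours = np.clip(_BASE_COLOURS + rng.uniform(-0.04, 0.04, (4, 3)), 0.0, 1.0)
        spec = SceneSpec(
            image_size=S,
            cervix=cervix,
            columnar=columnar,
            lesions=tuple(lesions),
            colours=colours,
            noise_sd=noise_sd,
            shading=rng.uniform(0.05, 0.25),
            seed=int(rng.integers(2**31 - 1)),
        )
        mask = _rasterize(spec)
        frac = np.bincount(mask.ravel(), minlength=N_CLASSES) / mask.size
        need = [LABEL_CERVIX, LABEL_COLUMNAR] + ([LABEL_LESION] if count > 0 else [])
        if all(frac[c] >= MIN_CLASS_FRACTION for c in need):
            return spec
    raise GenerationError(f"no feasible scene after {MAX_ATTEMPTS} attempts")


def render_scene(spec: SceneSpec) -> SamplePair:
    """Deterministically rasterize and shade a scene specification."""
    from skimage.filters import gaussian

    mask = _rasterize(spec)
    rng = np.random.default_rng(spec.seed)
    image = spec.colours[mask]
    S = spec.image_size
    rows, cols = np.mgrid[0:S, 0:S].astype(float)
    r2 = ((rows - spec.cervix.center[0]) ** 2 + (cols - spec.cervix.center[1]) ** 2) / (
        (S / 2) ** 2
    )
    image = image * (1.0 - spec.shading * r2)[..., None]
    image = gaussian(image, sigma=1.0, channel_axis=-1)  # soft anatomical edges
    image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    return SamplePair(image=np.clip(image, 0.0, 1.0), mask=mask)


def generate_sample(
    spec_or_seed: SceneSpec | int,
    image_size: int = 256,
    n_lesions: int | None = None,
    noise_sd: float = 0.03,
) -> SamplePair:
    """One synthetic pair, bit-reproducible from a seed or an explicit spec."""
    if isinstance(spec_or_seed, SceneSpec):
        return render_scene(spec_or_seed)
    rng = np.random.default_rng(spec_or_seed)
    spec = sample_scene(rng, image_size=image_size, n_lesions=n_lesions, noise_sd=noise_sd)
    return render_scene(spec)


def generate_dataset(
    n: int,
    seed: int,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    image_size: int = 256,
    noise_sd: float = 0.03,
) -> dict:
    """n samples split into disjoint train/val/test index sets.

    Validation and test sizes are ``round(n * fraction)``; the remainder goes
    to train.  Per-sample seeds are derived from the master seed so any
    sample is reproducible in isolation.
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    if abs(sum(split) - 1.0) > 1e-9 or any(f < 0 for f in split):
        raise ValueError(f"split fractions must be non-negative and sum to 1, got {split}")
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n)
    perm = rng.permutation(n)
    n_val = int(round(n * split[1]))
    n_test = int(round(n * split[2]))
    n_train = n - n_val - n_test
    idx = {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }
    pairs = [
        generate_sample(int(s), image_size=image_size, noise_sd=noise_sd)
        for s in sample_seeds
    ]
    out = {name: [pairs[i] for i in ids] for name, ids in idx.items()}
    out["indices"] = idx
    out["seeds"] = sample_seeds
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENT_OPS = ("hflip", "vflip", "rotate", "crop", "scale", "noise", "brightness_contrast")

# default magnitudes; exposed so experiments can widen or narrow them
AUGMENT_DEFAULTS = {
    "rotate_max_deg": 25.0,
    "crop_fraction": (0.70, 0.95),
    "scale_range": (0.9, 1.1),
    "noise_sd": 0.02,
    "brightness": 0.1,
    "contrast": (0.8, 1.2),
}


def _background_colour(pair: SamplePair) -> float:
    bg = pair.image[pair.mask == LABEL_BACKGROUND]
    return float(np.median(bg)) if len(bg) else 0.0


def augment(pair: SamplePair, ops, seed: int, params: dict | None = None) -> SamplePair:
    """Apply named augmentations in order, masks kept synchronized.

    Geometric ops (hflip, vflip, rotate, crop, scale) transform image and
    mask identically — the mask with nearest-neighbour interpolation so no
    new labels appear; exposed pixels are filled with background.  Photometric
    ops (noise, brightness_contrast) touch the image only.  The image is
    clipped to [0, 1] and returned at the original size.
    """
    p = dict(AUGMENT_DEFAULTS)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    img = pair.image.astype(np.float64).copy()
    mask = pair.mask.astype(np.int64).copy()
    size = mask.shape
    for op in ops:
        if op == "hflip":
            img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
        elif op == "vflip":
            img, mask = img[::-1].copy(), mask[::-1].copy()
        elif op == "rotate":
            angle = rng.uniform(-p["rotate_max_deg"], p["rotate_max_deg"])
            cval = _background_colour(SamplePair(img, mask))
            img = sktransform.rotate(img, angle, order=1, mode="constant", cval=cval)
            mask = sktransform.rotate(
                mask.astype(float), angle, order=0, mode="constant", cval=0.0,
                preserve_range=True,
            ).astype(np.int64)
        elif op == "crop":
            frac = rng.uniform(*p["crop_fraction"])
            ch, cw = max(1, int(size[0] * frac)), max(1, int(size[1] * frac))
            top = rng.integers(0, size[0] - ch + 1)
            left = rng.integers(0, size[1] - cw + 1)
            img = img[top : top + ch, left : left + cw]
            mask = mask[top : top + ch, left : left + cw]
            img, mask = _resize_pair(img, mask, size)
        elif op == "scale":
            factor = rng.uniform(*p["scale_range"])
            nh, nw = max(1, int(round(size[0] * factor))), max(1, int(round(size[1] * factor)))
            img, mask = _resize_pair(img, mask, (nh, nw))
            img, mask = _fit_to(img, mask, size, _background_colour(SamplePair(img, mask)))
        elif op == "noise":
            img = img + rng.normal(0.0, p["noise_sd"], img.shape)
        elif op == "brightness_contrast":
            b = rng.uniform(-p["brightness"], p["brightness"])
            c = rng.uniform(*p["contrast"])
            img = (img - 0.5) * c + 0.5 + b
        else:
            raise ValueError(f"unknown augmentation op: {op!r}")
    return SamplePair(image=np.clip(img, 0.0, 1.0), mask=mask)


def _resize_pair(img, mask, size):
    img = sktransform.resize(img, size + (3,) if img.ndim == 3 else size, order=1,
                             mode="edge", anti_aliasing=False)
    mask = sktransform.resize(
        mask.astype(float), size, order=0, mode="edge", anti_aliasing=False,
        preserve_range=True,
    ).astype(np.int64)
    return img, mask


def _fit_to(img, mask, size, cval):
    """Center-crop or background-pad to the target size."""
    H, W = mask.shape
    th, tw = size
    # crop
    if H > th:
        top = (H - th) // 2
        img, mask = img[top : top + th], mask[top : top + th]
    if W > tw:
        left = (W - tw) // 2
        img, mask = img[:, left : left + tw], mask[:, left : left + tw]
    H, W = mask.shape
    if H < th or W < tw:
        pt, pl = (th - H) // 2, (tw - W) // 2
        pb, pr = th - H - pt, tw - W - pl
        img = np.pad(img, ((pt, pb), (pl, pr), (0, 0)), constant_values=cval)
        mask = np.pad(mask, ((pt, pb), (pl, pr)), constant_values=LABEL_BACKGROUND)
    return img, mask


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_pair(pair: SamplePair, image_path, mask_path) -> None:
    """Image as 8-bit RGB PNG; mask as single-channel indexed PNG (labels = pixel values)."""
    img8 = np.round(np.clip(pair.image, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(img8, mode="RGB").save(image_path)
    m = Image.fromarray(pair.mask.astype(np.uint8), mode="P")
    m.putpalette(MASK_PALETTE + [0] * (768 - len(MASK_PALETTE)))
    m.save(mask_path)


def read_pair(image_path, mask_path) -> SamplePair:
    """Inverse of :func:`write_pair`; masks round-trip exactly, images within 1/255."""
    img = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float64) / 255.0
    mask = np.asarray(Image.open(mask_path), dtype=np.int64)
    if img.shape[:2] != mask.shape:
        raise ValueError(
            f"image {img.shape[:2]} and mask {mask.shape} sizes do not match"
        )
    return SamplePair(image=img, mask=mask)
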