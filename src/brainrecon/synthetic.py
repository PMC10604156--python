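"""Synthetic paired {fMRI, image} datasets with a known forward model.

The generator emulates the structure of the Generic Object Decoding
benchmark: 150 training classes x 8 images (1200 training stimuli), 50
test stimuli from classes disjoint from training, each test stimulus
presented repeatedly (35 times by default) with independent noise.

Ground truth is fully known: per-class latent centroids plus within-class
jitter define each stimulus' latent vector; toy images are rendered
deterministically from the first four latent dimensions; "visual" and
"text" features are seeded random projections of rendered-pixel statistics
and class identity.  Voxels are a linear (optionally tanh-squashed)
mixture of the concatenated true features plus Gaussian noise scaled to a
per-voxel signal-to-noise ratio.  All randomness flows through one seeded
generator, so datasets are bit-reproducible.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backends import MockFeatureEncoder
from .data_model import (
    CaptionSet,
    FeatureMatrix,
    ImageSet,
    PairedDataset,
    ValidationError,
    VoxelMatrix,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "render_toy_images",
    "make_captions",
    "latent_layout",
    "save_dataset",
]

# a compact color vocabulary: with GOD-sized class counts every color word
# occurs in the training captions, so test-caption semantics stay within
# the span of what the text channel saw during training
_COLOR_WORDS = ["red", "orange", "yellow", "green", "cyan", "blue", "violet", "magenta"]
_SHAPES = ("disc", "square", "triangle")
# shape thresholds at the tertiles of a standard normal
_SHAPE_T1, _SHAPE_T2 = -0.4307272992954576, 0.4307272992954576


@dataclass
class SyntheticConfig:
    """Study-shaped generation parameters.

    Defaults mirror the benchmark structure (150 classes x 8 = 1200 train,
    50 disjoint-class test stimuli, 35 repeats) at desk-scale feature and
    voxel dimensionality; snr is var(signal)/var(noise) per voxel.
    """

    n_train: int = 1200
    n_test: int = 50
    n_classes_train: int = 150
    images_per_class: int = 8
    n_test_repeats: int = 35
    n_voxels: int = 2000
    latent_dim: int = 64
    visual_dim: int = 128
    text_dim: int = 32
    snr: float = 5.0
    nonlinearity: str = "none"  # none | tanh
    # pre-activation gain for the tanh forward model; standardized mixing
    # gives unit pre-activation variance, so a gain of 2 drives the
    # squashing into its saturating (genuinely nonlinear) regime
    nonlinearity_gain: float = 2.0
    seed: int = 0
    image_size: int = 64
    jitter_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_train != self.n_classes_train * self.images_per_class:
            raise ValidationError(
                f"n_train={self.n_train} must equal n_classes_train x images_per_class "
                f"= {self.n_classes_train * self.images_per_class}"
            )
        if not (self.snr > 0):
            raise ValidationError("snr must be positive (np.inf for noiseless)")
        if self.nonlinearity not in ("none", "tanh"):
            raise ValidationError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.latent_dim < 4:
            raise ValidationError("latent_dim must be >= 4 (four dims drive rendering)")


@dataclass
class SyntheticTruth:
    """Everything the simulation knows that a real experiment would not.

    Feature matrices are stored per split (``{"train": ..., "test": ...}``)
    and are row-aligned with the corresponding dataset after repeat
    averaging.
    """

    true_latents: dict[str, FeatureMatrix]
    true_visual: dict[str, FeatureMatrix]
    true_text: dict[str, FeatureMatrix]
    mixing_matrix: np.ndarray
    class_of: dict[str, list[str]]
    vocabulary: list[str]
    feature_seed: int
    noise_sd: np.ndarray = field(default=None)


def latent_layout(latent_dim: int) -> list[tuple[int, ...]]:
    """Hierarchical layer shapes a codec splits a flat latent into: a small
    top layer of 4 (the rendering-controlling dims) plus two larger ones."""
    rest = latent_dim - 4
    mid = rest // 3
    return [(4,), (mid,), (rest - mid,)]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _hue_of(v: float) -> float:
    # squash an unbounded latent into [0, 1) hue
    return float(0.5 * (np.tanh(v) + 1.0)) % 1.0


def _shape_of(v: float) -> int:
    """Shape index from the second latent dim; boundary values take the
    lower shape index (documented tie-break)."""
    if v <= _SHAPE_T1:
        return 0  # disc
    if v <= _SHAPE_T2:
        return 1  # square
    return 2  # triangle


def render_toy_images(latents: FeatureMatrix | np.ndarray, size: int = 64) -> ImageSet:
    """Deterministically render one toy image per latent row.

    Latent dims 0-3 control background hue, foreground shape
    (disc/square/triangle via standard-normal tertile thresholds),
    horizontal shape position, and shape scale; the remaining dims are
    rendering-inert.  Pixel values are quantized to 8-bit levels so a PNG
    round trip is exact.  Identical latents give pixel-identical images.
    """
    vals = latents.values if isinstance(latents, FeatureMatrix) else np.asarray(latents)
    if vals.ndim == 1:
        vals = vals[np.newaxis, :]
    if vals.shape[1] < 4:
        raise ValidationError("need latent_dim >= 4 to render")
    images = []
    yy, xx = np.mgrid[0:size, 0:size]
    for row in vals:
        hue = _hue_of(row[0])
        shape = _shape_of(row[1])
        cx = size / 2.0 + round(float(np.tanh(row[2])) * size / 4.0)
        cy = size / 2.0
        r = max(2, round(size / 8.0 * (1.0 + 0.5 * float(np.tanh(row[3])))))

        bg = np.array(colorsys.hsv_to_rgb(hue, 0.45, 0.92))
        fg = np.array(colorsys.hsv_to_rgb((hue + 0.5) % 1.0, 0.85, 0.65))

        if shape == 0:
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        elif shape == 1:
            mask = (np.abs(yy - cy) <= r) & (np.abs(xx - cx) <= r)
        else:  # upward triangle
            mask = (yy >= cy - r) & (yy <= cy + r) & (
                np.abs(xx - cx) <= (yy - (cy - r)) / 2.0
            )

        img = np.where(mask[..., None], fg, bg)
        images.append(np.round(img * 255.0) / 255.0)
    ids = [f"img{i:05d}" for i in range(len(images))]
    return ImageSet(images, ids)


def make_captions(
    class_of: list[str], vocabulary: list[str] | None = None, image_ids: list[str] | None = None
) -> CaptionSet:
    """Template captions: ``"a photo of a <class-name>"`` per image."""
    if vocabulary is not None:
        vocab = set(vocabulary)
        unknown = sorted(set(class_of) - vocab)
        if unknown:
            raise ValidationError(f"labels outside the class vocabulary: {unknown[:10]}")
    caps = [f"a photo of a {name}" for name in class_of]
    if image_ids is None:
        image_ids = [f"img{i:05d}" for i in range(len(caps))]
    return CaptionSet(caps, image_ids)


def _class_names(centroids: np.ndarray) -> list[str]:
    """Deterministic, unique class names derived from each centroid's
    rendered shape and hue."""
    names, seen = [], {}
    for row in centroids:
        shape = _SHAPES[_shape_of(row[1])]
        color = _COLOR_WORDS[int(_hue_of(row[0]) * len(_COLOR_WORDS)) % len(_COLOR_WORDS)]
        base = f"{shape}_{color}"
        k = seen.get(base, 0)
        seen[base] = k + 1
        names.append(base if k == 0 else f"{base}_{k + 1}")
    return names


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[PairedDataset, PairedDataset, SyntheticTruth]:
    """Generate GOD-shaped train/test splits plus full ground truth.

    Per-class latent centroids are drawn once; each image's latent is its
    class centroid plus within-class jitter.  Voxels are
    ``standardize(concat(latents, visual, text)) @ mixing_matrix`` passed
    through the configured nonlinearity, plus Gaussian noise with
    per-voxel variance var(signal)/snr.  The test split carries
    ``n_test_repeats`` rows per stimulus with independent noise.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    feature_seed = (cfg.seed * 1_000_003 + 17) % (2**31)

    n_classes = cfg.n_classes_train + cfg.n_test
    centroids = rng.normal(0.0, 1.0, (n_classes, cfg.latent_dim))
    names = _class_names(centroids)
    train_classes = names[: cfg.n_classes_train]
    test_classes = names[cfg.n_classes_train :]

    # latents: class centroid + within-class jitter
    train_class_idx = np.repeat(np.arange(cfg.n_classes_train), cfg.images_per_class)
    lat_train = centroids[train_class_idx] + rng.normal(
        0.0, cfg.jitter_sd, (cfg.n_train, cfg.latent_dim)
    )
    test_class_idx = cfg.n_classes_train + np.arange(cfg.n_test)
    lat_test = centroids[test_class_idx] + rng.normal(
        0.0, cfg.jitter_sd, (cfg.n_test, cfg.latent_dim)
    )
    class_of_train = [train_classes[i] for i in train_class_idx]
    class_of_test = list(test_classes)

    # stimuli; stimulus sets contain visually distinct images (as in real
    # photo benchmarks), so any row whose quantized render collides with an
    # earlier one has its within-class jitter redrawn
    from .backends import image_fingerprint

    seen: set[str] = set()

    def _render_unique(lat: np.ndarray, centroid_rows: np.ndarray) -> list[np.ndarray]:
        images = []
        for i in range(lat.shape[0]):
            for attempt in range(200):
                img = render_toy_images(lat[i : i + 1], cfg.image_size).images[0]
                fp = image_fingerprint(img)
                if fp not in seen:
                    break
                lat[i] = centroid_rows[i] + rng.normal(0.0, cfg.jitter_sd, cfg.latent_dim)
            else:
                raise ValidationError("could not render a distinct stimulus after 200 tries")
            seen.add(fp)
            images.append(img)
        return images

    img_train = ImageSet(
        _render_unique(lat_train, centroids[train_class_idx]),
        [f"train_{i:04d}" for i in range(cfg.n_train)],
        class_of_train,
    )
    img_test = ImageSet(
        _render_unique(lat_test, centroids[test_class_idx]),
        [f"test_{i:03d}" for i in range(cfg.n_test)],
        class_of_test,
    )

    cap_train = make_captions(class_of_train, names, img_train.image_ids)
    cap_test = make_captions(class_of_test, names, img_test.image_ids)

    # "true" visual/text features via the seeded mock encoder
    encoder = MockFeatureEncoder(
        visual_dim=cfg.visual_dim,
        text_dim=cfg.text_dim,
        vocabulary=names,
        seed=feature_seed,
    )
    vis_train = np.stack([encoder.encode_image(im) for im in img_train.images])
    vis_test = np.stack([encoder.encode_image(im) for im in img_test.images])
    txt_train = np.stack([encoder.encode_text(c) for c in cap_train.captions])
    txt_test = np.stack([encoder.encode_text(c) for c in cap_test.captions])

    # voxel forward model
    F_train = np.hstack([lat_train, vis_train, txt_train])
    F_test = np.hstack([lat_test, vis_test, txt_test])
    f_mean = F_train.mean(axis=0)
    f_std = F_train.std(axis=0)
    f_std = np.where(f_std == 0, 1.0, f_std)
    Fs_train = (F_train - f_mean) / f_std
    Fs_test = (F_test - f_mean) / f_std

    d_total = F_train.shape[1]
    mixing = rng.normal(0.0, 1.0 / np.sqrt(d_total), (d_total, cfg.n_voxels))
    sig_train = Fs_train @ mixing
    sig_test = Fs_test @ mixing
    if cfg.nonlinearity == "tanh":
        sig_train = np.tanh(cfg.nonlinearity_gain * sig_train)
        sig_test = np.tanh(cfg.nonlinearity_gain * sig_test)

    if np.isinf(cfg.snr):
        noise_sd = np.zeros(cfg.n_voxels)
    else:
        noise_sd = np.sqrt(sig_train.var(axis=0) / cfg.snr)

    x_train = sig_train + rng.normal(0.0, 1.0, sig_train.shape) * noise_sd
    voxel_ids = [f"vox{j:05d}" for j in range(cfg.n_voxels)]
    vm_train = VoxelMatrix(x_train, img_train.image_ids, voxel_ids)

    # test: repeats with independent noise, stimulus-major order
    rep_sig = np.repeat(sig_test, cfg.n_test_repeats, axis=0)
    x_test = rep_sig + rng.normal(0.0, 1.0, rep_sig.shape) * noise_sd
    repeat_of = [iid for iid in img_test.image_ids for _ in range(cfg.n_test_repeats)]
    sample_ids = [
        f"{iid}_rep{r:02d}" for iid in img_test.image_ids for r in range(cfg.n_test_repeats)
    ]
    vm_test = VoxelMatrix(x_test, sample_ids, voxel_ids, repeat_of)

    train = PairedDataset(vm_train, img_train, cap_train, split="train")
    test = PairedDataset(vm_test, img_test, cap_test, split="test")

    truth = SyntheticTruth(
        true_latents={
            "train": FeatureMatrix(lat_train, "latent", latent_layout(cfg.latent_dim)),
            "test": FeatureMatrix(lat_test, "latent", latent_layout(cfg.latent_dim)),
        },
        true_visual={
            "train": FeatureMatrix(vis_train, "visual"),
            "test": FeatureMatrix(vis_test, "visual"),
        },
        true_text={
            "train": FeatureMatrix(txt_train, "text"),
            "test": FeatureMatrix(txt_test, "text"),
        },
        mixing_matrix=mixing,
        class_of={"train": class_of_train, "test": class_of_test},
        vocabulary=names,
        feature_seed=feature_seed,
        noise_sd=noise_sd,
    )
    return train, test, truth


def save_dataset(
    train: PairedDataset,
    test: PairedDataset,
    directory: str | Path,
    cfg: SyntheticConfig | None = None,
) -> Path:
    """Persist a paired dataset as NPZ + PNG + TSV with a YAML manifest."""
    import yaml

    from .data_model import save_captions, save_images, save_voxel_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for split, ds in (("train", train), ("test", test)):
        save_voxel_matrix(ds.fmri, directory / f"{split}_voxels.npz")
        save_images(ds.images, directory / f"{split}_images")
        if ds.captions is not None:
            save_captions(ds.captions, directory / f"{split}_captions.tsv")
    manifest = {"splits": ["train", "test"]}
    if cfg is not None:
        manifest["config"] = {k: (None if v is None else (float(v) if isinstance(v, float) else v)) for k, v in cfg.__dict__.items()}
        manifest["seed"] = cfg.seed
    with open(directory / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    return directory
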