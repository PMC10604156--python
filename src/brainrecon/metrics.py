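"""Reconstruction quality metrics.

Low-level fidelity is measured by pixel-wise Pearson correlation (PixCorr)
and the structural similarity index (SSIM); high-level semantic fidelity by
feature-space distance d = 1 - centered cosine similarity between deep
feature vectors of the two images (equivalently 1 - Pearson r), computed
under one or more pluggable feature extractors.  In the full-scale protocol
the extractors are pretrained networks (Inception-V3, a CLIP visual
encoder, SwAV-ResNet50); the package ships seeded random-projection
extractors with the same contract so the protocol runs without downloads.

Before comparison all images are resized to a common square size; PixCorr
and feature extraction operate on flattened RGB, SSIM on an ITU-R 601
luminance conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import ImageSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "MetricReport",
    "pixcorr",
    "ssim_global",
    "ssim_windowed",
    "feature_distance",
    "resize_to_common",
    "evaluate_reconstructions",
    "LUMA_WEIGHTS",
]

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])  # ITU-R 601


def _flat(a: np.ndarray) -> np.ndarray:
    return np.asarray(a, dtype=np.float64).ravel()


def pixcorr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between flattened pixels (or vectors)."""
    xf, yf = _flat(x), _flat(y)
    if xf.shape != yf.shape:
        raise ValidationError(f"shape mismatch after flattening: {xf.shape} vs {yf.shape}")
    xc = xf - xf.mean()
    yc = yf - yf.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValidationError("zero-variance input: correlation undefined")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def ssim_global(
    x: np.ndarray,
    y: np.ndarray,
    c1: float | None = None,
    c2: float | None = None,
    dynamic_range: float = 1.0,
) -> float:
    """Single-window SSIM evaluated with global image statistics:

        ((2 mu_x mu_y + c1)(2 sigma_xy + c2))
        / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    Defaults c1 = (0.01 L)^2, c2 = (0.03 L)^2 with dynamic range L.
    Multichannel images are converted to luminance first.  For the
    standard sliding-window variant see :func:`ssim_windowed`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim == 3:
        x = x @ LUMA_WEIGHTS
        y = y @ LUMA_WEIGHTS
    L = dynamic_range
    if c1 is None:
        c1 = (0.01 * L) ** 2
    if c2 is None:
        c2 = (0.03 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def ssim_windowed(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0) -> float:
    """Standard sliding-window SSIM (labeled distinctly from the global
    mode); delegates to scikit-image."""
    from skimage.metrics import structural_similarity

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim == 3:
        x = x @ LUMA_WEIGHTS
        y = y @ LUMA_WEIGHTS
    return float(structural_similarity(x, y, data_range=dynamic_range))


def feature_distance(mu: np.ndarray, nu: np.ndarray) -> float:
    """1 - centered cosine similarity between two feature vectors:

        d = 1 - (mu - mean(mu)) . (nu - mean(nu))
              / (||mu - mean(mu)|| ||nu - mean(nu)||)

    This equals 1 - Pearson(mu, nu); d is in [0, 2], 0 for identical
    vectors (up to positive affine rescaling), 2 for anticorrelated ones.
    Multidimensional feature maps are flattened first.
    """
    m, n = _flat(mu), _flat(nu)
    if m.shape != n.shape:
        raise ValidationError(f"length mismatch: {m.shape} vs {n.shape}")
    if m.size < 2:
        raise ValidationError("need at least 2 feature dims")
    mc = m - m.mean()
    nc = n - n.mean()
    nm, nn = np.linalg.norm(mc), np.linalg.norm(nc)
    if nm == 0 or nn == 0:
        raise ValidationError("constant feature vector: distance undefined")
    return float(np.clip(1.0 - mc @ nc / (nm * nn), 0.0, 2.0))


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------


def _bilinear_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resample to size x size with half-pixel-center alignment."""
    from scipy.ndimage import map_coordinates

    h, w = img.shape[:2]
    if h == size and w == size:
        return img.copy()
    ry = (np.arange(size) + 0.5) * h / size - 0.5
    rx = (np.arange(size) + 0.5) * w / size - 0.5
    yy, xx = np.meshgrid(ry, rx, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()])
    if img.ndim == 2:
        return map_coordinates(img, coords, order=1, mode="nearest").reshape(size, size)
    out = np.empty((size, size, img.shape[2]))
    for c in range(img.shape[2]):
        out[..., c] = map_coordinates(img[..., c], coords, order=1, mode="nearest").reshape(
            size, size
        )
    return out


def resize_to_common(images: ImageSet, size: int) -> ImageSet:
    """Bilinearly resize every image to size x size, clipping to [0, 1]."""
    if size < 8:
        raise ValidationError("common size must be >= 8 pixels")
    out = []
    for iid, im in zip(images.image_ids, images.images):
        if im.shape[0] == 0 or im.shape[1] == 0:
            raise ValidationError(f"image {iid}: zero area")
        out.append(np.clip(_bilinear_resize(im, size), 0.0, 1.0))
    return ImageSet(out, list(images.image_ids), images.class_labels)


# ---------------------------------------------------------------------------
# Feature extractors
# ---------------------------------------------------------------------------


@dataclass
class FeatureExtractor:
    """A deterministic image -> 1-D feature vector map with fixed dimension."""

    name: str
    extract: Callable[[np.ndarray], np.ndarray]
    dim: int


def RandomProjectionExtractor(
    name: str, dim: int = 64, seed: int = 0, input_size: int = 32
) -> FeatureExtractor:
    """A seeded random linear projection of downsampled pixels.

    Deterministic and fixed-dimensional, so it satisfies the extractor
    contract; it stands in for pretrained networks in download-free runs
    (real pretrained extractors plug into the same interface).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    proj = rng.normal(0.0, 1.0 / np.sqrt(input_size * input_size * 3), (input_size**2 * 3, dim))

    def extract(img: np.ndarray) -> np.ndarray:
        small = _bilinear_resize(np.asarray(img, dtype=np.float64), input_size)
        return small.ravel() @ proj

    return FeatureExtractor(name=name, extract=extract, dim=dim)


# ---------------------------------------------------------------------------
# Report harness
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Per-image metric table plus aggregate means and run metadata."""

    per_image: pd.DataFrame
    aggregate: dict[str, float]
    metadata: dict

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.per_image.to_csv(path)
        return path

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        with open(path, "w") as f:
            yaml.safe_dump(
                {"aggregate": self.aggregate, "metadata": self.metadata}, f, sort_keys=False
            )
        return path

    def render_table(self) -> str:
        """Text table: low-level metrics (higher better) then feature
        distances (lower better)."""
        cols = list(self.per_image.columns)
        low = [c for c in cols if c in ("PixCorr", "SSIM")]
        high = [c for c in cols if c not in low]
        header = "Low-Level (higher better) | High-Level (lower better)"
        parts = [header, "-" * len(header)]
        parts.append("  ".join(f"{c}={self.aggregate[c]:.4f}" for c in low + high))
        return "\n".join(parts)


def evaluate_reconstructions(
    truth: ImageSet,
    recon: ImageSet,
    extractors: Sequence[FeatureExtractor],
    size: int = 256,
    ssim_mode: str = "global",
) -> MetricReport:
    """Run the five-metric protocol over aligned truth/reconstruction pairs.

    Both image sets are resized to a common square size; per pair, PixCorr
    and SSIM are computed, plus one feature distance per extractor.  The
    aggregate is the arithmetic mean of each per-image column.
    """
    if list(truth.image_ids) != list(recon.image_ids):
        extra_t = set(truth.image_ids) - set(recon.image_ids)
        extra_r = set(recon.image_ids) - set(truth.image_ids)
        if extra_t or extra_r:
            raise ValidationError(
                f"unpaired image ids: truth-only={sorted(extra_t)[:5]}, "
                f"recon-only={sorted(extra_r)[:5]}"
            )
        raise ValidationError("image ids are paired but ordered differently")
    if len(extractors) == 0:
        raise ValidationError("need at least one feature extractor")

    t = resize_to_common(truth, size)
    r = resize_to_common(recon, size)
    rows = {}
    for iid, ti, ri in zip(t.image_ids, t.images, r.images):
        row = {"PixCorr": pixcorr(ti, ri)}
        if ssim_mode == "global":
            row["SSIM"] = ssim_global(ti, ri)
        else:
            row["SSIM"] = ssim_windowed(ti, ri)
        for ex in extractors:
            row[f"{ex.name}Dist"] = feature_distance(ex.extract(ti), ex.extract(ri))
        rows[iid] = row
    per_image = pd.DataFrame.from_dict(rows, orient="index")
    per_image.index.name = "image_id"
    aggregate = {c: float(per_image[c].mean()) for c in per_image.columns}
    metadata = {
        "size": size,
        "ssim_mode": ssim_mode,
        "extractors": [ex.name for ex in extractors],
        "n_images": len(t),
    }
    return MetricReport(per_image=per_image, aggregate=aggregate, metadata=metadata)
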