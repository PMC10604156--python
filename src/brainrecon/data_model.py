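"""Core domain containers for paired fMRI/stimulus datasets.

The decoding problem is posed over a handful of aligned tabular objects:
voxel response matrices (one row per stimulus presentation), stimulus image
sets, optional captions, and feature matrices (flattened generative-model
latents or embedding vectors) that decoders are trained to predict from
voxels.  Everything is numpy-backed, samples-first, and validated on
construction so that downstream stages can assume finite, aligned data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelMatrix",
    "ROIMask",
    "ImageSet",
    "CaptionSet",
    "FeatureMatrix",
    "PairedDataset",
    "ValidationError",
    "load_voxel_matrix",
    "save_voxel_matrix",
    "apply_roi_mask",
    "average_repeats",
    "flatten_latents",
    "reshape_latents",
    "load_images",
    "save_images",
    "load_captions",
    "save_captions",
]


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _as_str_list(items: Sequence) -> list[str]:
    return [str(i) for i in items]


@dataclass
class VoxelMatrix:
    """Per-subject fMRI responses, samples x voxels.

    ``repeat_of`` maps each row to the stimulus it is a presentation of;
    it is present on test splits where each stimulus is shown repeatedly.
    """

    values: np.ndarray
    sample_ids: list[str]
    voxel_ids: list[str]
    repeat_of: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValidationError("need at least one sample and one voxel")
        self.sample_ids = _as_str_list(self.sample_ids)
        self.voxel_ids = _as_str_list(self.voxel_ids)
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.voxel_ids) != p:
            raise ValidationError(f"{len(self.voxel_ids)} voxel_ids for {p} columns")
        if not np.all(np.isfinite(self.values)):
            bad = np.where(~np.isfinite(self.values).all(axis=1))[0]
            rows = [self.sample_ids[i] for i in bad[:10]]
            raise ValidationError(f"non-finite voxel values in rows {rows}")
        if self.repeat_of is not None:
            self.repeat_of = _as_str_list(self.repeat_of)
            if len(self.repeat_of) != n:
                raise ValidationError("repeat_of length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ROIMask:
    """A named set of voxels (e.g., a visual-cortex region)."""

    voxel_ids: list[str]
    region_name: str = "roi"

    def __post_init__(self) -> None:
        self.voxel_ids = _as_str_list(self.voxel_ids)
        if len(set(self.voxel_ids)) != len(self.voxel_ids):
            raise ValidationError("ROI voxel ids must be unique")


@dataclass
class ImageSet:
    """Stimulus (or reconstruction) images: H x W x 3 floats in [0, 1]."""

    images: list[np.ndarray]
    image_ids: list[str]
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.images = [np.asarray(im, dtype=np.float64) for im in self.images]
        self.image_ids = _as_str_list(self.image_ids)
        if len(self.images) != len(self.image_ids):
            raise ValidationError("images and image_ids must align")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValidationError("image_ids must be unique")
        for iid, im in zip(self.image_ids, self.images):
            if im.ndim != 3 or im.shape[2] != 3:
                raise ValidationError(f"image {iid}: expected HxWx3, got {im.shape}")
            if im.size and (im.min() < 0.0 or im.max() > 1.0):
                raise ValidationError(f"image {iid}: intensities outside [0, 1]")
        if self.class_labels is not None:
            self.class_labels = _as_str_list(self.class_labels)
            if len(self.class_labels) != len(self.images):
                raise ValidationError("class_labels must align with images")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices: Sequence[int]) -> "ImageSet":
        labels = None
        if self.class_labels is not None:
            labels = [self.class_labels[i] for i in indices]
        return ImageSet(
            [self.images[i] for i in indices],
            [self.image_ids[i] for i in indices],
            labels,
        )


@dataclass
class CaptionSet:
    """One free-text caption per image id."""

    captions: list[str]
    image_ids: list[str]

    def __post_init__(self) -> None:
        self.captions = [str(c) for c in self.captions]
        self.image_ids = _as_str_list(self.image_ids)
        if len(self.captions) != len(self.image_ids):
            raise ValidationError("one caption per image id required")


@dataclass
class FeatureMatrix:
    """Target or predicted feature vectors, samples x dims.

    ``layout`` optionally records the per-layer array shapes that each row
    was flattened from, so hierarchical latents can be restored exactly.
    """

    values: np.ndarray
    feature_kind: str = "latent"  # latent | visual | text
    layout: list[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        if self.feature_kind not in ("latent", "visual", "text"):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.layout is not None:
            self.layout = [tuple(int(d) for d in s) for s in self.layout]
            total = sum(int(np.prod(s)) for s in self.layout)
            if total != self.n_dims:
                raise ValidationError(
                    f"layout multiplies out to {total}, but n_dims={self.n_dims}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class PairedDataset:
    """Aligned {fMRI, image} pairs for one split.

    For test splits with repeated presentations the alignment is 1:1 after
    repeat-averaging: ``fmri.repeat_of`` values must cover exactly the image
    ids.
    """

    fmri: VoxelMatrix
    images: ImageSet
    captions: CaptionSet | None = None
    split: str = "train"

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValidationError(f"split must be train|test, got {self.split!r}")
        stim_ids = (
            self.fmri.repeat_of if self.fmri.repeat_of is not None else self.fmri.sample_ids
        )
        if set(stim_ids) != set(self.images.image_ids):
            raise ValidationError("fMRI stimulus ids do not match image ids")
        if self.fmri.repeat_of is None and len(stim_ids) != len(self.images):
            raise ValidationError("fMRI rows must align 1:1 with images")


# ---------------------------------------------------------------------------
# Voxel matrix I/O
# ---------------------------------------------------------------------------

_NPZ_KEYS = ("values", "sample_ids", "voxel_ids")


def load_voxel_matrix(path: str | Path, format: str | None = None) -> VoxelMatrix:
    """Load a voxel response matrix from npz, csv, hdf5 or a NIfTI series.

    CSV expects a header row of voxel ids; npz/hdf5 expect arrays/datasets
    named ``values``, ``sample_ids``, ``voxel_ids`` and optionally
    ``repeat_of``.  NIfTI is load-only convenience: a 4-D volume is
    flattened to samples x voxels (voxel ids encode the flat index).
    All orientations normalize to samples x voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".npz": "npz",
            ".csv": "csv",
            ".h5": "hdf5",
            ".hdf5": "hdf5",
            ".nii": "nifti-series",
            ".gz": "nifti-series",
        }.get(suffix, "npz")

    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            missing = [k for k in _NPZ_KEYS if k not in z]
            if missing:
                raise ValidationError(f"{path}: npz missing arrays {missing}")
            repeat = list(z["repeat_of"]) if "repeat_of" in z else None
            vm = VoxelMatrix(z["values"], list(z["sample_ids"]), list(z["voxel_ids"]), repeat)
    elif format == "csv":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        vm = VoxelMatrix(df.to_numpy(dtype=np.float64), list(df.index), list(df.columns))
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            missing = [k for k in _NPZ_KEYS if k not in f]
            if missing:
                raise ValidationError(f"{path}: hdf5 missing datasets {missing}")
            repeat = None
            if "repeat_of" in f:
                repeat = [s.decode() if isinstance(s, bytes) else str(s) for s in f["repeat_of"][()]]
            sample_ids = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][()]
            ]
            voxel_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["voxel_ids"][()]]
            vm = VoxelMatrix(f["values"][()], sample_ids, voxel_ids, repeat)
    elif format == "nifti-series":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise ValidationError(f"{path}: expected 3-D or 4-D NIfTI, got {data.ndim}-D")
        n = data.shape[3]
        flat = data.reshape(-1, n).T  # samples x voxels
        vm = VoxelMatrix(
            flat,
            [f"vol{i:04d}" for i in range(n)],
            [f"vox{j:06d}" for j in range(flat.shape[1])],
        )
    else:
        raise ValidationError(f"unknown voxel matrix format {format!r}")

    logger.info("loaded voxel matrix %s: %d samples x %d voxels", path, vm.n_samples, vm.n_voxels)
    return vm


def save_voxel_matrix(vm: VoxelMatrix, path: str | Path) -> Path:
    """Write a voxel matrix to npz (the canonical interchange format)."""
    path = Path(path)
    arrays = {
        "values": vm.values,
        "sample_ids": np.array(vm.sample_ids),
        "voxel_ids": np.array(vm.voxel_ids),
    }
    if vm.repeat_of is not None:
        arrays["repeat_of"] = np.array(vm.repeat_of)
    np.savez(path, **arrays)
    return path


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def apply_roi_mask(x: VoxelMatrix, mask: ROIMask) -> VoxelMatrix:
    """Restrict a voxel matrix to the voxels of an ROI.

    Column order of the retained voxels follows the original matrix, not
    the mask.
    """
    wanted = set(mask.voxel_ids)
    missing = sorted(wanted - set(x.voxel_ids))
    if missing:
        raise ValidationError(
            f"ROI {mask.region_name!r} names voxels absent from the matrix: {missing[:10]}"
        )
    keep = [j for j, v in enumerate(x.voxel_ids) if v in wanted]
    return VoxelMatrix(
        x.values[:, keep],
        list(x.sample_ids),
        [x.voxel_ids[j] for j in keep],
        list(x.repeat_of) if x.repeat_of is not None else None,
    )


def average_repeats(x: VoxelMatrix) -> VoxelMatrix:
    """Average repeated presentations of each stimulus into one row.

    Rows sharing a ``repeat_of`` stimulus id are replaced by their
    arithmetic mean; output rows are ordered by first appearance of each
    stimulus and carry no repeat structure.
    """
    if x.repeat_of is None:
        raise ValidationError("average_repeats requires repeat_of")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, stim in enumerate(x.repeat_of):
        if stim not in groups:
            groups[stim] = []
            order.append(stim)
        groups[stim].append(i)
    values = np.stack([x.values[groups[s]].mean(axis=0) for s in order])
    return VoxelMatrix(values, order, list(x.voxel_ids), None)


def flatten_latents(
    per_layer: Sequence[Sequence[np.ndarray]], feature_kind: str = "latent"
) -> FeatureMatrix:
    """Concatenate each sample's hierarchical latents into one flat row.

    ``per_layer[i]`` is the list of per-layer arrays for sample ``i``; all
    samples must share the same per-layer shapes.  The layout is recorded
    so :func:`reshape_latents` can invert the flattening bit-exactly.
    """
    if len(per_layer) == 0:
        raise ValidationError("no samples to flatten")
    ref_shapes = [tuple(np.asarray(a).shape) for a in per_layer[0]]
    rows = []
    for i, layers in enumerate(per_layer):
        shapes = [tuple(np.asarray(a).shape) for a in layers]
        if shapes != ref_shapes:
            raise ValidationError(
                f"sample {i} has per-layer shapes {shapes}, expected {ref_shapes}"
            )
        rows.append(np.concatenate([np.asarray(a, dtype=np.float64).ravel() for a in layers]))
    return FeatureMatrix(np.stack(rows), feature_kind=feature_kind, layout=ref_shapes)


def reshape_latents(f: FeatureMatrix) -> list[list[np.ndarray]]:
    """Invert :func:`flatten_latents` using the recorded layout."""
    if f.layout is None:
        raise ValidationError("feature matrix carries no layout to reshape by")
    sizes = [int(np.prod(s)) for s in f.layout]
    if sum(sizes) != f.n_dims:
        raise ValidationError("layout inconsistent with n_dims")
    out = []
    for row in f.values:
        offs = 0
        layers = []
        for shape, size in zip(f.layout, sizes):
            layers.append(row[offs : offs + size].reshape(shape))
            offs += size
        out.append(layers)
    return out


# ---------------------------------------------------------------------------
# Image and caption I/O
# ---------------------------------------------------------------------------


def save_images(images: ImageSet, directory: str | Path) -> list[Path]:
    """Write each image as an 8-bit PNG named by its image id."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for iid, im in zip(images.image_ids, images.images):
        arr = np.round(im * 255.0).astype(np.uint8)
        p = directory / f"{iid}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths


def load_images(directory: str | Path, image_ids: Sequence[str] | None = None) -> ImageSet:
    """Load PNG/JPEG images from a directory as floats in [0, 1]."""
    from PIL import Image

    directory = Path(directory)
    if image_ids is None:
        paths = sorted(
            p for p in directory.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        image_ids = [p.stem for p in paths]
    else:
        paths = []
        for iid in image_ids:
            for ext in (".png", ".jpg", ".jpeg"):
                p = directory / f"{iid}{ext}"
                if p.exists():
                    paths.append(p)
                    break
            else:
                raise FileNotFoundError(f"no image file for id {iid!r} in {directory}")
    images = []
    for p in paths:
        with Image.open(p) as im:
            images.append(np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0)
    return ImageSet(images, list(image_ids))


def save_captions(captions: CaptionSet, path: str | Path) -> Path:
    """Write captions as a UTF-8 TSV: image_id<TAB>caption."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as f:
        for iid, cap in zip(captions.image_ids, captions.captions):
            f.write(f"{iid}\t{cap}\n")
    return path


def load_captions(path: str | Path) -> CaptionSet:
    ids, caps = [], []
    with open(path, encoding="utf-8") as f:
        for line in f:
            line = line.rstrip("\n")
            if not line:
                continue
            iid, _, cap = line.partition("\t")
            ids.append(iid)
            caps.append(cap)
    return CaptionSet(caps, ids)
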