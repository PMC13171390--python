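"""Fundus image I/O, preprocessing, and the patch representation.

Images are held as float arrays in [0, 1] (H×W grayscale or H×W×3 RGB);
vessel / field-of-view (FOV) / boundary masks are uint8 {0, 1} arrays of
the same height and width.  Training uses randomly centred square crops
restricted to the FOV; whole-image inference tiles the image on a regular
overlapping grid and averages overlapping predictions back together.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import color, exposure

VALID_SOURCES = ("drive", "stare", "chasedb1", "synthetic", "other")


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


@dataclass
class FundusSample:
    """One fundus photograph with its reference masks.

    ``boundary_mask`` is the morphological gradient of ``vessel_mask`` and
    serves as the supervision target of the boundary branch.
    """

    image: np.ndarray
    vessel_mask: np.ndarray
    fov_mask: np.ndarray
    boundary_mask: np.ndarray
    sample_id: str = ""
    source: str = "other"

    def __post_init__(self):
        hw = self.image.shape[:2]
        for name in ("vessel_mask", "fov_mask", "boundary_mask"):
            m = getattr(self, name)
            if m.shape != hw:
                raise ValidationError(
                    f"{name} shape {m.shape} does not match image {hw}")
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"{name} must be binary, got values {vals}")
        if self.source not in VALID_SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")

    @property
    def shape(self):
        return self.image.shape[:2]


@dataclass
class PatchSet:
    """Square patches cut from one image plus where they came from.

    Coordinates are 0-based (row, col) top-left corners on the padded
    canvas, enumerated row-major for grid patches.
    """

    patches: np.ndarray          # (n, S, S)
    coords: np.ndarray           # (n, 2)
    patch_size: int
    source_shape: tuple
    stride: object               # int or "random"
    padded_shape: tuple = None

    def __post_init__(self):
        if len(self.patches) != len(self.coords):
            raise ValidationError("patches and coords length mismatch")
        hp, wp = self.padded_shape or self.source_shape
        s = self.patch_size
        if len(self.coords) and (
            (self.coords < 0).any()
            or (self.coords[:, 0] > hp - s).any()
            or (self.coords[:, 1] > wp - s).any()
        ):
            raise ValidationError("patch coordinates exit the padded canvas")

    def __len__(self):
        return len(self.patches)


@dataclass
class TrainPatchSet:
    """Paired image / vessel / boundary patches sharing one coordinate set."""

    image: PatchSet
    vessel: PatchSet
    boundary: PatchSet


@dataclass
class PreprocessConfig:
    """The grayscale → histogram equalisation → gamma correction chain.

    CLAHE is the default equaliser (the de-facto standard for fundus
    photographs); ``clahe_clip`` uses the familiar OpenCV-style scale and
    is mapped internally to skimage's [0, 1] clip fraction.  ``gamma`` is
    the illumination-correction exponent (output = input**gamma).
    """

    use_grayscale: bool = True
    hist_eq: str = "clahe"       # {"global", "clahe", "none"}
    gamma: float = 1.2
    clahe_clip: float = 2.0
    clahe_tile: int = 8

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if self.hist_eq not in ("global", "clahe", "none"):
            raise ValidationError(f"unknown hist_eq {self.hist_eq!r}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_image(path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:       # drop alpha
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float32)
    return np.clip(arr, 0.0, 1.0)


def _read_mask(path) -> np.ndarray:
    arr = _read_image(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return (arr >= 0.5).astype(np.uint8)


def load_sample(image_path, mask_path, fov_path=None, sample_id=None,
                source="other") -> FundusSample:
    """Load an image / vessel-mask / optional FOV-mask triple from disk.

    Intensities are scaled to [0, 1]; masks are binarised at the midpoint
    of their value range; an absent FOV defaults to all-ones.
    """
    image = _read_image(image_path)
    vessel = _read_mask(mask_path)
    if image.shape[:2] != vessel.shape:
        raise ValidationError(
            f"image {image.shape[:2]} and mask {vessel.shape} shapes differ "
            f"({image_path} vs {mask_path})")
    if fov_path is not None:
        fov = _read_mask(fov_path)
        if fov.shape != vessel.shape:
            raise ValidationError(
                f"fov mask {fov.shape} does not match image {image.shape[:2]}")
    else:
        fov = np.ones_like(vessel)
    return FundusSample(
        image=image,
        vessel_mask=vessel,
        fov_mask=fov,
        boundary_mask=derive_boundary(vessel),
        sample_id=sample_id or Path(image_path).stem,
        source=source,
    )


def read_manifest(manifest_path, source="other") -> list:
    """Read a plain-text manifest: one `image mask [fov]` triple per line.

    Relative paths are resolved against the manifest's directory.
    """
    base = Path(manifest_path).parent
    samples = []
    with open(manifest_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ValidationError(f"manifest line needs >= 2 paths: {line!r}")
            paths = [p if os.path.isabs(p) else str(base / p) for p in parts[:3]]
            fov = paths[2] if len(paths) > 2 else None
            samples.append(load_sample(paths[0], paths[1], fov, source=source))
    if not samples:
        raise ValidationError(f"manifest {manifest_path} resolves to no samples")
    return samples


def read_dataset_dir(root, layout="drive") -> list:
    """Read the conventional DRIVE / STARE / CHASE_DB1 directory layouts.

    DRIVE: `images/`, `1st_manual/`, `mask/` subdirectories paired by sort
    order.  STARE and CHASE_DB1: `images/` and `labels/` paired the same
    way (no FOV masks ship with those datasets).
    """
    root = Path(root)
    if layout == "drive":
        img_dir, lab_dir, fov_dir = root / "images", root / "1st_manual", root / "mask"
    elif layout in ("stare", "chasedb1"):
        img_dir, lab_dir, fov_dir = root / "images", root / "labels", None
    else:
        raise ValidationError(f"unknown dataset layout {layout!r}")
    images = sorted(p for p in img_dir.iterdir() if p.is_file())
    labels = sorted(p for p in lab_dir.iterdir() if p.is_file())
    fovs = (sorted(p for p in fov_dir.iterdir() if p.is_file())
            if fov_dir is not None and fov_dir.is_dir() else [None] * len(images))
    if not (len(images) == len(labels) == len(fovs)):
        raise ValidationError(
            f"unpaired dataset files under {root}: {len(images)} images, "
            f"{len(labels)} labels, {len(fovs)} fov masks")
    return [load_sample(i, l, f, source=layout)
            for i, l, f in zip(images, labels, fovs)]


# ---------------------------------------------------------------------------
# boundary supervision target
# ---------------------------------------------------------------------------

def derive_boundary(vessel_mask: np.ndarray, thickness: int = 1) -> np.ndarray:
    """Morphological gradient (dilation − erosion) of a binary mask.

    Uses a (2·thickness+1)² square structuring element.  Outside the grid
    the mask is treated as background, so a mask of all ones reports its
    outer frame as boundary.
    """
    vessel_mask = np.asarray(vessel_mask)
    vals = np.unique(vessel_mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"vessel_mask must be binary, got {vals}")
    se = np.ones((2 * thickness + 1,) * 2, dtype=bool)
    dil = ndimage.binary_dilation(vessel_mask.astype(bool), se)
    ero = ndimage.binary_erosion(vessel_mask.astype(bool), se, border_value=0)
    return (dil & ~ero).astype(np.uint8)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(sample: FundusSample, cfg: PreprocessConfig = None) -> FundusSample:
    """Apply grayscale → histogram equalisation → gamma, masks untouched."""
    cfg = cfg or PreprocessConfig()
    img = sample.image
    if img.min() < 0 or img.max() > 1:
        raise ValidationError("image intensities must lie in [0, 1]")
    if img.ndim == 3 and cfg.use_grayscale:
        img = color.rgb2gray(img)
    elif img.ndim == 3:
        img = img.mean(axis=2)
    img = np.clip(img, 0.0, 1.0)
    if cfg.hist_eq == "global":
        img = exposure.equalize_hist(img)
    elif cfg.hist_eq == "clahe":
        img = exposure.equalize_adapthist(
            img,
            kernel_size=max(8, min(img.shape) // cfg.clahe_tile),
            clip_limit=cfg.clahe_clip / 100.0,
        )
    img = np.power(img, cfg.gamma)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return replace(sample, image=img)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def _pad_reflect(arr: np.ndarray, pad_h: int, pad_w: int) -> np.ndarray:
    """Reflect-pad bottom/right, chunked so pads larger than the image work."""
    while pad_h > 0 or pad_w > 0:
        ph = min(pad_h, arr.shape[0] - 1)
        pw = min(pad_w, arr.shape[1] - 1)
        if ph == 0 and pad_h > 0 or pw == 0 and pad_w > 0:
            raise ValidationError("cannot reflect-pad a singleton axis")
        arr = np.pad(arr, ((0, ph), (0, pw)) + ((0, 0),) * (arr.ndim - 2),
                     mode="reflect")
        pad_h -= ph
        pad_w -= pw
    return arr


def _padded_size(dim: int, size: int, stride: int) -> int:
    if dim <= size:
        return size
    return size + int(np.ceil((dim - size) / stride)) * stride


def sample_train_patches(sample: FundusSample, n: int, size: int,
                         rng_seed: int) -> TrainPatchSet:
    """Draw `n` random square crops centred on FOV pixels.

    Identical arguments give bit-identical output.  Windows whose centre
    sits near the border are clamped into the reflect-padded canvas, so
    every crop is fully inside the padded image.
    """
    if n <= 0 or size <= 0:
        raise ValidationError("n and size must be positive")
    h, w = sample.shape
    img = sample.image
    if img.ndim == 3:
        img = color.rgb2gray(img).astype(np.float32)
    # reflect-pad (bottom/right) only when the window is larger than the
    # image; otherwise windows are clamped inside the frame, so an image
    # exactly the patch size admits a single window
    pad_h, pad_w = max(0, size - h), max(0, size - w)
    imgp = _pad_reflect(img, pad_h, pad_w)
    vesp = _pad_reflect(sample.vessel_mask, pad_h, pad_w)
    bndp = _pad_reflect(sample.boundary_mask, pad_h, pad_w)
    hp, wp = imgp.shape[:2]

    rng = np.random.default_rng(rng_seed)
    fov_idx = np.flatnonzero(sample.fov_mask)
    if fov_idx.size == 0:
        raise ValidationError("FOV mask is empty; no centres to sample")
    picks = rng.choice(fov_idx, size=n, replace=True)
    rows = np.clip(picks // w - size // 2, 0, hp - size)
    cols = np.clip(picks % w - size // 2, 0, wp - size)
    coords = np.stack([rows, cols], axis=1)

    def cut(canvas, dtype):
        out = np.empty((n, size, size), dtype=dtype)
        for k, (r, c) in enumerate(coords):
            out[k] = canvas[r:r + size, c:c + size]
        return out

    common = dict(coords=coords, patch_size=size, source_shape=(h, w),
                  stride="random", padded_shape=(hp, wp))
    return TrainPatchSet(
        image=PatchSet(patches=cut(imgp, np.float32), **common),
        vessel=PatchSet(patches=cut(vesp, np.uint8), **common),
        boundary=PatchSet(patches=cut(bndp, np.uint8), **common),
    )


def grid_patches(image: np.ndarray, size: int = 96, stride: int = 32) -> PatchSet:
    """Tile an image with overlapping windows on a regular grid.

    The image is reflect-padded (bottom/right) to the smallest canvas on
    which windows of `size` spaced by `stride` fit exactly; patches are
    enumerated row-major.
    """
    if stride <= 0:
        raise ValidationError("stride must be positive")
    if size < stride:
        raise ValidationError("patch size must be >= stride")
    h, w = image.shape[:2]
    hp, wp = _padded_size(h, size, stride), _padded_size(w, size, stride)
    padded = _pad_reflect(image, hp - h, wp - w)
    rows = range(0, hp - size + 1, stride)
    cols = range(0, wp - size + 1, stride)
    coords = np.array([(r, c) for r in rows for c in cols])
    patches = np.stack([padded[r:r + size, c:c + size] for r, c in coords])
    return PatchSet(patches=patches, coords=coords, patch_size=size,
                    source_shape=(h, w), stride=stride, padded_shape=(hp, wp))


def overlay(image: np.ndarray, mask: np.ndarray, color=(1.0, 0.1, 0.1),
            alpha: float = 0.5) -> np.ndarray:
    """Blend a binary mask over an image for qualitative inspection."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    mask = np.asarray(mask)
    if mask.shape != img.shape[:2]:
        raise ValidationError(
            f"mask {mask.shape} does not match image {img.shape[:2]}")
    out = img.copy()
    sel = mask.astype(bool)
    out[sel] = (1 - alpha) * out[sel] + alpha * np.asarray(color, np.float32)
    return np.clip(out, 0.0, 1.0)


def stitch(patch_preds: PatchSet, full_shape=None) -> np.ndarray:
    """Average overlapping patch predictions back onto the image canvas."""
    full_shape = full_shape or patch_preds.source_shape
    hp, wp = patch_preds.padded_shape or full_shape
    s = patch_preds.patch_size
    acc = np.zeros((hp, wp), dtype=np.float64)
    cov = np.zeros((hp, wp), dtype=np.int32)
    for patch, (r, c) in zip(patch_preds.patches, patch_preds.coords):
        acc[r:r + s, c:c + s] += patch
        cov[r:r + s, c:c + s] += 1
    if (cov == 0).any():
        raise RuntimeError("stitch: some pixels received no patch coverage")
    out = (acc / cov)[: full_shape[0], : full_shape[1]]
    return out.astype(np.float32)
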