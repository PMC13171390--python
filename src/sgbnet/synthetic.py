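"""Procedural fundus-like image generator with paired ground truth.

The generator emulates the properties that make fundus vessel
segmentation hard: thin branching vessels of decaying caliber that are
darker than a low-contrast background, smooth non-uniform illumination,
sensor noise, a circular camera field of view, and bright (exudate-like)
and dark (hemorrhage-like) lesion discs that act as false-positive
distractors.  Vessel trees are random recursive binary trees grown
outward from near the FOV centre; every sample is a pure function of its
parameter set (one seeded generator, no global random state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import FundusSample, ValidationError, derive_boundary


@dataclass
class SynthParams:
    seed: int = 0
    size: tuple = (256, 256)
    n_trees: int = 5              # primary vessels leaving the disc region
    branch_depth: int = 5
    root_width: float = 3.0       # px
    width_decay: float = 0.8
    branch_angle_deg: float = 40.0
    contrast: float = 0.35        # vessel-background intensity gap
    noise_sd: float = 0.03
    illum_gradient: float = 0.15  # peak-to-peak smooth shading amplitude
    n_lesions: int = 4
    lesion_radius: float = 7.0    # px
    fov_margin: float = 0.05      # inset of the FOV ellipse, fraction

    def __post_init__(self):
        if min(self.n_trees, self.branch_depth, self.n_lesions) < 0:
            raise ValidationError("counts must be >= 0")
        if not 0.0 < self.width_decay < 1.0:
            raise ValidationError("width_decay must lie in (0, 1)")
        if tuple(self.size) < (64, 64):
            raise ValidationError("size must be at least 64x64")
        if self.n_trees > 0 and self.root_width < 0.5:
            raise ValidationError("root_width below 0.5 px cannot be rasterised")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _fov_ellipse(shape, margin) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = (h / 2) * (1 - margin), (w / 2) * (1 - margin)
    return ((((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1).astype(np.uint8)


def _stamp_segment(canvas, p0, p1, width):
    """Anti-aliased capsule (thick segment) rendered by distance to the
    segment; intensity ramps linearly over the final half pixel."""
    h, w = canvas.shape
    r = width / 2.0
    lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 2).astype(int)
    y0, x0 = np.clip(lo, 0, (h, w))
    y1, x1 = np.clip(hi, 0, (h, w))
    if y1 <= y0 or x1 <= x0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.stack([yy - p0[0], xx - p0[1]], axis=-1).astype(np.float64)
    seg = np.asarray(p1) - np.asarray(p0)
    seg_len2 = float(seg @ seg)
    if seg_len2 < 1e-12:
        dist = np.hypot(d[..., 0], d[..., 1])
    else:
        t = np.clip((d @ seg) / seg_len2, 0.0, 1.0)
        proj = t[..., None] * seg
        dist = np.hypot(d[..., 0] - proj[..., 0], d[..., 1] - proj[..., 1])
    val = np.clip(r + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], val, out=canvas[y0:y1, x0:x1])


def _grow_tree(rng, canvas, fov, start, direction, width, depth, decay,
               branch_angle, seg_len):
    """Recursive binary branching; children get jittered headings and
    decayed widths.  Growth stops on leaving the FOV or below 0.5 px."""
    if depth < 0 or width < 0.5:
        return
    h, w = canvas.shape
    length = seg_len * rng.uniform(0.75, 1.25)
    end = start + length * direction
    _stamp_segment(canvas, start, end, width)
    ei, ej = int(round(end[0])), int(round(end[1]))
    if not (0 <= ei < h and 0 <= ej < w) or not fov[ei, ej]:
        return
    spread = np.deg2rad(branch_angle)
    for sign in (-1.0, 1.0):
        ang = np.arctan2(direction[0], direction[1])
        ang = ang + sign * spread / 2 + rng.normal(0, spread / 6)
        child_dir = np.array([np.sin(ang), np.cos(ang)])
        _grow_tree(rng, canvas, fov, end, child_dir, width * decay,
                   depth - 1, decay, branch_angle, seg_len)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(params: SynthParams, return_prenoise: bool = False):
    """Render one synthetic fundus image with vessel/boundary/FOV masks.

    With ``return_prenoise`` the pre-noise, pre-lesion green-channel
    canvas is returned alongside the sample (used to verify the stated
    vessel/background contrast without the confound of sensor noise).
    """
    h, w = params.size
    rng = np.random.default_rng(params.seed)
    fov = _fov_ellipse((h, w), params.fov_margin)

    # -- vessel trees -------------------------------------------------
    canvas = np.zeros((h, w), dtype=np.float64)
    centre = np.array([(h - 1) / 2, (w - 1) / 2])
    seg_len = 0.09 * min(h, w)
    for _ in range(params.n_trees):
        offset = rng.uniform(-0.12, 0.12, size=2) * min(h, w)
        heading = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(heading), np.cos(heading)])
        _grow_tree(rng, canvas, fov, centre + offset, direction,
                   params.root_width, params.branch_depth,
                   params.width_decay, params.branch_angle_deg, seg_len)
    canvas *= fov
    soft = ndimage.gaussian_filter(canvas, 0.5)
    vessel = (soft > 0.5).astype(np.uint8)

    # -- pre-noise intensity canvas -----------------------------------
    base = 0.62
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.sin(theta) * (yy / h - 0.5) + np.cos(theta) * (xx / w - 0.5))
    illum = params.illum_gradient * ramp
    vessel_shade = params.contrast * ndimage.gaussian_filter(
        canvas.clip(0, 1), 0.8)
    green = base + illum - vessel_shade
    prenoise = green.copy()

    # -- lesion distractors -------------------------------------------
    lesions = np.zeros((h, w), dtype=np.float64)
    placed = 0
    attempts = 0
    while placed < params.n_lesions and attempts < params.n_lesions * 20:
        attempts += 1
        ci = rng.integers(0, h)
        cj = rng.integers(0, w)
        if not fov[ci, cj] or vessel[ci, cj]:
            continue
        radius = params.lesion_radius * rng.uniform(0.6, 1.4)
        sign = 1.0 if placed % 2 == 0 else -1.0   # alternate bright/dark
        dist2 = (yy - ci) ** 2 + (xx - cj) ** 2
        lesions += sign * 0.18 * np.exp(-dist2 / (2 * (radius / 1.5) ** 2))
        placed += 1
    green = green + lesions

    noise = rng.normal(0.0, params.noise_sd, size=(h, w))
    green = np.clip(green + noise, 0.0, 1.0)

    # fundus-like RGB: dominant red channel, informative green, weak blue
    image = np.stack([
        np.clip(green * 0.55 + 0.42, 0, 1),
        green,
        np.clip(green * 0.45, 0, 1),
    ], axis=-1).astype(np.float32)
    image *= fov[..., None]

    sample = FundusSample(
        image=image,
        vessel_mask=vessel,
        fov_mask=fov,
        boundary_mask=derive_boundary(vessel),
        sample_id=f"synth-{params.seed}",
        source="synthetic",
    )
    if return_prenoise:
        return sample, prenoise
    return sample


def generate_split(params: SynthParams, n_train: int, n_test: int,
                   seed: int = None):
    """Deterministically derive disjoint train/test sample lists.

    Per-sample seeds are spawned from the master seed via SeedSequence,
    so train and test never share a sample.
    """
    if n_train < 1 or n_test < 1:
        raise ValidationError("split counts must be >= 1")
    master = params.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(
        n_train + n_test) & 0x7FFFFFFF
    samples = [generate(replace(params, seed=int(s))) for s in child_seeds]
    return samples[:n_train], samples[n_train:]


def write_samples(samples, out_dir) -> Path:
    """Write PNG images/masks plus a manifest consumable by imaging.

    Returns the manifest path.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for s in samples:
        img8 = (np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(out_dir / f"{s.sample_id}.png", img8)
        iio.imwrite(out_dir / f"{s.sample_id}_vessel.png",
                    (s.vessel_mask * 255).astype(np.uint8))
        iio.imwrite(out_dir / f"{s.sample_id}_fov.png",
                    (s.fov_mask * 255).astype(np.uint8))
        lines.append(f"{s.sample_id}.png {s.sample_id}_vessel.png "
                     f"{s.sample_id}_fov.png")
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
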