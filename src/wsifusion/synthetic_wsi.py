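"""Seeded two-class synthetic pyramidal slides.

The generator emulates the gross appearance of an H&E-stained slide scan at
desk scale: a near-white scanner background, a contiguous eosinophilic
(pink) tissue region, dark nuclear texture inside the tissue, and a few
saturated-red blood artifacts.  The two classes differ only in the geometry
of the dark texture:

* ``MEN`` (meningioma-like) — isotropic dark blobs scattered over the pink
  field, echoing whorled sheets of rounded nuclei;
* ``SFT`` (solitary-fibrous-tumor-like) — elongated dark streaks at a
  per-slide orientation, echoing the spindled, fascicular growth pattern.

Classes are therefore separable by low-level texture statistics (gradient-
orientation anisotropy in particular) while remaining deliberately far from
real nuclear morphology.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .pyramid import (
    DEFAULT_DOWNSAMPLES,
    DEFAULT_MAGNIFICATIONS,
    PyramidImage,
    save_pyramid,
)

CLASSES = ("MEN", "SFT")

DEFAULT_BASE_SIZE = 2048
DEFAULT_TISSUE_COVER = 0.6
DEFAULT_ARTIFACT_COUNT = 3

# Palette and texture parameters, in level-0 pixels.  A plausible cartoon
# of an H&E slide: pink stroma, dark basophilic marks covering ~30% of the
# tissue, mild sensor noise.  The two classes differ in mark geometry
# (isotropic blobs vs oriented streaks) and, more subtly, in mark
# chromatin intensity: the meningioma-like class gets denser, darker marks
# than the paler spindled marks of the SFT-like class, so the classes stay
# separable through intensity statistics at every pyramid level even
# though the streak orientation varies from slide to slide.
_BACKGROUND_MEAN = 250
_PINK = np.array([225, 170, 200], dtype=np.float64)
_DARK_BY_CLASS = {
    "MEN": np.array([70, 50, 110], dtype=np.float64),
    "SFT": np.array([125, 95, 150], dtype=np.float64),
}
_RED = np.array([200, 30, 35], dtype=np.float64)
# stain-intensity variability of the dark marks, in luma units.  The
# within-slide field makes some areas ambiguously pale or dark, so patch
# errors cluster spatially; the per-slide offset shifts a whole slide's
# marks toward or away from the class boundary, so the per-slide error
# rate itself varies between slides — the spread that the beta model of
# p(MEN) is meant to capture.
_STAIN_FIELD_LUMA_SD = 8.0
_SLIDE_STAIN_LUMA_SD = 9.0
_DARK_DENSITY = 0.30
_BLOB_SIGMA = 3.0
_STREAK_SIGMA = (1.5, 16.0)
_PIXEL_NOISE_SD = 8.0
_MASK_SIGMA_FRACTION = 1 / 8  # tissue-region smoothness relative to base size

MANIFEST_NAME = "manifest.csv"
TISSUE_MASK_NAME = "tissue_mask.png"


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide."""

    label: str
    seed: int
    base_size: int = DEFAULT_BASE_SIZE
    tissue_cover: float = DEFAULT_TISSUE_COVER
    artifact_count: int = DEFAULT_ARTIFACT_COUNT

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if self.base_size % 16 != 0 or self.base_size <= 0:
            raise ValueError(
                f"base_size must be a positive multiple of 16 (so every pyramid "
                f"level has integer dimensions), got {self.base_size}"
            )
        if not 0.0 <= self.tissue_cover <= 1.0:
            raise ValueError(f"tissue_cover must lie in [0, 1], got {self.tissue_cover}")
        if self.artifact_count < 0:
            raise ValueError(f"artifact_count must be >= 0, got {self.artifact_count}")


@dataclass
class GroundTruth:
    """Level-0 tissue mask and the slide's class label."""

    tissue_mask: np.ndarray
    label: str


def _smooth_field(rng: np.random.Generator, n: int, sigma) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=sigma)


def _tissue_field(rng: np.random.Generator, n: int) -> np.ndarray:
    """Slide-scale smooth field, rendered coarse and upsampled: the tissue
    outline only needs features at ~n/8 wavelengths."""
    c = max(n // 16, 16)
    coarse = _smooth_field(rng, c, c * _MASK_SIGMA_FRACTION)
    return ndimage.zoom(coarse, n / c, order=1)


def _threshold_by_cover(field: np.ndarray, cover: float) -> np.ndarray:
    """Binary mask covering (approximately) the top ``cover`` fraction."""
    if cover <= 0.0:
        return np.zeros(field.shape, dtype=bool)
    if cover >= 1.0:
        return np.ones(field.shape, dtype=bool)
    return field >= np.quantile(field, 1.0 - cover)


def _texture_mask(rng: np.random.Generator, n: int, label: str) -> np.ndarray:
    """Dark-mark mask: isotropic blobs for MEN, oriented streaks for SFT."""
    if label == "MEN":
        field = _smooth_field(rng, n, _BLOB_SIGMA)
    else:
        theta = rng.uniform(0.0, 180.0)  # per-slide fascicle orientation
        field = _smooth_field(rng, n, _STREAK_SIGMA)
        field = ndimage.rotate(field, theta, reshape=False, order=1, mode="reflect")
    return _threshold_by_cover(field, _DARK_DENSITY)


def _paint_artifacts(
    rng: np.random.Generator, image: np.ndarray, tissue: np.ndarray, count: int
) -> None:
    """Stamp saturated-red elliptical blood pools, clipped to the tissue
    region so the background stays near-white."""
    n = image.shape[0]
    for _ in range(count):
        cy, cx = rng.uniform(0.1 * n, 0.9 * n, size=2)
        ry, rx = rng.uniform(n / 40, n / 16, size=2)
        theta = rng.uniform(0, np.pi)
        # evaluate the rotated-ellipse equation only inside its bounding box
        hx = float(np.hypot(rx * np.cos(theta), ry * np.sin(theta)))
        hy = float(np.hypot(rx * np.sin(theta), ry * np.cos(theta)))
        x0, x1 = max(int(cx - hx), 0), min(int(cx + hx) + 2, n)
        y0, y1 = max(int(cy - hy), 0), min(int(cy + hy) + 2, n)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        sel = ((u / rx) ** 2 + (v / ry) ** 2 <= 1.0) & tissue[y0:y1, x0:x1]
        image[y0:y1, x0:x1][sel] = _RED


def generate_slide(spec: SlideSpec) -> tuple[PyramidImage, GroundTruth]:
    """Render one slide and its pyramid, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.base_size

    tissue = _threshold_by_cover(_tissue_field(rng, n), spec.tissue_cover)
    dark = _texture_mask(rng, n, spec.label)

    # flat near-white background: a blank scanner field has no contrast, so
    # pure-background patches binarise as tissue-free and get filtered
    image = np.empty((n, n, 3), dtype=np.float64)
    image[:] = _BACKGROUND_MEAN + rng.integers(-4, 5)
    image[tissue] = _PINK
    image[tissue & dark] = _DARK_BY_CLASS[spec.label]
    # stain-intensity modulation of the dark marks: a smooth within-slide
    # field plus one per-slide offset
    stain = _tissue_field(rng, n)
    stain = stain / max(stain.std(), 1e-12) * _STAIN_FIELD_LUMA_SD
    stain += rng.normal(0.0, _SLIDE_STAIN_LUMA_SD)
    marks = tissue & dark
    image[marks] += stain[marks, None]
    _paint_artifacts(rng, image, tissue, spec.artifact_count)
    # mild sensor noise on tissue only; the background must stay >= 240
    noise = rng.normal(0.0, _PIXEL_NOISE_SD, (n, n, 1))
    image[tissue] += noise[tissue]
    base = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)

    pyramid = build_pyramid(base, DEFAULT_DOWNSAMPLES, slide_id=f"{spec.label}_{spec.seed}")
    return pyramid, GroundTruth(tissue_mask=tissue, label=spec.label)


def build_pyramid(
    base_image: np.ndarray,
    downsamples=DEFAULT_DOWNSAMPLES,
    magnifications=None,
    slide_id: str = "",
) -> PyramidImage:
    """Build lower levels by block mean-pooling the level-0 raster.

    Each level-``i`` pixel is the mean of a ``d x d`` level-0 block
    (``d`` = downsample), rounded half away from zero — mean pooling keeps
    intensity statistics stable across levels, unlike plain subsampling.
    """
    if magnifications is None:
        # base level is nominally 40x; each downsample divides the scale
        magnifications = tuple(40.0 / d for d in downsamples)
    base = np.asarray(base_image)
    if base.ndim == 2:
        base = base[:, :, None]
    h, w = base.shape[:2]
    for d in downsamples:
        if h % d or w % d:
            raise ValueError(
                f"base dimensions {(w, h)} are not divisible by downsample {d}"
            )
    levels = []
    for d in downsamples:
        if d == 1:
            levels.append(base.copy())
            continue
        pooled = base.astype(np.float64).reshape(h // d, d, w // d, d, -1).mean(axis=(1, 3))
        levels.append(np.floor(pooled + 0.5).astype(np.uint8))
    levels = [lvl if lvl.shape[2] > 1 else lvl[:, :, 0] for lvl in levels]
    return PyramidImage(
        levels=levels,
        downsamples=tuple(downsamples),
        magnifications=tuple(magnifications),
        slide_id=slide_id,
    )


def slide_seed(cohort_seed: int, slide_index: int) -> int:
    """Per-slide seed derived from (cohort seed, slide index); stable and
    independent of generation order."""
    ss = np.random.SeedSequence((int(cohort_seed), int(slide_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    n_per_class: int,
    seed: int,
    out_dir: str | Path,
    base_size: int = DEFAULT_BASE_SIZE,
    tissue_cover: float = DEFAULT_TISSUE_COVER,
    artifact_count: int = DEFAULT_ARTIFACT_COUNT,
    save_ground_truth: bool = True,
) -> Path:
    """Write a balanced two-class cohort of fixture slides plus a CSV
    manifest (slide_id, label, path).  Returns the manifest path."""
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for label in CLASSES:
        for k in range(n_per_class):
            slide_id = f"{label}_{k:03d}"
            spec = SlideSpec(
                label=label,
                seed=slide_seed(seed, index),
                base_size=base_size,
                tissue_cover=tissue_cover,
                artifact_count=artifact_count,
            )
            pyramid, truth = generate_slide(spec)
            pyramid.slide_id = slide_id
            slide_dir = out_dir / slide_id
            save_pyramid(pyramid, slide_dir)
            if save_ground_truth:
                Image.fromarray(truth.tissue_mask.astype(np.uint8) * 255).save(
                    slide_dir / TISSUE_MASK_NAME
                )
            rows.append({"slide_id": slide_id, "label": label, "path": slide_id})
            index += 1
    manifest = out_dir / MANIFEST_NAME
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["slide_id", "label", "path"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
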