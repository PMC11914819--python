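"""Patch quality filtering: background and blood rejection, circular masking.

Patches with little histological content are dropped before classification.
The decision combines a gray-level analysis (Rec.601 luma, global Otsu
binarisation, dark-pixel fraction as a tissue proxy) with a simple chromatic
blood rule (mean red / mean green ratio).  An optional circular mask blanks
the corners of each square patch so downstream features see a rotation-
neutral field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

REASON_KEPT = "kept"
REASON_BACKGROUND = "background"
REASON_BLOOD = "blood"


@dataclass(frozen=True)
class FilterConfig:
    tissue_threshold: float = 0.25
    binarize_method: str = "otsu"
    blood_red_ratio: float = 1.8
    circular_mask_enabled: bool = True
    mask_fill: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_threshold <= 1.0:
            raise ValueError(
                f"tissue_threshold must lie in [0, 1], got {self.tissue_threshold}"
            )
        if self.binarize_method not in ("otsu", "mean"):
            raise ValueError(f"unknown binarize_method {self.binarize_method!r}")


def rec601_gray(patch: np.ndarray) -> np.ndarray:
    """Rec.601 luma of an RGB patch, as float64 in [0, 255]."""
    p = np.asarray(patch, dtype=np.float64)
    if p.ndim == 2:
        return p
    return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


def tissue_fraction(patch: np.ndarray, method: str = "otsu") -> float:
    """Fraction of pixels darker than a global threshold of the patch luma.

    Dark pixels proxy stained tissue against a bright scanner background.  A
    contrast-free (uniform) patch has no meaningful threshold and is defined
    to contain no tissue.
    """
    if np.asarray(patch).size == 0:
        raise ValueError("patch is empty")
    gray = rec601_gray(patch)
    if np.ptp(gray) < 1e-9:
        return 0.0
    if method == "otsu":
        thr = threshold_otsu(gray)
    elif method == "mean":
        thr = float(gray.mean())
    else:
        raise ValueError(f"unknown binarize method {method!r}")
    return float(np.mean(gray < thr))


def red_green_ratio(patch: np.ndarray) -> float:
    """mean(R)/mean(G); +inf when the green channel is entirely zero."""
    p = np.asarray(patch, dtype=np.float64)
    if p.ndim == 2:
        return 1.0
    mean_g = p[..., 1].mean()
    if mean_g == 0.0:
        return np.inf
    return float(p[..., 0].mean() / mean_g)


def keep_patch(patch: np.ndarray, cfg: FilterConfig = FilterConfig()) -> tuple[bool, str]:
    """Keep a patch iff it is neither blood-dominated nor background.

    Returns ``(keep, reason)`` with reason in {kept, background, blood}.
    Blood is checked first: a saturated-red pool can be contrast-free and
    would otherwise masquerade as background.
    """
    if red_green_ratio(patch) >= cfg.blood_red_ratio:
        return (False, REASON_BLOOD)
    if tissue_fraction(patch, cfg.binarize_method) < cfg.tissue_threshold:
        return (False, REASON_BACKGROUND)
    return (True, REASON_KEPT)


def keep_triple(patches: Sequence[np.ndarray], cfg: FilterConfig = FilterConfig()) -> tuple[bool, str]:
    """Triple-level filter decision.

    The level-0 (finest) window carries the most reliable content signal, so
    its verdict decides for the whole triple: a triple is dropped exactly
    when its level-0 window is dropped.
    """
    return keep_patch(patches[0], cfg)


def circular_mask(patch: np.ndarray, fill: tuple[int, int, int] = (255, 255, 255)) -> np.ndarray:
    """Blank everything outside the inscribed circle of a square patch.

    The circle is centred at (s/2, s/2) with radius s/2 in continuous
    coordinates; a pixel is outside when its centre is.  The operation is
    idempotent and commutes with 90-degree rotations.
    """
    p = np.asarray(patch)
    s = p.shape[0]
    if p.shape[1] != s:
        raise ValueError(f"circular_mask requires a square patch, got {p.shape[:2]}")
    coords = np.arange(s, dtype=np.float64) + 0.5 - s / 2.0
    outside = coords[:, None] ** 2 + coords[None, :] ** 2 > (s / 2.0) ** 2
    out = p.copy()
    out[outside] = fill if p.ndim == 3 else fill[0]
    return out
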