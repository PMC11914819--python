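"""Pyramid geometry: level specs, cross-level coordinate mapping, and
midpoint-aligned patch-triple extraction.

A pyramidal slide stores the same physical scene at several resolutions.
Level 0 is the full-resolution raster; level ``i`` has every dimension
divided by an integer downsample factor.  The default three-level layout
(downsamples 1, 4, 16) mirrors the 40x / 10x / 2.5x magnification tiers of
a clinical slide scanner.

Patch triples are driven from the coarsest level: its raster is tiled, each
tile's centre is mapped up the pyramid, and a window of the same pixel size
is centred on that point at every finer level, so the three windows show one
physical neighbourhood at three magnifications.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

DEFAULT_DOWNSAMPLES = (1, 4, 16)
DEFAULT_MAGNIFICATIONS = (40.0, 10.0, 2.5)
DEFAULT_PATCH_SIZE = 512

PYRAMID_SIDECAR = "pyramid.json"


@dataclass(frozen=True)
class LevelSpec:
    """One resolution tier of a pyramid."""

    index: int
    magnification: float
    downsample: int

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValueError(f"downsample must be >= 1, got {self.downsample}")


@dataclass(frozen=True)
class PatchWindow:
    """A square, axis-aligned, half-open pixel window in level-local
    coordinates (0-based, x rightward, y downward)."""

    level: int
    x: int
    y: int
    size: int = DEFAULT_PATCH_SIZE

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"window origin must be non-negative, got ({self.x}, {self.y})")
        if self.size < 1:
            raise ValueError(f"window size must be positive, got {self.size}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.size / 2.0, self.y + self.size / 2.0)


@dataclass(frozen=True)
class AlignedTriple:
    """One window per pyramid level, all sharing a physical centre.

    ``center_l0`` is the shared centre expressed in level-0 pixels; mapping
    any window's own centre up to level 0 lands within half a downsample
    step of it per axis.
    """

    triple_id: int
    windows: tuple[PatchWindow, ...]
    center_l0: tuple[int, int]


class SlideReader(Protocol):
    """Adapter contract for real pyramidal slide readers (e.g. OpenSlide).

    Any object with these members can stand in for :class:`PyramidImage`
    in the geometry routines; bit-exactness across readers is not required.
    """

    downsamples: Sequence[int]

    def level_dimensions(self, level: int) -> tuple[int, int]: ...

    def read_region(self, level: int, window: PatchWindow) -> np.ndarray: ...


@dataclass
class PyramidImage:
    """An in-memory pyramidal image: ordered RGB rasters plus their
    downsample factors and nominal magnifications."""

    levels: list[np.ndarray]
    downsamples: tuple[int, ...] = DEFAULT_DOWNSAMPLES
    magnifications: tuple[float, ...] = DEFAULT_MAGNIFICATIONS
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.downsamples = tuple(int(d) for d in self.downsamples)
        self.magnifications = tuple(float(m) for m in self.magnifications)
        if len(self.levels) != len(self.downsamples):
            raise ValueError("one downsample factor required per level")
        if len(self.magnifications) != len(self.levels):
            raise ValueError("one magnification required per level")
        if self.downsamples[0] != 1:
            raise ValueError("level 0 must have downsample 1")
        if any(b <= a for a, b in zip(self.downsamples, self.downsamples[1:])):
            raise ValueError("downsamples must be strictly increasing")
        h0, w0 = self.levels[0].shape[:2]
        for i, (lvl, d) in enumerate(zip(self.levels, self.downsamples)):
            h, w = lvl.shape[:2]
            if h * d != h0 or w * d != w0:
                raise ValueError(
                    f"level {i} dimensions {(w, h)} are not level-0 {(w0, h0)} "
                    f"divided exactly by downsample {d}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_dimensions(self, level: int) -> tuple[int, int]:
        """(width, height) of one level."""
        h, w = self.levels[level].shape[:2]
        return (w, h)

    def level_spec(self, level: int) -> LevelSpec:
        return LevelSpec(level, self.magnifications[level], self.downsamples[level])

    def read_region(self, level: int, window: PatchWindow) -> np.ndarray:
        return read_region(self, level, window)


def map_point(
    point: tuple[float, float],
    from_level: LevelSpec | int,
    to_level: LevelSpec | int,
) -> tuple[int, int]:
    """Map a pixel coordinate between levels.

    Accepts :class:`LevelSpec` objects or bare downsample factors.  Going to
    a finer level multiplies by the integer downsample ratio; going to a
    coarser level floor-divides, so the round trip fine -> coarse -> fine
    moves a point by less than one downsample ratio per axis.
    """
    d_from = from_level.downsample if isinstance(from_level, LevelSpec) else int(from_level)
    d_to = to_level.downsample if isinstance(to_level, LevelSpec) else int(to_level)
    x, y = point
    if d_from == d_to:
        return (int(x), int(y))
    if d_to < d_from:
        if d_from % d_to:
            raise ValueError(f"downsample ratio {d_from}/{d_to} is not an integer")
        r = d_from // d_to
        return (int(x) * r, int(y) * r)
    if d_to % d_from:
        raise ValueError(f"downsample ratio {d_to}/{d_from} is not an integer")
    r = d_to // d_from
    return (int(x) // r, int(y) // r)


def map_point_checked(
    pyramid: PyramidImage,
    point: tuple[float, float],
    from_level: int,
    to_level: int,
) -> tuple[int, int]:
    """:func:`map_point` with a bounds check against the source level."""
    w, h = pyramid.level_dimensions(from_level)
    x, y = point
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"point {point} outside level {from_level} bounds {(w, h)}")
    return map_point(point, pyramid.level_spec(from_level), pyramid.level_spec(to_level))


def read_region(pyramid: PyramidImage, level: int, window: PatchWindow) -> np.ndarray:
    """Return a copy of the pixels under ``window`` at ``level``."""
    w, h = pyramid.level_dimensions(level)
    if window.x + window.size > w or window.y + window.size > h:
        raise ValueError(
            f"window {window} exceeds level {level} bounds {(w, h)}"
        )
    return pyramid.levels[level][
        window.y : window.y + window.size, window.x : window.x + window.size
    ].copy()


def aligned_patch_triples(
    pyramid: PyramidImage,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int | None = None,
) -> list[AlignedTriple]:
    """Tile the coarsest level and lift each tile centre up the pyramid.

    For every stride-spaced ``patch_size`` window on the coarsest level, the
    window centre is mapped to each finer level and a ``patch_size`` window
    is centred there.  Triples whose centred windows would cross a level
    boundary are dropped rather than padded, so every returned triple has
    full pixel coverage at all levels.
    """
    if stride is None:
        stride = patch_size
    if stride < 1:
        raise ValueError("stride must be positive")
    coarse = pyramid.n_levels - 1
    wc, hc = pyramid.level_dimensions(coarse)
    if patch_size > min(wc, hc):
        warnings.warn(
            f"patch_size {patch_size} exceeds coarsest level raster {(wc, hc)}; "
            "no triples can be extracted",
            stacklevel=2,
        )
        return []
    half = patch_size // 2
    ds = pyramid.downsamples
    triples: list[AlignedTriple] = []
    tid = 0
    for y in range(0, hc - patch_size + 1, stride):
        for x in range(0, wc - patch_size + 1, stride):
            cx, cy = x + half, y + half
            center_l0 = (cx * ds[coarse], cy * ds[coarse])
            windows: list[PatchWindow] = []
            ok = True
            for lvl in range(pyramid.n_levels):
                lx, ly = map_point(center_l0, 1, ds[lvl])
                wx, wy = lx - half, ly - half
                wl, hl = pyramid.level_dimensions(lvl)
                if wx < 0 or wy < 0 or wx + patch_size > wl or wy + patch_size > hl:
                    ok = False
                    break
                windows.append(PatchWindow(level=lvl, x=wx, y=wy, size=patch_size))
            if ok:
                triples.append(
                    AlignedTriple(triple_id=tid, windows=tuple(windows), center_l0=center_l0)
                )
                tid += 1
    return triples


def read_triple(pyramid: PyramidImage, triple: AlignedTriple) -> list[np.ndarray]:
    """Read the pixel data of every window in a triple, finest first."""
    return [read_region(pyramid, w.level, w) for w in triple.windows]


# --------------------------------------------------------------------------
# Fixture slide format: a directory holding level_<i>.png plus pyramid.json
# ({"downsamples": [...], "magnifications": [...]}).


def save_pyramid(pyramid: PyramidImage, slide_dir: str | Path) -> Path:
    slide_dir = Path(slide_dir)
    slide_dir.mkdir(parents=True, exist_ok=True)
    for i, lvl in enumerate(pyramid.levels):
        Image.fromarray(np.asarray(lvl, dtype=np.uint8)).save(slide_dir / f"level_{i}.png")
    sidecar = {
        "downsamples": list(pyramid.downsamples),
        "magnifications": list(pyramid.magnifications),
        "slide_id": pyramid.slide_id,
    }
    (slide_dir / PYRAMID_SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return slide_dir


def load_pyramid(slide_dir: str | Path) -> PyramidImage:
    slide_dir = Path(slide_dir)
    sidecar = json.loads((slide_dir / PYRAMID_SIDECAR).read_text())
    downsamples = tuple(sidecar["downsamples"])
    levels = [
        np.asarray(Image.open(slide_dir / f"level_{i}.png").convert("RGB"))
        for i in range(len(downsamples))
    ]
    return PyramidImage(
        levels=levels,
        downsamples=downsamples,
        magnifications=tuple(sidecar["magnifications"]),
        slide_id=sidecar.get("slide_id", slide_dir.name),
    )
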