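"""Patch extraction from slide images.

Candidate 1024x1024 windows are sampled from a flat raster slide, kept when
they contain enough stained tissue (dark pixels) and no saturation artifact,
and converted to grayscale.  Stained tissue is darker than the near-white
glass background, so the tissue criterion is a dark-pixel fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Patch",
    "TissueFilterConfig",
    "to_grayscale",
    "tissue_fraction",
    "saturated_fraction",
    "extract_patches",
]

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class Patch:
    """A square grayscale window cut from a slide.

    ``row``/``col`` are the 0-based offsets of the top-left corner in the
    parent slide; the window is half-open: [row, row+size) x [col, col+size).
    """

    pixels: np.ndarray
    row: int = 0
    col: int = 0

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class TissueFilterConfig:
    """Acceptance rules for candidate patches.

    tissue_threshold: pixels strictly darker than this count as tissue
        (default 220: glass background on an 8-bit slide is near-white).
    min_tissue_fraction: minimum tissue-pixel fraction (default 0.5).
    saturation_level: pixels at or above this are considered saturated.
    saturation_fraction_max: maximum tolerated saturated-pixel fraction,
        an automated stand-in for manual artifact review.
    """

    tissue_threshold: float = 220.0
    min_tissue_fraction: float = 0.5
    saturation_level: float = 250.0
    saturation_fraction_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in (0, 1]")
        if not 0.0 <= self.saturation_fraction_max <= 1.0:
            raise ValueError("saturation_fraction_max must be a proportion")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale by the Rec. 601 luma sum.

    Already-grayscale (2-D) input passes through unchanged (idempotent).
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected 2-D grayscale or HxWx3 RGB, got shape {arr.shape}")
    w = np.asarray(LUMA_WEIGHTS)
    gray = arr[..., 0] * w[0] + arr[..., 1] * w[1] + arr[..., 2] * w[2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def tissue_fraction(patch: np.ndarray | Patch, cfg: TissueFilterConfig | None = None) -> float:
    """Fraction of pixels darker than the tissue threshold, in [0, 1]."""
    cfg = cfg or TissueFilterConfig()
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return float(np.mean(pixels < cfg.tissue_threshold))


def saturated_fraction(patch: np.ndarray | Patch, cfg: TissueFilterConfig | None = None) -> float:
    """Fraction of pixels at or above the saturation level."""
    cfg = cfg or TissueFilterConfig()
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return float(np.mean(pixels >= cfg.saturation_level))


def patch_qualifies(pixels: np.ndarray, cfg: TissueFilterConfig) -> bool:
    """Re-checkable acceptance predicate used by :func:`extract_patches`."""
    return (tissue_fraction(pixels, cfg) >= cfg.min_tissue_fraction
            and saturated_fraction(pixels, cfg) <= cfg.saturation_fraction_max)


def _grid_origins(h: int, w: int, size: int) -> list[tuple[int, int]]:
    rows = list(range(0, h - size + 1, size))
    cols = list(range(0, w - size + 1, size))
    if rows and rows[-1] != h - size:
        rows.append(h - size)
    if cols and cols[-1] != w - size:
        cols.append(w - size)
    return [(r, c) for r in rows for c in cols]


def extract_patches(slide: np.ndarray, n_patches: int = 100, patch_size: int = 1024,
                    cfg: TissueFilterConfig | None = None, rng_seed: int = 0,
                    max_tries_per_patch: int = 200) -> list[Patch]:
    """Extract up to ``n_patches`` qualifying grayscale patches from a slide.

    Candidate origins are sampled uniformly at random (seeded) with
    rejection; when random sampling stalls, a regular grid of origins is
    scanned as a fallback so small slides are still fully explored.  Origins
    are unique.  If the slide cannot supply ``n_patches`` qualifying
    windows, the shorter list is returned with a warning.
    """
    cfg = cfg or TissueFilterConfig()
    gray = to_grayscale(slide)
    h, w = gray.shape
    if h < patch_size or w < patch_size:
        raise ValueError(f"slide {gray.shape} smaller than patch_size {patch_size}")

    rng = np.random.default_rng(rng_seed)
    accepted: list[Patch] = []
    seen: set[tuple[int, int]] = set()

    budget = max_tries_per_patch * n_patches
    while len(accepted) < n_patches and budget > 0:
        budget -= 1
        r = int(rng.integers(0, h - patch_size + 1))
        c = int(rng.integers(0, w - patch_size + 1))
        if (r, c) in seen:
            continue
        seen.add((r, c))
        window = gray[r:r + patch_size, c:c + patch_size]
        if patch_qualifies(window, cfg):
            accepted.append(Patch(window.copy(), r, c))

    if len(accepted) < n_patches:
        for r, c in _grid_origins(h, w, patch_size):
            if len(accepted) >= n_patches:
                break
            if (r, c) in seen:
                continue
            seen.add((r, c))
            window = gray[r:r + patch_size, c:c + patch_size]
            if patch_qualifies(window, cfg):
                accepted.append(Patch(window.copy(), r, c))

    if len(accepted) < n_patches:
        msg = (f"slide supplied only {len(accepted)}/{n_patches} qualifying "
               f"patches (tissue >= {cfg.min_tissue_fraction:.0%}, "
               f"saturation <= {cfg.saturation_fraction_max:.0%})")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return accepted
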