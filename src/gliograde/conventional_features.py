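"""Conventional imaging features: whole-patch statistics and nuclear morphometry.

Two groups, 26 features in total per patch:

* 16 statistical features over all pixels: mean, standard deviation, median,
  skewness, kurtosis (non-excess), max, min, and the nine deciles
  (10th..90th percentile, linear interpolation).
* 10 morphology features averaged over nucleus-like connected components:
  edge sharpness, perimeter, area, eccentricity, convex area, Euler number,
  orientation, compactness, major- and minor-axis length.

Components come from a two-cluster K-means split of the intensity histogram
(the darker cluster is the nuclear foreground on an H&E-like grayscale
patch), 8-connected labeling, and an area filter that keeps components with
area strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from scipy.ndimage import binary_erosion
from skimage.filters import sobel

__all__ = [
    "STATISTICAL_FEATURE_NAMES",
    "MORPHOLOGY_FEATURE_NAMES",
    "CONVENTIONAL_FEATURE_NAMES",
    "ComponentSet",
    "EmptyComponentError",
    "statistical_features",
    "kmeans_threshold",
    "segment_components",
    "morphological_features",
    "conventional_features",
]

STATISTICAL_FEATURE_NAMES = (
    "conv_mean", "conv_std", "conv_median", "conv_skewness", "conv_kurtosis",
    "conv_max", "conv_min",
    "conv_p10", "conv_p20", "conv_p30", "conv_p40", "conv_p50",
    "conv_p60", "conv_p70", "conv_p80", "conv_p90",
)

MORPHOLOGY_FEATURE_NAMES = (
    "conv_edge_sharpness", "conv_perimeter", "conv_area", "conv_eccentricity",
    "conv_convex_area", "conv_euler_number", "conv_orientation",
    "conv_compactness", "conv_major_axis_length", "conv_minor_axis_length",
)

CONVENTIONAL_FEATURE_NAMES = STATISTICAL_FEATURE_NAMES + MORPHOLOGY_FEATURE_NAMES


class EmptyComponentError(ValueError):
    """Raised when no component survives the area filter; the caller should
    drop the patch (with a warning) rather than emit undefined features."""


@dataclass(frozen=True)
class ComponentSet:
    """Labeled foreground components of one patch.

    ``labels`` is 0 on background and 1..n_components on retained
    components (8-connectivity); ``area_threshold`` is the strict lower
    bound applied to component pixel counts.
    """

    labels: np.ndarray
    area_threshold: int

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


def statistical_features(patch: np.ndarray) -> dict[str, float]:
    """The 16 whole-patch statistics.

    Skewness and kurtosis are the standardized third/fourth central moments
    (kurtosis non-excess: 3 for a normal sample); on a zero-variance patch
    both are reported as 0 so downstream feature matrices stay finite.
    """
    x = np.asarray(patch, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty patch")
    mean = float(np.mean(x))
    std = float(np.std(x))
    if std > 0:
        z = (x - mean) / std
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    else:
        skew = 0.0
        kurt = 0.0
    out = {
        "conv_mean": mean,
        "conv_std": std,
        "conv_median": float(np.median(x)),
        "conv_skewness": skew,
        "conv_kurtosis": kurt,
        "conv_max": float(np.max(x)),
        "conv_min": float(np.min(x)),
    }
    deciles = np.percentile(x, np.arange(10, 100, 10))
    for q, v in zip(range(10, 100, 10), deciles):
        out[f"conv_p{q}"] = float(v)
    return out


def kmeans_threshold(patch: np.ndarray, max_iter: int = 100) -> float:
    """Two-cluster 1-D K-means on pixel intensities; returns the midpoint
    between the two final centers (pixels below it form the dark cluster).

    Centers are initialized at the 25th/75th intensity percentiles, which
    makes the segmentation deterministic.  A constant patch has no two
    clusters and raises ``ValueError``.
    """
    x = np.asarray(patch, dtype=np.float64).ravel()
    lo, hi = np.percentile(x, [25, 75])
    if np.min(x) == np.max(x):
        raise ValueError("constant patch: K-means needs >= 2 distinct intensities")
    if lo == hi:  # degenerate but non-constant: fall back to extremes
        lo, hi = float(np.min(x)), float(np.max(x))
    c_dark, c_bright = float(lo), float(hi)
    for _ in range(max_iter):
        cut = 0.5 * (c_dark + c_bright)
        dark = x < cut
        if not dark.any() or dark.all():
            break
        new_dark = float(np.mean(x[dark]))
        new_bright = float(np.mean(x[~dark]))
        if new_dark == c_dark and new_bright == c_bright:
            break
        c_dark, c_bright = new_dark, new_bright
    return 0.5 * (c_dark + c_bright)


def segment_components(patch: np.ndarray, k: int = 2,
                       area_threshold: int = 100) -> ComponentSet:
    """Segment nucleus-like components: K-means split, dark cluster as
    foreground, 8-connected labeling, area filter (keep area > threshold)."""
    if k != 2:
        raise ValueError("only k=2 intensity clustering is supported")
    cut = kmeans_threshold(patch)
    mask = np.asarray(patch, dtype=np.float64) < cut
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas > area_threshold) + 1
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    return ComponentSet(labels=labels, area_threshold=area_threshold)


def _edge_sharpness(region_mask: np.ndarray, gradient: np.ndarray) -> float:
    """Mean gradient magnitude over the boundary pixels of one component."""
    boundary = region_mask & ~binary_erosion(region_mask)
    if not boundary.any():
        boundary = region_mask
    return float(np.mean(gradient[boundary]))


def morphological_features(components: ComponentSet,
                           patch: np.ndarray) -> dict[str, float]:
    """The 10 morphology features, each averaged over retained components.

    Orientation is the angle of the major axis from the image horizontal,
    in degrees in (-90, 90]; compactness is 4*pi*area/perimeter^2 (1 for a
    perfect disk); edge sharpness is the mean Sobel gradient magnitude on
    component boundary pixels.
    """
    if components.n_components == 0:
        raise EmptyComponentError("no component above area threshold")
    gradient = sobel(np.asarray(patch, dtype=np.float64))
    labels = components.labels
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        perimeter = float(p.perimeter)
        area = float(p.area)
        compactness = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
        # regionprops orientation: major axis vs row (vertical) axis, in
        # (-pi/2, pi/2]; convert to signed angle from horizontal in (-90, 90]
        orient = 90.0 - np.degrees(p.orientation)
        if orient > 90.0:
            orient -= 180.0
        region_mask = np.zeros_like(labels, dtype=bool)
        sl = p.slice
        region_mask[sl] = labels[sl] == p.label
        rows.append({
            "conv_edge_sharpness": _edge_sharpness(region_mask, gradient),
            "conv_perimeter": perimeter,
            "conv_area": area,
            "conv_eccentricity": float(p.eccentricity),
            "conv_convex_area": float(p.area_convex),
            "conv_euler_number": float(p.euler_number),
            "conv_orientation": orient,
            "conv_compactness": compactness,
            "conv_major_axis_length": float(p.axis_major_length),
            "conv_minor_axis_length": float(p.axis_minor_length),
        })
    return {name: float(np.mean([r[name] for r in rows]))
            for name in MORPHOLOGY_FEATURE_NAMES}


def conventional_features(patch: np.ndarray,
                          area_threshold: int = 100) -> dict[str, float]:
    """All 26 conventional features of one grayscale patch.

    Raises :class:`EmptyComponentError` when segmentation yields no
    component above the area threshold.
    """
    out = statistical_features(patch)
    comps = segment_components(patch, area_threshold=area_threshold)
    out.update(morphological_features(comps, patch))
    return out
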