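"""Texture features from gray-level co-occurrence and run-length matrices.

The patch is first quantized to 16 gray levels (equal-width bins spanning
the patch's own intensity range).  For each of the four principal
directions (0, 45, 90, 135 degrees) a distance-1 co-occurrence matrix
(GLCM, symmetrized and normalized) and a run-length matrix (GLRLM, maximal
runs along that direction's scan lines) are built.  Eight Haralick-style
GLCM statistics and ten Galloway run-length statistics are computed per
direction and averaged over the four directions: 18 features per patch.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DIRECTIONS",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "quantize",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "extract_texture",
]

#: Direction -> (row, col) offset of the distance-1 neighbor.  Angles follow
#: the usual image convention (0 deg = east, 45 deg = north-east).
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

GLCM_FEATURE_NAMES = (
    "tex_glcm_contrast", "tex_glcm_correlation", "tex_glcm_energy",
    "tex_glcm_homogeneity", "tex_glcm_entropy", "tex_glcm_cluster_shade",
    "tex_glcm_cluster_prominence", "tex_glcm_autocorrelation",
)

GLRLM_FEATURE_NAMES = (
    "tex_glrlm_lre", "tex_glrlm_sre", "tex_glrlm_rln", "tex_glrlm_gln",
    "tex_glrlm_hglre", "tex_glrlm_lglre", "tex_glrlm_srhgle",
    "tex_glrlm_srlgle", "tex_glrlm_lrhgle", "tex_glrlm_lrlgle",
)

TEXTURE_FEATURE_NAMES = GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES


def quantize(patch: np.ndarray, levels: int = 16) -> np.ndarray:
    """Quantize a patch to ``levels`` gray levels by equal-width binning of
    its own [min, max] range; a constant patch maps to level 0 everywhere.

    Quantization preserves intensity order.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    x = np.asarray(patch, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(x.shape, dtype=np.int64)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def build_glcm(q: np.ndarray, direction: int, levels: int = 16) -> np.ndarray:
    """Distance-1 co-occurrence matrix for one direction, symmetrized and
    normalized to a joint probability table p(i, j)."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
    q = np.asarray(q)
    if q.ndim != 2 or min(q.shape) < 2:
        raise ValueError("quantized patch must be 2-D, at least 2x2")
    dr, dc = DIRECTIONS[direction]
    h, w = q.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()
    glcm = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(glcm, (a, b), 1.0)
    glcm = glcm + glcm.T
    total = glcm.sum()
    if total == 0:
        raise ValueError("no pixel pairs in this direction")
    return glcm / total


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Eight Haralick-style statistics of one normalized GLCM.

    Entropy uses log base 2 with 0*log(0) = 0.  Correlation of a
    zero-variance GLCM (all mass on one level) is defined as 1.
    """
    p = np.asarray(glcm, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    var_i = float(((ii - mu_i) ** 2 * p).sum())
    var_j = float(((jj - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum()
                            / np.sqrt(var_i * var_j))
    else:
        correlation = 1.0
    nz = p[p > 0]
    spread = ii + jj - mu_i - mu_j
    return {
        "tex_glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "tex_glcm_correlation": correlation,
        "tex_glcm_energy": float((p ** 2).sum()),
        "tex_glcm_homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "tex_glcm_entropy": float(-(nz * np.log2(nz)).sum()),
        "tex_glcm_cluster_shade": float((spread ** 3 * p).sum()),
        "tex_glcm_cluster_prominence": float((spread ** 4 * p).sum()),
        "tex_glcm_autocorrelation": float((ii * jj * p).sum()),
    }


def _scan_lines(q: np.ndarray, direction: int) -> list[np.ndarray]:
    """Scan lines of the patch along one direction (for run extraction)."""
    if direction == 0:
        return list(q)
    if direction == 90:
        return list(q.T)
    if direction == 45:
        f = np.fliplr(q)
        return [f.diagonal(k) for k in range(-(q.shape[0] - 1), q.shape[1])]
    if direction == 135:
        return [q.diagonal(k) for k in range(-(q.shape[0] - 1), q.shape[1])]
    raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")


def build_glrlm(q: np.ndarray, direction: int, levels: int = 16) -> np.ndarray:
    """Run-length matrix r(i, j): number of maximal runs of level i with
    length j (column j-1) along the direction's scan lines."""
    q = np.asarray(q)
    if q.ndim != 2 or q.size == 0:
        raise ValueError("quantized patch must be a non-empty 2-D array")
    max_run = max(q.shape)
    glrlm = np.zeros((levels, max_run), dtype=np.float64)
    for line in _scan_lines(q, direction):
        line = np.asarray(line)
        n = line.size
        if n == 0:
            continue
        # boundaries of maximal equal-value runs
        breaks = np.flatnonzero(line[1:] != line[:-1]) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [n]))
        lengths = ends - starts
        np.add.at(glrlm, (line[starts], lengths - 1), 1.0)
    return glrlm


def glrlm_features(glrlm: np.ndarray) -> dict[str, float]:
    """Ten Galloway run-length statistics of one GLRLM.

    Gray-level index i is taken 1-based in the emphasis terms so the
    low-gray-level features stay finite at level 0; run length j is the
    natural 1-based length.  Nr is the total run count.
    """
    r = np.asarray(glrlm, dtype=np.float64)
    nr = r.sum()
    if nr == 0:
        raise ValueError("empty GLRLM (no runs)")
    L, J = r.shape
    i = np.arange(1, L + 1, dtype=np.float64)[:, None]
    j = np.arange(1, J + 1, dtype=np.float64)[None, :]
    run_per_level = r.sum(axis=1)
    run_per_length = r.sum(axis=0)
    return {
        "tex_glrlm_lre": float((r * j ** 2).sum() / nr),
        "tex_glrlm_sre": float((r / j ** 2).sum() / nr),
        "tex_glrlm_rln": float((run_per_length ** 2).sum() / nr),
        "tex_glrlm_gln": float((run_per_level ** 2).sum() / nr),
        "tex_glrlm_hglre": float((r * i ** 2).sum() / nr),
        "tex_glrlm_lglre": float((r / i ** 2).sum() / nr),
        "tex_glrlm_srhgle": float((r * i ** 2 / j ** 2).sum() / nr),
        "tex_glrlm_srlgle": float((r / (i ** 2 * j ** 2)).sum() / nr),
        "tex_glrlm_lrhgle": float((r * i ** 2 * j ** 2).sum() / nr),
        "tex_glrlm_lrlgle": float((r * j ** 2 / i ** 2).sum() / nr),
    }


def extract_texture(patch: np.ndarray, levels: int = 16) -> dict[str, float]:
    """The 18 direction-averaged texture features of one grayscale patch."""
    q = quantize(patch, levels)
    acc: dict[str, float] = {name: 0.0 for name in TEXTURE_FEATURE_NAMES}
    for direction in DIRECTIONS:
        feats = glcm_features(build_glcm(q, direction, levels))
        feats.update(glrlm_features(build_glrlm(q, direction, levels)))
        for name, v in feats.items():
            acc[name] += v
    return {name: v / len(DIRECTIONS) for name, v in acc.items()}
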