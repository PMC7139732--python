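"""Texture features vs brute-force oracles and analytic limits."""

import numpy as np
import pytest

from gliograde.texture_features import (DIRECTIONS, TEXTURE_FEATURE_NAMES,
                                        build_glcm, build_glrlm,
                                        extract_texture, glcm_features,
                                        glrlm_features, quantize)

# ---------------------------------------------------------------- oracles


def brute_glcm(q, direction, levels=16):
    """Double-loop distance-1 pair counter, symmetrized and normalized."""
    dr, dc = DIRECTIONS[direction]
    h, w = q.shape
    m = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
                m[q[r2, c2], q[r, c]] += 1
    return m / m.sum()


def brute_glrlm(q, direction, levels=16):
    """Literal run scanner over the direction's scan lines."""
    h, w = q.shape
    if direction == 0:
        lines = [q[r, :] for r in range(h)]
    elif direction == 90:
        lines = [q[:, c] for c in range(w)]
    else:
        flipped = np.fliplr(q) if direction == 45 else q
        lines = [flipped.diagonal(k) for k in range(-(h - 1), w)]
    m = np.zeros((levels, max(h, w)))
    for line in lines:
        idx = 0
        while idx < len(line):
            j = idx
            while j + 1 < len(line) and line[j + 1] == line[idx]:
                j += 1
            m[line[idx], j - idx] += 1
            idx = j + 1
    return m


def literal_glcm_features(p):
    """Textbook formulas evaluated with explicit loops."""
    L = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * p[i, j] for i in range(L) for j in range(L))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(L) for j in range(L))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    corr = (sum((i - mu_i) * (j - mu_j) * p[i, j]
                for i in range(L) for j in range(L)) / np.sqrt(var_i * var_j)
            if var_i > 0 and var_j > 0 else 1.0)
    return {
        "tex_glcm_contrast": sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L)),
        "tex_glcm_correlation": corr,
        "tex_glcm_energy": sum(p[i, j] ** 2 for i in range(L) for j in range(L)),
        "tex_glcm_homogeneity": sum(p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L)),
        "tex_glcm_entropy": -sum(p[i, j] * np.log2(p[i, j])
                                 for i in range(L) for j in range(L) if p[i, j] > 0),
        "tex_glcm_cluster_shade": sum((i + j - mu_i - mu_j) ** 3 * p[i, j]
                                      for i in range(L) for j in range(L)),
        "tex_glcm_cluster_prominence": sum((i + j - mu_i - mu_j) ** 4 * p[i, j]
                                           for i in range(L) for j in range(L)),
        "tex_glcm_autocorrelation": sum(i * j * p[i, j] for i in range(L) for j in range(L)),
    }


def literal_glrlm_features(r):
    L, J = r.shape
    nr = r.sum()
    f = dict.fromkeys(
        ("tex_glrlm_lre", "tex_glrlm_sre", "tex_glrlm_hglre", "tex_glrlm_lglre",
         "tex_glrlm_srhgle", "tex_glrlm_srlgle", "tex_glrlm_lrhgle",
         "tex_glrlm_lrlgle"), 0.0)
    for i0 in range(L):
        i = i0 + 1  # 1-based gray level
        for j0 in range(J):
            j = j0 + 1
            v = r[i0, j0]
            f["tex_glrlm_lre"] += v * j ** 2
            f["tex_glrlm_sre"] += v / j ** 2
            f["tex_glrlm_hglre"] += v * i ** 2
            f["tex_glrlm_lglre"] += v / i ** 2
            f["tex_glrlm_srhgle"] += v * i ** 2 / j ** 2
            f["tex_glrlm_srlgle"] += v / (i ** 2 * j ** 2)
            f["tex_glrlm_lrhgle"] += v * i ** 2 * j ** 2
            f["tex_glrlm_lrlgle"] += v * j ** 2 / i ** 2
    f["tex_glrlm_gln"] = sum(r[i0, :].sum() ** 2 for i0 in range(L))
    f["tex_glrlm_rln"] = sum(r[:, j0].sum() ** 2 for j0 in range(J))
    return {k: v / nr for k, v in f.items()}


# ------------------------------------------------------------- quantizer


class TestQuantize:
    def test_linear_ramp_hits_all_16_levels(self):
        ramp = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        q = quantize(ramp, 16)
        assert sorted(np.unique(q)) == list(range(16))

    def test_constant_patch_maps_to_level_zero(self):
        q = quantize(np.full((8, 8), 93, np.uint8))
        assert np.all(q == 0)

    def test_two_valued_patch_hits_extremes(self):
        patch = np.array([[10, 240], [240, 10]], np.uint8)
        assert sorted(np.unique(quantize(patch, 16))) == [0, 15]

    def test_preserves_intensity_order(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 256, size=(12, 12))
        q = quantize(patch, 16)
        a, b = patch.ravel(), q.ravel()
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order]) >= 0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4)), levels=1)


# ------------------------------------------------------------------ GLCM


class TestGLCM:
    def test_two_row_image_pairs(self):
        q = np.array([[0, 0], [1, 1]])
        p = build_glcm(q, 0, levels=2)
        assert p[0, 0] == pytest.approx(0.5)
        assert p[1, 1] == pytest.approx(0.5)
        assert p[0, 1] == 0 and p[1, 0] == 0

    def test_constant_image_single_cell(self):
        p = build_glcm(np.zeros((4, 4), int), 45, levels=16)
        assert p[0, 0] == 1.0

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, direction, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 16, size=rng.integers(2, 8, size=2))
        np.testing.assert_allclose(build_glcm(q, direction),
                                   brute_glcm(q, direction), atol=1e-15)

    def test_features_on_constant_image(self):
        f = glcm_features(build_glcm(np.zeros((6, 6), int), 0))
        assert f["tex_glcm_contrast"] == 0
        assert f["tex_glcm_energy"] == 1
        assert f["tex_glcm_homogeneity"] == 1
        assert f["tex_glcm_entropy"] == 0
        assert f["tex_glcm_cluster_shade"] == 0
        assert f["tex_glcm_correlation"] == 1  # zero-variance convention

    def test_checkerboard_contrast_is_225(self):
        base = np.indices((8, 8)).sum(axis=0) % 2
        q = base * 15  # strict two-level checkerboard at levels 0 and 15
        f = glcm_features(build_glcm(q, 0))
        assert f["tex_glcm_contrast"] == pytest.approx(225.0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_features_match_literal_formulas(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 16, size=(8, 8))
        got = glcm_features(build_glcm(q, 0))
        expected = literal_glcm_features(build_glcm(q, 0))
        for name in expected:
            assert got[name] == pytest.approx(expected[name], rel=1e-12, abs=1e-12), name

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((16, 16)))


# ----------------------------------------------------------------- GLRLM


class TestGLRLM:
    def test_constant_image_horizontal_runs(self):
        r = build_glrlm(np.zeros((4, 4), int), 0)
        assert r[0, 3] == 4 and r.sum() == 4

    def test_alternating_rows_all_runs_length_one(self):
        q = np.tile([0, 1, 0, 1], (4, 1))
        r = build_glrlm(q, 0)
        assert r.sum() == 16
        assert r[:, 0].sum() == 16

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, direction, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 4, size=rng.integers(2, 8, size=2))
        got = build_glrlm(q, direction)
        expected = brute_glrlm(q, direction)
        np.testing.assert_allclose(got[:, :expected.shape[1]], expected, atol=0)

    def test_run_pixel_conservation(self):
        rng = np.random.default_rng(5)
        q = rng.integers(0, 16, size=(9, 7))
        for direction in DIRECTIONS:
            r = build_glrlm(q, direction)
            j = np.arange(1, r.shape[1] + 1)
            assert (r * j).sum() == q.size  # every pixel in exactly one run

    def test_constant_4x4_feature_values(self):
        f = glrlm_features(build_glrlm(np.zeros((4, 4), int), 0))
        assert f["tex_glrlm_sre"] == pytest.approx(1 / 16)
        assert f["tex_glrlm_lre"] == pytest.approx(16)
        assert f["tex_glrlm_rln"] == pytest.approx(4)
        assert f["tex_glrlm_gln"] == pytest.approx(4)

    def test_all_length_one_runs(self):
        q = np.tile([0, 1, 0, 1], (4, 1))
        f = glrlm_features(build_glrlm(q, 0))
        assert f["tex_glrlm_sre"] == 1.0
        assert f["tex_glrlm_lre"] == 1.0

    @pytest.mark.parametrize("seed", [6, 7])
    def test_features_match_literal_formulas(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 16, size=(10, 6))
        r = build_glrlm(q, 135)
        got = glrlm_features(r)
        expected = literal_glrlm_features(r)
        for name in expected:
            assert got[name] == pytest.approx(expected[name], abs=1e-12), name

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            glrlm_features(np.zeros((16, 4)))


# ------------------------------------------------------ direction average


class TestExtractTexture:
    def test_exactly_18_features(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        f = extract_texture(patch)
        assert tuple(f) == TEXTURE_FEATURE_NAMES
        assert len(f) == 18
        assert 0 < f["tex_glcm_energy"] <= 1
        assert 0 < f["tex_glcm_homogeneity"] <= 1
        assert f["tex_glcm_entropy"] >= 0

    def test_constant_patch_limits(self):
        f = extract_texture(np.full((16, 16), 7, np.uint8))
        assert f["tex_glcm_contrast"] == 0
        assert f["tex_glcm_energy"] == 1

    def test_invariant_to_90_degree_rotation_and_flips(self):
        rng = np.random.default_rng(1)
        patch = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
        f0 = extract_texture(patch)
        for transform in (np.rot90, np.fliplr, np.flipud):
            ft = extract_texture(transform(patch).copy())
            for name in TEXTURE_FEATURE_NAMES:
                assert ft[name] == pytest.approx(f0[name], abs=1e-9), name

    def test_contrast_and_entropy_rise_with_noise(self):
        # two anchor pixels pin the quantization range to [0, 255] so the
        # noise effect is not confounded by the per-patch adaptive binning
        means = {"tex_glcm_contrast": [], "tex_glcm_entropy": []}
        for sd in (0.0, 1.0, 8.0, 16.0, 32.0):
            feats = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                patch = np.clip(128 + rng.normal(0, sd, (32, 32)), 0, 255).astype(np.uint8)
                patch[0, 0], patch[0, 1] = 0, 255
                feats.append(extract_texture(patch))
            for name in means:
                means[name].append(np.mean([f[name] for f in feats]))
        for name, series in means.items():
            assert all(a <= b + 1e-12 for a, b in zip(series, series[1:])), name
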