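"""Unit and property tests for quantization, GLCMs and Haralick features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofilmtex import (
    ANGLES,
    EmptyGLCMError,
    GLCM,
    GreyImage,
    OffsetSpec,
    QuantizedImage,
    compute_glcm,
    directional_summary,
    haralick_features,
    normalize_glcm,
    quantize,
)


# ---------------------------------------------------------------- oracles


def brute_force_glcm(levels, L, dr, dc, symmetric=False):
    """Exhaustive pixel-pair enumeration."""
    H, W = levels.shape
    out = np.zeros((L, L))
    for r in range(H):
        for c in range(W):
            rn, cn = r + dr, c + dc
            if 0 <= rn < H and 0 <= cn < W:
                out[levels[r, c], levels[rn, cn]] += 1
                if symmetric:
                    out[levels[rn, cn], levels[r, c]] += 1
    return out


def naive_features(p):
    """Direct double-loop evaluation of the five statistics (nats)."""
    L = p.shape[0]
    contrast = corr_num = energy = homog = entropy = 0.0
    mu_i = mu_j = s_ii = s_jj = 0.0
    for i in range(L):
        for j in range(L):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    for i in range(L):
        for j in range(L):
            contrast += (i - j) ** 2 * p[i, j]
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
            if p[i, j] > 0:
                entropy -= p[i, j] * math.log(p[i, j])
            s_ii += i * i * p[i, j]
            s_jj += j * j * p[i, j]
            corr_num += (i - mu_i) * (j - mu_j) * p[i, j]
    var_i = s_ii - mu_i**2
    var_j = s_jj - mu_j**2
    corr = (
        corr_num / math.sqrt(var_i * var_j)
        if var_i > 0 and var_j > 0
        else float("nan")
    )
    return dict(
        contrast=contrast,
        correlation=corr,
        energy=energy,
        homogeneity=homog,
        entropy=entropy,
    )


# ------------------------------------------------------------- quantize


@pytest.mark.parametrize(
    "pixels, L, rng_, expected",
    [
        ([[7.0, 7.0], [7.0, 7.0]], 5, None, [[0, 0], [0, 0]]),
        ([[10, 20], [30, 40]], 4, (10, 40), [[0, 1], [2, 3]]),
    ],
)
def test_quantize_examples(pixels, L, rng_, expected):
    q = quantize(GreyImage(np.array(pixels, float)), L, rng_)
    assert q.levels.tolist() == expected


def test_quantize_linear_scaling_convention():
    """0..255 into 8 levels: bin edges at multiples of 32, endpoints clamp."""
    img = GreyImage(np.arange(256.0).reshape(16, 16))
    q = quantize(img, 8, (0, 255))
    flat = q.levels.ravel()
    assert flat[31] == 0 and flat[32] == 1
    assert flat[0] == 0 and flat[255] == 7
    for v in range(256):
        assert flat[v] == min(v // 32, 7)


def test_quantize_out_of_range_clamps():
    img = GreyImage(np.array([[-5.0, 0.0, 100.0, 300.0]]))
    q = quantize(img, 4, (0, 255))
    assert q.levels.tolist() == [[0, 0, 1, 3]]


def test_quantize_rejects_bad_levels():
    img = GreyImage(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        quantize(img, 1)


def test_grey_image_rejects_non_finite():
    with pytest.raises(ValueError):
        GreyImage(np.array([[1.0, np.nan]]))


# ------------------------------------------------------------ compute_glcm


@pytest.mark.parametrize(
    "levels, expected",
    [
        ([[0, 0], [1, 1]], [[1, 0], [0, 1]]),
        ([[0, 1], [1, 0]], [[0, 1], [1, 0]]),
    ],
)
def test_glcm_horizontal_examples(levels, expected):
    q = QuantizedImage(np.array(levels), 2)
    g = compute_glcm(q, OffsetSpec(0, 1), symmetric=False)
    assert g.matrix.tolist() == expected


def test_glcm_matches_brute_force(rng):
    for _ in range(20):
        H, W = rng.integers(4, 33, 2)
        L = int(rng.choice([2, 4, 8, 16]))
        levels = rng.integers(0, L, (H, W))
        q = QuantizedImage(levels, L)
        for angle in ANGLES:
            for symmetric in (False, True):
                off = OffsetSpec(angle, 1)
                got = compute_glcm(q, off, symmetric=symmetric).matrix
                dr, dc = off.displacement
                want = brute_force_glcm(levels, L, dr, dc, symmetric)
                np.testing.assert_array_equal(got, want)


def test_glcm_count_conservation(rng):
    """Total counts follow the closed-form in-bounds pair formulas."""
    H, W, d = 11, 17, 2
    q = QuantizedImage(rng.integers(0, 8, (H, W)), 8)
    expected = {
        0: H * (W - d),
        45: (H - d) * (W - d),
        90: (H - d) * W,
        135: (H - d) * (W - d),
    }
    for angle, n in expected.items():
        g = compute_glcm(q, OffsetSpec(angle, d))
        assert g.matrix.sum() == n


def test_glcm_empty_raises():
    q = QuantizedImage(np.array([[0, 1]]), 2)
    with pytest.raises(EmptyGLCMError):
        compute_glcm(q, OffsetSpec(90, 1))  # one row, vertical displacement


def test_glcm_matches_skimage_symmetric(rng):
    """Independent cross-check against scikit-image (symmetric mode).

    skimage's diagonal displacement signs mirror the row-downward
    convention used here, so its pi/4 matches this 135 degrees and vice
    versa; symmetric accumulation makes the matched pairs identical.
    """
    from skimage.feature import graycomatrix

    levels = rng.integers(0, 8, (32, 32))
    q = QuantizedImage(levels, 8)
    pairing = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
    for angle, sk_angle in pairing.items():
        mine = compute_glcm(q, OffsetSpec(angle, 1), symmetric=True).matrix
        theirs = graycomatrix(
            levels.astype(np.uint8), [1], [sk_angle], levels=8, symmetric=True
        )[:, :, 0, 0]
        np.testing.assert_array_equal(mine, theirs)


# ---------------------------------------------------------- normalization


def test_normalize_examples():
    for counts, want in [
        ([[1, 0], [0, 1]], [[0.5, 0], [0, 0.5]]),
        ([[0, 1], [1, 0]], [[0, 0.5], [0.5, 0]]),
    ]:
        g = GLCM(np.array(counts, float), "counts", OffsetSpec(0))
        np.testing.assert_allclose(normalize_glcm(g).matrix, want)


def test_normalize_zero_total_rejected():
    g = GLCM(np.zeros((2, 2)), "counts", OffsetSpec(0))
    with pytest.raises(ValueError):
        normalize_glcm(g)


def test_normalize_sums_to_one(rng):
    counts = rng.integers(0, 50, (8, 8)).astype(float)
    counts[0, 0] += 1  # guarantee nonzero
    g = GLCM(counts, "counts", OffsetSpec(45))
    assert abs(normalize_glcm(g).matrix.sum() - 1.0) < 1e-9


# ------------------------------------------------------ haralick_features


@pytest.mark.parametrize(
    "p, expected",
    [
        (
            [[0.5, 0], [0, 0.5]],
            dict(contrast=0, correlation=1, energy=0.5, homogeneity=1,
                 entropy=math.log(2)),
        ),
        (
            [[0, 0.5], [0.5, 0]],
            dict(contrast=1, correlation=-1, energy=0.5, homogeneity=0.5,
                 entropy=math.log(2)),
        ),
    ],
)
def test_haralick_closed_forms(p, expected):
    g = GLCM(np.array(p), "probabilities", OffsetSpec(0))
    f = haralick_features(g)
    for name, want in expected.items():
        assert f[name] == pytest.approx(want, abs=1e-15)


def test_haralick_single_entry_matrix():
    """A constant image: all mass on one entry."""
    p = np.zeros((4, 4))
    p[2, 2] = 1.0
    f = haralick_features(GLCM(p, "probabilities", OffsetSpec(0)))
    assert f.contrast == 0
    assert f.energy == 1
    assert f.homogeneity == 1
    assert f.entropy == 0
    assert math.isnan(f.correlation)


def test_haralick_matches_naive_loops(rng):
    for _ in range(25):
        p = rng.random((8, 8))
        p /= p.sum()
        f = haralick_features(GLCM(p, "probabilities", OffsetSpec(0)))
        want = naive_features(p)
        for name, w in want.items():
            got = f[name]
            if math.isnan(w):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(w, abs=1e-12)


def test_haralick_rejects_counts_matrix():
    g = GLCM(np.ones((2, 2)), "counts", OffsetSpec(0))
    with pytest.raises(ValueError):
        haralick_features(g)


def test_entropy_base_two():
    p = np.full((2, 2), 0.25)
    f = haralick_features(GLCM(p, "probabilities", OffsetSpec(0)), entropy_base=2)
    assert f.entropy == pytest.approx(2.0)


# -------------------------------------------------------------- summaries


def test_summary_constant_image():
    s = directional_summary(GreyImage(np.full((8, 8), 3.7)))
    assert s.mean("contrast") == 0 and s.std("contrast") == 0
    assert s.mean("energy") == 1 and s.mean("homogeneity") == 1
    assert s.mean("entropy") == 0
    assert math.isnan(s.mean("correlation"))


def test_summary_vertical_stripes_anisotropy():
    """Uniform vertical stripes: horizontal pairs differ, vertical agree."""
    img = GreyImage(np.tile(np.array([0.0, 1.0] * 8), (16, 1)))
    s = directional_summary(img, n_levels=2)
    f0 = s.per_offset[0].contrast
    f90 = s.per_offset[90].contrast
    assert f0 > f90
    assert s.std("contrast") > 0


def test_summary_matches_per_offset_brute_force(rng):
    img = GreyImage(rng.integers(0, 256, (20, 20)).astype(float))
    s = directional_summary(img, n_levels=8)
    q = quantize(img, 8)
    vals = []
    for angle in ANGLES:
        dr, dc = OffsetSpec(angle, 1).displacement
        counts = brute_force_glcm(q.levels, 8, dr, dc)
        vals.append(naive_features(counts / counts.sum())["contrast"])
    assert s.mean("contrast") == pytest.approx(np.mean(vals), abs=1e-12)
    assert s.std("contrast") == pytest.approx(np.std(vals), abs=1e-12)


def test_summary_cell_formatting():
    s = directional_summary(GreyImage(np.full((4, 4), 1.0)))
    assert s.format_cell("contrast") == "0.000 ± 0.000"
    assert " ± " in s.format_cell("energy")
    assert s.format_cell("correlation") == "undefined"


def test_summary_names_offending_offset():
    img = GreyImage(np.zeros((1, 8)))  # no vertical or diagonal pairs
    with pytest.raises(EmptyGLCMError, match="45"):
        directional_summary(img)


# --------------------------------------------------------------- properties


@st.composite
def quantized_images(draw):
    L = draw(st.sampled_from([2, 4, 8]))
    H = draw(st.integers(3, 12))
    W = draw(st.integers(3, 12))
    seed = draw(st.integers(0, 2**31 - 1))
    levels = np.random.default_rng(seed).integers(0, L, (H, W))
    return QuantizedImage(levels, L)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(quantized_images(), st.sampled_from(ANGLES))
def test_property_grey_level_reversal_invariance(q, angle):
    """Reversing grey levels (i -> L-1-i) leaves the statistics unchanged."""
    rev = QuantizedImage(q.n_levels - 1 - q.levels, q.n_levels)
    f1 = haralick_features(normalize_glcm(compute_glcm(q, OffsetSpec(angle))))
    f2 = haralick_features(normalize_glcm(compute_glcm(rev, OffsetSpec(angle))))
    for name in ("contrast", "energy", "homogeneity", "entropy"):
        assert f1[name] == pytest.approx(f2[name], abs=1e-12)
    if not math.isnan(f1.correlation):
        assert f1.correlation == pytest.approx(f2.correlation, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(quantized_images(), st.sampled_from(ANGLES))
def test_property_symmetric_glcm_is_symmetric(q, angle):
    g = compute_glcm(q, OffsetSpec(angle), symmetric=True)
    np.testing.assert_array_equal(g.matrix, g.matrix.T)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(quantized_images(), st.sampled_from(ANGLES))
def test_property_feature_ranges(q, angle):
    P = normalize_glcm(compute_glcm(q, OffsetSpec(angle)))
    assert abs(P.matrix.sum() - 1.0) < 1e-9
    f = haralick_features(P)
    L = q.n_levels
    assert f.contrast >= 0
    assert 0 < f.energy <= 1
    assert 0 < f.homogeneity <= 1
    assert 0 <= f.entropy <= 2 * math.log(L) + 1e-12
    if not math.isnan(f.correlation):
        assert -1 - 1e-9 <= f.correlation <= 1 + 1e-9
    # energy == 1 iff exactly one nonzero entry
    assert (f.energy == 1) == (np.count_nonzero(P.matrix) == 1)
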