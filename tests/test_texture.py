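"""LBP riu2 / VAR operators, quantization and element features."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from skimage.feature import local_binary_pattern

from slidequant.texture import (DEFAULT_SCALES, FEATURE_LENGTH, VarQuantizer,
                                enumerate_elements, extract_element_feature,
                                lbp_riu2, preprocess, train_var_quantizer,
                                var_local)


def _interior(arr, R):
    b = int(np.ceil(R))
    return arr[b:-b, b:-b]


@pytest.fixture(scope="module")
def random_gray():
    return np.random.default_rng(0).integers(0, 256, (60, 60)).astype(np.uint8)


@pytest.fixture(scope="module")
def simple_quantizers(random_gray):
    return {(p, r): train_var_quantizer([random_gray], p, r)
            for (p, r) in DEFAULT_SCALES}


# ---------------------------------------------------------------- preprocess

def test_preprocess_halves_and_masks_background():
    white = np.full((400, 400, 3), 255, dtype=np.uint8)
    gray, tissue = preprocess(white)
    assert gray.shape == (200, 200)
    assert not tissue.any()


def test_grayscale_weights_on_pure_red():
    red = np.zeros((64, 64, 3), dtype=np.uint8)
    red[..., 0] = 255
    gray, _ = preprocess(red)
    assert np.all(gray == round(0.2989 * 255))


# ----------------------------------------------------------------- LBP riu2

def test_constant_image_gives_all_ones_code():
    """Ties (neighbour == centre) count as 1, so a flat image yields the
    all-ones pattern with bit count P."""
    img = np.full((20, 20), 57, dtype=np.uint8)
    for P, R in DEFAULT_SCALES:
        codes = lbp_riu2(img, P, R)
        assert np.all(_interior(codes, R) == P)


def test_bright_centre_on_dark_field_codes_zero():
    img = np.zeros((9, 9), dtype=np.uint8)
    img[4, 4] = 200
    codes = lbp_riu2(img, 8, 1)
    assert codes[4, 4] == 0


def test_code_alphabet_bounded(random_gray):
    codes = lbp_riu2(random_gray, 8, 1)
    assert codes.min() >= 0 and codes.max() <= 9
    assert len(np.unique(codes)) <= 10


def test_codes_match_reference_uniform_lbp(random_gray):
    """Cross-check riu2 codes against an independent implementation.

    Rotation-invariant uniform codes do not depend on the angular
    origin or direction of sampling, so both implementations must agree
    wherever neither touches the image border.
    """
    for P, R in DEFAULT_SCALES:
        ours = lbp_riu2(random_gray, P, R)
        ref = local_binary_pattern(random_gray, P, R, method="uniform")
        assert np.array_equal(_interior(ours, R), _interior(ref, R))


def test_lbp_invariant_to_constant_shift(random_gray):
    img = np.clip(random_gray, 0, 205)
    shifted = (img + 50).astype(np.uint8)
    for P, R in DEFAULT_SCALES:
        assert np.array_equal(lbp_riu2(img, P, R), lbp_riu2(shifted, P, R))


def test_lbp_rejects_too_small_images():
    with pytest.raises(ValueError):
        lbp_riu2(np.zeros((3, 3), dtype=np.uint8), 16, 2)


# ---------------------------------------------------------------------- VAR

def test_var_zero_on_constant_image():
    img = np.full((16, 16), 123, dtype=np.uint8)
    for P, R in DEFAULT_SCALES:
        assert np.allclose(_interior(var_local(img, P, R), R), 0.0)


def test_var_against_independent_sampler(random_gray):
    """Population variance of the circular samples, cross-checked with
    an interpolating sampler built on scipy."""
    P, R = 8, 1
    ours = var_local(random_gray, P, R)
    h, w = random_gray.shape
    rows, cols = np.mgrid[2:h - 2, 2:w - 2]
    samples = []
    for k in range(P):
        angle = 2 * np.pi * k / P
        dr, dc = -R * np.sin(angle), R * np.cos(angle)
        samples.append(map_coordinates(random_gray.astype(float),
                                       [rows + dr, cols + dc], order=1))
    oracle = np.var(np.stack(samples), axis=0)
    assert np.allclose(ours[2:h - 2, 2:w - 2], oracle, atol=1e-9)


def test_var_half_split_neighbourhood_value():
    """P samples split half dark / half bright have variance (range/2)^2."""
    # vertical stripes 0/255 of width 1: at P=4, R=1 the four samples are
    # two 0s and two 255s
    img = np.zeros((12, 12), dtype=np.uint8)
    img[:, 1::2] = 255
    v = var_local(img, 4, 1)
    assert v[5, 5] == pytest.approx(127.5 ** 2)


def test_var_equivariant_under_quarter_rotation(random_gray):
    """VAR is rotation invariant: rotating the image rotates the map."""
    for P, R in DEFAULT_SCALES:
        rotated = var_local(np.rot90(random_gray), P, R)
        expected = np.rot90(var_local(random_gray, P, R))
        b = int(np.ceil(R))
        assert np.allclose(rotated[b:-b, b:-b], expected[b:-b, b:-b],
                           atol=1e-8)


# --------------------------------------------------------------- quantizers

def test_quantizer_equal_occupancy_on_training_pool(random_gray):
    quant = train_var_quantizer([random_gray], 8, 1, Q=8)
    var = var_local(random_gray, 8, 1)[1:-1, 1:-1].ravel()
    bins = quant.assign(var)
    counts = np.bincount(bins, minlength=8)
    assert counts.min() >= 0.8 * var.size / 8
    assert counts.max() <= 1.2 * var.size / 8


def test_two_level_quantizer_cut_is_median(random_gray):
    quant = train_var_quantizer([random_gray], 8, 1, Q=2)
    var = var_local(random_gray, 8, 1)[1:-1, 1:-1]
    assert quant.cut_points[0] == pytest.approx(np.median(var))


def test_quantizer_bins_are_right_open():
    quant = VarQuantizer(np.array([1.0, 2.0, 3.0]))
    assert list(quant.assign(np.array([0.5, 1.0, 2.9, 3.0, 99.0]))) == \
        [0, 1, 2, 3, 3]


def test_degenerate_training_pool_rejected():
    flat = np.full((30, 30), 99, dtype=np.uint8)
    with pytest.raises(ValueError):
        train_var_quantizer([flat], 8, 1)


# ----------------------------------------------------------------- features

def test_feature_vector_geometry(random_gray, simple_quantizers):
    feat = extract_element_feature(random_gray[:40, :40], simple_quantizers)
    assert feat.vector.shape == (FEATURE_LENGTH,)
    assert FEATURE_LENGTH == 224
    assert np.linalg.norm(feat.vector) == pytest.approx(1.0, abs=1e-9)
    assert np.all(feat.vector >= 0)


def test_histogram_counts_conserved(random_gray, simple_quantizers):
    """Unnormalized joint histograms sum to the valid pixel count."""
    element = random_gray[:40, :40]
    raw = extract_element_feature(element, simple_quantizers,
                                  normalize=False).vector
    assert raw[:80].sum() == 38 * 38    # (8,1): border 1
    assert raw[80:].sum() == 36 * 36    # (16,2): border 2


def test_constant_element_concentrates_in_flat_cells(simple_quantizers):
    flat = np.full((80, 80), 130, dtype=np.uint8)
    feat = extract_element_feature(flat, simple_quantizers)
    # (code P, var bin 0) cells: index 8*8 = 64 in block 1 and
    # 80 + 16*8 = 208 in block 2
    assert feat.vector[64] > 0.5
    assert feat.vector[208] > 0.5
    assert feat.vector[64] ** 2 + feat.vector[208] ** 2 == pytest.approx(1.0)


# ----------------------------------------------------------------- elements

def test_element_grid_geometry():
    gray = np.zeros((168, 168), dtype=np.uint8)
    tissue = np.ones_like(gray, dtype=bool)
    assert len(enumerate_elements(gray, tissue)) == 9
    assert len(enumerate_elements(gray, np.zeros_like(tissue))) == 0


def test_element_tissue_coverage_threshold():
    gray = np.zeros((80, 80), dtype=np.uint8)
    tissue = np.zeros_like(gray, dtype=bool)
    tissue.flat[:3135] = True   # 48.98% -> excluded
    assert enumerate_elements(gray, tissue) == []
    tissue.flat[:3200] = True   # exactly 50% -> included
    assert enumerate_elements(gray, tissue) == [(0, 0)]
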