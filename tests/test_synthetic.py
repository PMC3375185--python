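"""Synthetic scene generators: determinism, ground truth, separability."""

import hashlib

import numpy as np
import pytest
from PIL import Image

from slidequant.ihc import color_deconvolve, threshold_masks
from slidequant.synthetic import (IhcSceneParams, TextureSceneParams,
                                  generate_dataset, generate_ihc_core,
                                  generate_texture_image, texture_params)
from slidequant.texture import preprocess


def _digest(arr):
    return hashlib.sha256(np.ascontiguousarray(arr)).hexdigest()


def test_ihc_core_deterministic_for_fixed_seed():
    p = IhcSceneParams(seed=7, n_nuclei=200, positive_fraction=0.30)
    img1, gt1 = generate_ihc_core(p)
    img2, gt2 = generate_ihc_core(p)
    assert _digest(img1) == _digest(img2)
    assert gt1.true_extent == gt2.true_extent
    img3, _ = generate_ihc_core(IhcSceneParams(seed=8, n_nuclei=200,
                                               positive_fraction=0.30))
    assert _digest(img1) != _digest(img3)


def test_binomial_positivity_lands_near_requested_fraction():
    """Per-nucleus positivity is Bernoulli, so the planted pixel share
    scatters around the requested fraction (slightly above it, because
    a pixel shared by a positive and a negative nucleus carries DAB)."""
    extents = [generate_ihc_core(IhcSceneParams(seed=s,
                                                positive_fraction=0.30))[1]
               .true_extent for s in range(7, 12)]
    assert all(0.2 <= e <= 0.45 for e in extents)
    assert abs(np.mean(extents) - 0.33) <= 0.06


@pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 1.0)])
def test_extreme_positive_fractions(fraction, expected):
    image, gt = generate_ihc_core(IhcSceneParams(seed=3,
                                                 positive_fraction=fraction))
    assert gt.true_extent == expected
    if fraction == 0.0:
        assert not gt.positive_mask.any()
        # no DAB-positive pixels appear after deconvolution either
        _, dab_mask = threshold_masks(color_deconvolve(image))
        assert dab_mask.mean() < 0.01


def test_positive_mask_subset_of_nucleus_mask():
    _, gt = generate_ihc_core(IhcSceneParams(seed=11, positive_fraction=0.5))
    assert not (gt.positive_mask & ~gt.nucleus_mask).any()
    assert gt.true_extent == pytest.approx(
        gt.positive_mask.sum() / gt.nucleus_mask.sum())


def test_invalid_scene_parameters_rejected():
    with pytest.raises(ValueError):
        IhcSceneParams(positive_fraction=1.2)
    with pytest.raises(ValueError):
        IhcSceneParams(width=32)
    with pytest.raises(ValueError):
        IhcSceneParams(n_nuclei=0)
    with pytest.raises(ValueError):
        IhcSceneParams(width=64, height=64, nucleus_radius_range=(20, 40))
    with pytest.raises(ValueError):
        TextureSceneParams(width=100)
    with pytest.raises(ValueError):
        TextureSceneParams(class_label="muscle")
    with pytest.raises(ValueError):
        TextureSceneParams(other_mix=0.8)


def test_texture_determinism_and_class_contrast():
    p_epi = TextureSceneParams(class_label="epithelium", seed=5)
    p_str = TextureSceneParams(class_label="stroma", seed=5)
    img1, lab1 = generate_texture_image(p_epi)
    img2, _ = generate_texture_image(p_epi)
    img3, lab3 = generate_texture_image(p_str)
    assert _digest(img1) == _digest(img2)
    assert _digest(img1) != _digest(img3)
    assert (lab1, lab3) == ("epithelium", "stroma")


def test_texture_scene_has_bright_glass_border_and_tissue():
    img, _ = generate_texture_image(TextureSceneParams(seed=2))
    gray, tissue = preprocess(img)
    assert 0.5 < tissue.mean() < 1.0


def test_texture_classes_are_separable_in_feature_space():
    """Class centroids are farther apart than within-class spread
    (positive silhouette) for the LBP+VAR element features."""
    from sklearn.metrics import silhouette_score
    from slidequant.segmentation import image_features
    from slidequant.texture import DEFAULT_SCALES, train_var_quantizer

    params = texture_params(6, base_seed=77, size_range=(240, 280),
                             mix_range=(0.0, 0.0))
    images = [generate_texture_image(p)[0] for p in params]
    labels = [p.class_label for p in params]
    pre = [preprocess(img) for img in images]
    quantizers = {(p, r): train_var_quantizer([g for g, _ in pre], p, r,
                                              tissue_masks=[m for _, m in pre])
                  for (p, r) in DEFAULT_SCALES}
    feats, feat_labels = [], []
    for img, lab in zip(images, labels):
        f = image_features(img, quantizers)
        feats.append(f)
        feat_labels += [lab] * len(f)
    score = silhouette_score(np.vstack(feats), feat_labels)
    assert score > 0


def test_generate_dataset_writes_manifest_and_pngs(tmp_path):
    manifest = generate_dataset(5, base_seed=21, kind="ihc",
                                out_dir=tmp_path / "d1")
    assert len(manifest) == 5
    assert (tmp_path / "d1" / "manifest.csv").exists()
    for name in manifest["file"]:
        img = np.asarray(Image.open(tmp_path / "d1" / name))
        assert img.dtype == np.uint8 and img.shape[2] == 3
    # sweep covers a wide range of planted extents
    assert manifest["true_extent"].min() < 0.15
    assert manifest["true_extent"].max() > 0.85


def test_generate_dataset_reproducible_byte_identical(tmp_path):
    generate_dataset(3, base_seed=9, kind="texture", out_dir=tmp_path / "a")
    generate_dataset(3, base_seed=9, kind="texture", out_dir=tmp_path / "b")
    for name in ["texture_0000.png", "texture_0005.png"]:
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_generate_dataset_refuses_silent_overwrite(tmp_path):
    generate_dataset(2, base_seed=1, kind="ihc", out_dir=tmp_path)
    with pytest.raises(FileExistsError):
        generate_dataset(2, base_seed=1, kind="ihc", out_dir=tmp_path)
    generate_dataset(2, base_seed=1, kind="ihc", out_dir=tmp_path,
                     overwrite=True)


def test_texture_collection_is_stratified():
    params = texture_params(8, base_seed=4)
    epi = [p for p in params if p.class_label == "epithelium"]
    stroma = [p for p in params if p.class_label == "stroma"]
    assert len(epi) == len(stroma) == 8
    for group in (epi, stroma):
        factors = sorted(p.size_factor for p in group)
        assert factors[0] == pytest.approx(0.9)
        assert factors[-1] == pytest.approx(1.1)
        assert all(168 <= p.width <= 1191 for p in group)
    # annotation composition: epithelium spans the admixture range,
    # stroma stays much purer
    assert max(p.other_mix for p in epi) == pytest.approx(0.38)
    assert max(p.other_mix for p in stroma) < 0.15
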