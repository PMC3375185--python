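import numpy as np
import pytest

from slidequant.synthetic import (IhcSceneParams, TextureSceneParams,
                                  generate_ihc_core, generate_texture_image,
                                  texture_params)
from slidequant.segmentation import fit_segmenter


@pytest.fixture(scope="session")
def ihc_core():
    """One default synthetic core with its ground truth."""
    return generate_ihc_core(IhcSceneParams(seed=7))


@pytest.fixture(scope="session")
def noise_free_core():
    return generate_ihc_core(IhcSceneParams(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def texture_pair():
    """One epithelium and one stroma scene at the same seed."""
    epi, _ = generate_texture_image(
        TextureSceneParams(class_label="epithelium", seed=3))
    stroma, _ = generate_texture_image(
        TextureSceneParams(class_label="stroma", seed=3))
    return epi, stroma


@pytest.fixture(scope="session")
def small_segmenter():
    """A segmenter trained on a small pure-texture split, with its
    training parameters for reuse."""
    params = texture_params(10, base_seed=210, size_range=(240, 320),
                             mix_range=(0.0, 0.0))
    images, labels = [], []
    for p in params:
        img, lab = generate_texture_image(p)
        images.append(img)
        labels.append(lab)
    model, quantizers = fit_segmenter(images, labels)
    return model, quantizers, images, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
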