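"""Synthetic histology-like images with known ground truth.

Real tissue-microarray scans behind the study designs in this package
are not publicly packaged, so every downstream stage is exercised on
synthetic stand-ins:

* **IHC cores** — bright background with elliptical nuclei; every
  nucleus carries haematoxylin and a Bernoulli-chosen subset
  additionally carries DAB.  Colours are produced by the Beer–Lambert
  forward model ``RGB = 255 * 10**(-OD · stain_vector)`` with the same
  H-DAB stain vectors the deconvolution module inverts, so colour
  deconvolution can in principle recover the planted masks exactly.
  The planted positive-pixel fraction is returned as ground truth.

* **Texture scenes** — two classes mimicking tumor epithelium
  (densely packed rounded blobs) and stroma (elongated oriented
  fibres) on a bright tissue matrix, at the annotation sizes of the
  study design (168–1191 px per side).

All outputs are pure functions of their parameters, including the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from .ihc import StainVectors

__all__ = [
    "IhcSceneParams",
    "TextureSceneParams",
    "GroundTruth",
    "EPITHELIUM",
    "STROMA",
    "generate_ihc_core",
    "generate_texture_image",
    "generate_dataset",
    "sweep_ihc_params",
    "texture_params",
]

EPITHELIUM = "epithelium"
STROMA = "stroma"

MANIFEST_COLUMNS = ["file", "seed", "kind", "width", "height",
                    "true_extent", "class_label"]


@dataclass(frozen=True)
class IhcSceneParams:
    """Parameters of one synthetic IHC core.

    ``dab_od`` and ``hem_od`` are peak optical densities per nucleus;
    with the defaults a haematoxylin-only nucleus renders around
    transmittance ``255 * 10**-0.65 ≈ 57`` in the H channel.
    ``noise_sd`` is additive Gaussian noise in 8-bit units, applied
    after the Beer–Lambert forward model.
    """

    width: int = 640
    height: int = 640
    n_nuclei: int = 225
    positive_fraction: float = 0.3
    nucleus_radius_range: tuple[int, int] = (11, 16)
    dab_od: float = 0.9
    hem_od: float = 0.65
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.width < 64 or self.height < 64:
            raise ValueError("width and height must be >= 64")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.nucleus_radius_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid nucleus_radius_range")
        if 2 * hi >= min(self.width, self.height):
            raise ValueError("image too small to hold one nucleus")
        if self.dab_od <= 0 or self.hem_od <= 0:
            raise ValueError("stain optical densities must be > 0")


@dataclass(frozen=True)
class TextureSceneParams:
    """Parameters of one synthetic texture annotation.

    ``density`` is the expected number of texture elements (blobs or
    fibres) per 10⁴ pixels; ``background_level`` is the 8-bit gray of
    empty glass, rendered as a thin border around the tissue.
    """

    width: int = 320
    height: int = 320
    class_label: str = EPITHELIUM
    background_level: int = 248
    density: float = 12.0
    size_factor: float = 1.0
    other_mix: float = 0.0
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in (EPITHELIUM, STROMA):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if not 168 <= self.width <= 1191 or not 168 <= self.height <= 1191:
            raise ValueError("width and height must be within [168, 1191]")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not 0.3 <= self.size_factor <= 3.0:
            raise ValueError("size_factor must be in [0.3, 3.0]")
        if not 0.0 <= self.other_mix <= 0.5:
            raise ValueError("other_mix must be in [0, 0.5]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted masks and the positive-pixel share of all nuclear pixels."""

    true_extent: float
    nucleus_mask: np.ndarray
    positive_mask: np.ndarray


def generate_ihc_core(params: IhcSceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic IHC core and its ground truth.

    Nuclei are random ellipses; overlaps are resolved by taking the
    maximum optical density per stain, which keeps the planted masks
    well defined.  Positivity is assigned per nucleus (Bernoulli with
    ``positive_fraction``), mirroring a nuclear proliferation marker.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    hem_od = np.zeros((h, w))
    dab_od = np.zeros((h, w))
    nucleus_mask = np.zeros((h, w), dtype=bool)
    positive_mask = np.zeros((h, w), dtype=bool)
    lo, hi = params.nucleus_radius_range

    is_positive = rng.random(params.n_nuclei) < params.positive_fraction
    for i in range(params.n_nuclei):
        r = rng.uniform(hi, h - hi)
        c = rng.uniform(hi, w - hi)
        r_radius = rng.uniform(lo, hi)
        c_radius = rng.uniform(lo, hi)
        angle = rng.uniform(0, np.pi)
        jitter = rng.uniform(0.85, 1.15)
        rr, cc = ellipse(r, c, r_radius, c_radius, shape=(h, w),
                         rotation=angle)
        nucleus_mask[rr, cc] = True
        np.maximum.at(hem_od, (rr, cc), params.hem_od * jitter)
        if is_positive[i]:
            positive_mask[rr, cc] = True
            np.maximum.at(dab_od, (rr, cc), params.dab_od * jitter)

    vectors = StainVectors.h_dab().matrix
    od_rgb = hem_od[..., None] * vectors[0] + dab_od[..., None] * vectors[1]
    rgb = 255.0 * 10.0 ** (-od_rgb)
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, rgb.shape)
    image = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    n_nuc = int(np.count_nonzero(nucleus_mask))
    n_pos = int(np.count_nonzero(positive_mask))
    true_extent = n_pos / n_nuc if n_nuc else 0.0
    return image, GroundTruth(true_extent=true_extent,
                              nucleus_mask=nucleus_mask,
                              positive_mask=positive_mask)


def _tint(intensity: np.ndarray, rgb_weights: tuple[float, float, float]
          ) -> np.ndarray:
    """Map a grayscale field to a softly tinted RGB image."""
    out = np.stack([intensity * wt for wt in rgb_weights], axis=-1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


MIX_BLOCK = 80  # full-scale block size used for mixed-composition scenes


def _render_class(rng: np.random.Generator, h: int, w: int, label: str,
                  n_elements: int, size_factor: float) -> np.ndarray:
    """Draw one class's texture onto a mottled pale tissue matrix.

    Epithelium: rounded dark blobs; stroma: thin elongated fibres with
    a coherent orientation.  ``size_factor`` scales element size, the
    per-image texture-fineness knob.  The matrix carries smooth
    mid-frequency mottling, as out-of-plane tissue does in brightfield
    scans; it keeps the background's local variance well away from the
    quantizer's lowest bins, so codec-level pixel noise cannot move
    large histogram mass.
    """
    if label == EPITHELIUM:
        canvas = np.full((h, w), 215.0)
        for _ in range(n_elements):
            r = rng.uniform(0, h)
            c = rng.uniform(0, w)
            rad_r = rng.uniform(5.8, 14.8) * size_factor
            rad_c = rad_r * rng.uniform(0.8, 1.25)
            level = rng.uniform(40, 110)
            rr, cc = ellipse(r, c, rad_r, rad_c, shape=(h, w),
                             rotation=rng.uniform(0, np.pi))
            np.minimum.at(canvas, (rr, cc), level)
    else:
        canvas = np.full((h, w), 210.0)
        base_angle = rng.uniform(0, np.pi)
        for _ in range(n_elements):
            r = rng.uniform(0, h)
            c = rng.uniform(0, w)
            length = rng.uniform(25, 70)
            angle = base_angle + rng.normal(0, 0.35)
            half_width = rng.uniform(1.4, 3.2) * size_factor
            level = rng.uniform(90, 150)
            rr, cc = ellipse(r, c, half_width, length / 2.0, shape=(h, w),
                             rotation=angle)
            np.minimum.at(canvas, (rr, cc), level)
    mottle = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.5)
    canvas += mottle * (10.0 / mottle.std())
    return canvas


def generate_texture_image(params: TextureSceneParams
                           ) -> tuple[np.ndarray, str]:
    """Render one two-class texture scene.

    Epithelium is rendered as densely packed rounded dark blobs on a
    pale matrix; stroma as thin elongated fibres with a coherent
    orientation field.  Both sit inside a thin bright-glass border so
    the background-removal step has something to remove.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    density_factor = rng.uniform(0.7, 1.4)
    n_elements = int(params.density * density_factor * h * w / 1e4)
    canvas = _render_class(rng, h, w, params.class_label, n_elements,
                           params.size_factor)
    if params.other_mix > 0:
        # mixed tissue composition: a fraction of 80-px blocks carries
        # the opposite texture, as real annotations are rarely pure
        other = (STROMA if params.class_label == EPITHELIUM else EPITHELIUM)
        other_canvas = _render_class(rng, h, w, other, n_elements,
                                     params.size_factor)
        bh = -(-h // MIX_BLOCK)
        bw = -(-w // MIX_BLOCK)
        n_other = int(round(params.other_mix * bh * bw))
        chosen = rng.choice(bh * bw, size=n_other, replace=False)
        block_mask = np.zeros(bh * bw, dtype=bool)
        block_mask[chosen] = True
        pixel_mask = np.repeat(np.repeat(block_mask.reshape(bh, bw),
                                         MIX_BLOCK, axis=0),
                               MIX_BLOCK, axis=1)[:h, :w]
        canvas = np.where(pixel_mask, other_canvas, canvas)

    canvas += rng.normal(0.0, params.noise_sd, canvas.shape)

    # thin glass border so a background region exists
    border = max(4, min(h, w) // 40)
    glass = np.ones((h, w), dtype=bool)
    glass[border:h - border, border:w - border] = False
    canvas[glass] = params.background_level + rng.normal(0.0, 1.0,
                                                         int(glass.sum()))
    image = _tint(canvas, (1.08, 0.96, 1.02))
    return image, params.class_label


def sweep_ihc_params(n: int, base_seed: int) -> list[IhcSceneParams]:
    """IHC cores with positive fractions swept evenly across (0, 1)."""
    sweep_rng = np.random.default_rng(base_seed)
    fractions = np.linspace(0.05, 0.95, n)
    sweep_rng.shuffle(fractions)
    return [IhcSceneParams(positive_fraction=float(fractions[i]),
                           seed=base_seed + i)
            for i in range(n)]


def texture_params(n_per_class: int, base_seed: int,
                    size_range: tuple[int, int] = (240, 420),
                    fineness_range: tuple[float, float] = (0.9, 1.1),
                    mix_range: tuple[float, float] = (0.0, 0.38),
                    ) -> list[TextureSceneParams]:
    """Texture scenes with fineness and composition stratified.

    Per class, ``size_factor`` (texture fineness) and ``other_mix``
    (opposite-texture admixture) are evenly spaced over their ranges
    and shuffled independently, so any split of the collection spans
    the whole difficulty spectrum rather than depending on an i.i.d.
    draw.  Use ``mix_range=(0, 0)`` for texture-pure exemplars, e.g. a
    training split.  ``mix_range`` applies to epithelium; stroma
    annotations are kept much purer (a third of the range), as stromal
    regions are the easier tissue to delineate.
    """
    rng = np.random.default_rng(base_seed)
    out = []
    for label in (EPITHELIUM, STROMA):
        factors = np.linspace(fineness_range[0], fineness_range[1],
                              n_per_class)
        hi = mix_range[1] if label == EPITHELIUM else mix_range[1] / 3.0
        mixes = np.linspace(mix_range[0], hi, n_per_class)
        rng.shuffle(factors)
        rng.shuffle(mixes)
        for j in range(n_per_class):
            width = int(rng.integers(size_range[0], size_range[1] + 1))
            height = int(rng.integers(size_range[0], size_range[1] + 1))
            out.append(TextureSceneParams(
                width=width, height=height, class_label=label,
                size_factor=float(factors[j]), other_mix=float(mixes[j]),
                seed=base_seed + 1000 + len(out)))
    return out


def generate_dataset(n_per_condition: int, base_seed: int, kind: str,
                     out_dir: str | os.PathLike,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write a reproducible synthetic dataset as PNGs plus a CSV manifest.

    For ``kind='ihc'`` the planted positive fraction is swept evenly
    over (0, 1) across the ``n_per_condition`` cores; for
    ``kind='texture'`` both classes are generated ``n_per_condition``
    times at random annotation sizes.  Refuses to overwrite an existing
    manifest unless ``overwrite`` is set.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if kind not in ("ihc", "texture"):
        raise ValueError(f"kind must be 'ihc' or 'texture', got {kind!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it")

    rows = []
    if kind == "ihc":
        for i, params in enumerate(sweep_ihc_params(n_per_condition,
                                                     base_seed)):
            image, truth = generate_ihc_core(params)
            name = f"ihc_{i:04d}.png"
            Image.fromarray(image).save(out_dir / name)
            rows.append({"file": name, "seed": params.seed, "kind": kind,
                         "width": params.width, "height": params.height,
                         "true_extent": truth.true_extent,
                         "class_label": ""})
    else:
        for i, params in enumerate(texture_params(n_per_condition,
                                                   base_seed)):
            image, label = generate_texture_image(params)
            name = f"texture_{i:04d}.png"
            Image.fromarray(image).save(out_dir / name)
            rows.append({"file": name, "seed": params.seed, "kind": kind,
                         "width": params.width, "height": params.height,
                         "true_extent": np.nan, "class_label": label})

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return manifest
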