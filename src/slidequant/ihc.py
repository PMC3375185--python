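"""Automated scoring of immunohistochemical stainings.

Implements an area-based DAB/haematoxylin scorer for brightfield IHC
images: colour deconvolution into per-stain transmittance channels,
global thresholding into binary stain masks, a pseudocoloured result
image, and the two summary statistics — extent of staining (share of
stained tissue that is DAB-positive) and mean DAB intensity on a 0–100%
scale.

The deconvolution follows the Beer–Lambert model: a pixel's optical
density ``OD = -log10(I/255)`` is a non-negative combination of unit
stain vectors, so stain concentrations are recovered by projecting OD
onto the inverse of the stain matrix.  Channels are re-expressed as
8-bit transmittance (255 = no stain, 0 = maximal stain), the convention
of the widely used ImageJ colour-deconvolution plugin, so "positive"
means *below* a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StainVectors",
    "ThresholdConfig",
    "StainChannels",
    "StainQuantResult",
    "DEFAULT_THRESHOLDS",
    "color_deconvolve",
    "threshold_masks",
    "merge_result_image",
    "staining_extent",
    "staining_intensity",
    "quantify",
]


# Ruifrok & Johnston H-DAB optical-density directions (R, G, B).
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.268, 0.570, 0.776)


@dataclass(frozen=True)
class StainVectors:
    """Unit-length optical-density directions for three stains.

    ``matrix`` rows are (haematoxylin, DAB, residual); each row has unit
    Euclidean norm and the matrix must be invertible.  The residual row
    of the built-in H-DAB matrix is the normalized cross product of the
    first two, which makes it orthogonal to both.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be non-zero")
        m = m / norms[:, None]
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def h_dab(cls) -> "StainVectors":
        """Built-in haematoxylin + DAB matrix (Ruifrok–Johnston values)."""
        h = np.array(_HEMATOXYLIN)
        d = np.array(_DAB)
        residual = np.cross(h, d)
        return cls(np.stack([h, d, residual]))


@dataclass(frozen=True)
class ThresholdConfig:
    """Global 8-bit threshold levels for the H and DAB channels.

    A pixel is stain-positive when its channel value is strictly below
    the threshold (channels are transmittance: darker = more stain).
    """

    h_threshold: int
    dab_threshold: int

    def __post_init__(self) -> None:
        for name, t in (("h_threshold", self.h_threshold),
                        ("dab_threshold", self.dab_threshold)):
            if not 0 <= t <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {t}")


# Frozen defaults, determined once on five synthetic calibration cores
# (see examples/calibrate_thresholds.py) and kept constant thereafter.
# Each threshold is the deconvolved channel value of a pixel exactly half
# covered by its stain (blending happens in transmittance, deconvolution
# in log space, so this differs from the channel-level midpoint): a pixel
# counts as positive when stain covers at least half of it, which keeps
# measured areas unbiased under resolution reduction.
DEFAULT_THRESHOLDS = ThresholdConfig(h_threshold=149, dab_threshold=151)


@dataclass(frozen=True)
class StainChannels:
    """Per-stain 8-bit transmittance rasters (255 = unstained)."""

    h_channel: np.ndarray
    dab_channel: np.ndarray


@dataclass(frozen=True)
class StainQuantResult:
    """Summary statistics of one scored IHC image."""

    extent: float
    intensity_pct: float
    n_dab_pixels: int
    n_h_only_pixels: int
    n_background_pixels: int


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit RGB image (H, W, 3) uint8, got shape "
            f"{image.shape} dtype {image.dtype}")
    return image


def color_deconvolve(image: np.ndarray,
                     vectors: StainVectors | None = None) -> StainChannels:
    """Unmix an RGB brightfield image into H and DAB channels.

    Per pixel the optical density ``-log10(max(I, 1)/255)`` is projected
    onto the inverse stain matrix; each stain concentration is mapped
    back to 8-bit transmittance ``255 * 10**(-conc)`` clipped to
    [0, 255].  A pure white pixel therefore maps to 255 in every
    channel.
    """
    image = _check_rgb8(image)
    if vectors is None:
        vectors = StainVectors.h_dab()
    od = -np.log10(np.maximum(image.astype(float), 1.0) / 255.0)
    conc = od @ vectors.inverse
    trans = np.clip(np.round(255.0 * 10.0 ** (-conc)), 0, 255).astype(np.uint8)
    return StainChannels(h_channel=trans[..., 0], dab_channel=trans[..., 1])


def threshold_masks(channels: StainChannels,
                    cfg: ThresholdConfig = DEFAULT_THRESHOLDS,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Binary stain masks: positive iff channel value < threshold.

    The H and DAB masks are independent and may overlap.
    """
    h_mask = channels.h_channel < cfg.h_threshold
    dab_mask = channels.dab_channel < cfg.dab_threshold
    return h_mask, dab_mask


def merge_result_image(h_mask: np.ndarray, dab_mask: np.ndarray) -> np.ndarray:
    """Pseudocoloured result image.

    DAB-positive pixels (regardless of H status) are red, H-positive
    DAB-negative pixels green, and the remaining background white.
    """
    h_mask = np.asarray(h_mask, dtype=bool)
    dab_mask = np.asarray(dab_mask, dtype=bool)
    if h_mask.shape != dab_mask.shape:
        raise ValueError("mask shapes differ")
    out = np.full(h_mask.shape + (3,), 255, dtype=np.uint8)
    out[h_mask & ~dab_mask] = (0, 255, 0)
    out[dab_mask] = (255, 0, 0)
    return out


def staining_extent(h_mask: np.ndarray, dab_mask: np.ndarray) -> float:
    """DAB-positive pixels over the union of H- and DAB-positive pixels.

    Returns 0.0 for a blank image (empty union).
    """
    h_mask = np.asarray(h_mask, dtype=bool)
    dab_mask = np.asarray(dab_mask, dtype=bool)
    if h_mask.shape != dab_mask.shape:
        raise ValueError("mask shapes differ")
    union = int(np.count_nonzero(h_mask | dab_mask))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(dab_mask)) / union


def staining_intensity(dab_mask: np.ndarray, dab_channel: np.ndarray,
                       dab_threshold: int = DEFAULT_THRESHOLDS.dab_threshold,
                       ) -> float:
    """Mean DAB intensity on the DAB-positive area, scaled to 0–100%.

    The scale is anchored at the DAB threshold so that results are
    comparable across threshold choices: a mean channel value equal to
    the threshold maps to 0% and maximal stain (channel value 0) to
    100%.  An empty mask yields 0%.
    """
    dab_mask = np.asarray(dab_mask, dtype=bool)
    if not dab_mask.any():
        return 0.0
    if dab_threshold <= 0:
        return 0.0
    mean_value = float(np.mean(dab_channel[dab_mask]))
    return 100.0 * (dab_threshold - mean_value) / dab_threshold


def quantify(image: np.ndarray,
             vectors: StainVectors | None = None,
             cfg: ThresholdConfig = DEFAULT_THRESHOLDS) -> StainQuantResult:
    """Score one IHC image: deconvolve, threshold, and summarise."""
    channels = color_deconvolve(image, vectors)
    h_mask, dab_mask = threshold_masks(channels, cfg)
    n_dab = int(np.count_nonzero(dab_mask))
    n_h_only = int(np.count_nonzero(h_mask & ~dab_mask))
    n_background = h_mask.size - n_dab - n_h_only
    return StainQuantResult(
        extent=staining_extent(h_mask, dab_mask),
        intensity_pct=staining_intensity(dab_mask, channels.dab_channel,
                                         cfg.dab_threshold),
        n_dab_pixels=n_dab,
        n_h_only_pixels=n_h_only,
        n_background_pixels=n_background,
    )
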