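"""Rotation-invariant LBP + local-variance texture features.

The local binary pattern operator (LBP) thresholds the P circularly
sampled neighbours of each pixel by the centre value and encodes the
sign pattern; the rotation-invariant uniform variant (riu2) maps each
*uniform* pattern (at most two 0/1 transitions around the circle) to
its number of set bits and all non-uniform patterns to a single extra
code, leaving P + 2 possible codes.  LBP is invariant to monotonic
gray-scale changes and discards contrast, so it is paired with the
rotation-invariant local variance (VAR) of the same circular samples.
VAR is quantized into Q equal-occupancy bins learned from training
images, and the joint (LBP, VAR) occurrence histogram — (P + 2) × Q
bins per scale — is the texture descriptor.

Feature extraction uses two scales, (P=8, R=1) and (P=16, R=2), over
80 × 80-pixel elements of the half-scale grayscale image, concatenated
to a (8+2)·8 + (16+2)·8 = 224-bin vector normalized to unit Euclidean
norm.

Neighbour sampling starts at offset (0, +R) and proceeds
counter-clockwise, with bilinear interpolation at non-integer
positions; ties (neighbour equal to centre) count as 1.  These
conventions do not affect riu2 codes but are fixed for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_erosion
from skimage.morphology import disk

from .codec import box_downscale

__all__ = [
    "LbpConfig",
    "VarQuantizer",
    "TextureFeature",
    "DEFAULT_SCALES",
    "GRAY_WEIGHTS",
    "preprocess",
    "lbp_riu2",
    "var_local",
    "train_var_quantizer",
    "extract_element_feature",
    "enumerate_elements",
    "FEATURE_LENGTH",
]

GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)
DEFAULT_SCALES = ((8, 1), (16, 2))
ELEMENT_SIZE = 80
ELEMENT_STEP = 40
VAR_LEVELS = 8
FEATURE_LENGTH = sum((p + 2) * VAR_LEVELS for p, _ in DEFAULT_SCALES)

BACKGROUND_GRAY_THRESHOLD = 240
MORPHOLOGY_RADIUS = 5


@dataclass(frozen=True)
class LbpConfig:
    """One (P, R) operator scale plus the VAR quantization depth Q."""

    P: int = 8
    R: float = 1.0
    Q: int = VAR_LEVELS

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError("P must be >= 4")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.Q < 2:
            raise ValueError("Q must be >= 2")

    @property
    def n_codes(self) -> int:
        return self.P + 2

    @property
    def histogram_size(self) -> int:
        return (self.P + 2) * self.Q


@dataclass(frozen=True)
class VarQuantizer:
    """Equal-occupancy quantizer for local-variance values.

    ``cut_points`` are the Q−1 ascending (k/Q)-quantiles of VAR pooled
    over training-image tissue pixels.  Bins are right-open
    ``[cut_{k-1}, cut_k)`` with the last bin unbounded.
    """

    cut_points: np.ndarray

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cut_points, dtype=float)
        if cuts.ndim != 1 or len(cuts) < 1:
            raise ValueError("cut_points must be a 1-D array of length Q-1")
        if not np.all(np.diff(cuts) > 0):
            raise ValueError("cut_points must be strictly ascending")
        object.__setattr__(self, "cut_points", cuts)

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def assign(self, variances: np.ndarray) -> np.ndarray:
        """Map non-negative variances to bin indices 0..Q-1."""
        return np.searchsorted(self.cut_points, variances, side="right")


@dataclass(frozen=True)
class TextureFeature:
    """Unit-norm 224-component descriptor of one 80×80 element."""

    vector: np.ndarray
    element_origin: tuple[int, int]


def preprocess(image: np.ndarray,
               background_threshold: int = BACKGROUND_GRAY_THRESHOLD,
               morphology_radius: int = MORPHOLOGY_RADIUS,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Half-scale, grayscale and background-mask an RGB annotation.

    The image is scaled by 0.5 (box average), converted to grayscale
    with weights 0.2989 R + 0.5870 G + 0.1140 B rounded to 8 bits, and
    bright glass (gray above ``background_threshold``) is removed.  The
    tissue mask is smoothed by morphological closing then erosion with
    a disk footprint.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected RGB input")
    half = box_downscale(image.astype(np.uint8), 2)
    gray_f = (GRAY_WEIGHTS[0] * half[..., 0].astype(float)
              + GRAY_WEIGHTS[1] * half[..., 1].astype(float)
              + GRAY_WEIGHTS[2] * half[..., 2].astype(float))
    gray = np.clip(np.round(gray_f), 0, 255).astype(np.uint8)
    tissue = gray <= background_threshold
    footprint = disk(morphology_radius)
    tissue = binary_closing(tissue, structure=footprint)
    tissue = binary_erosion(tissue, structure=footprint)
    return gray, tissue


def _circular_offsets(P: int, R: float) -> list[tuple[float, float]]:
    """(row, col) offsets of the P samples, CCW from (0, +R)."""
    offsets = []
    for k in range(P):
        angle = 2.0 * np.pi * k / P
        dr = -R * np.sin(angle)
        dc = R * np.cos(angle)
        # snap near-integer positions so exact grid samples stay exact
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        offsets.append((dr, dc))
    return offsets


def _sample_neighbors(gray: np.ndarray, P: int, R: float) -> np.ndarray:
    """Bilinearly sampled neighbour stack of shape (P, H, W).

    The image is edge-padded so every pixel has P samples; callers
    should treat a border of width ceil(R) as invalid.
    """
    gray = np.asarray(gray, dtype=np.float64)
    pad = int(np.ceil(R)) + 1
    padded = np.pad(gray, pad, mode="edge")
    h, w = gray.shape
    stack = np.empty((P,) + gray.shape)
    for i, (dr, dc) in enumerate(_circular_offsets(P, R)):
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        acc = np.zeros_like(gray)
        for (orow, ocol, wt) in ((r0, c0, (1 - fr) * (1 - fc)),
                                 (r0, c0 + 1, (1 - fr) * fc),
                                 (r0 + 1, c0, fr * (1 - fc)),
                                 (r0 + 1, c0 + 1, fr * fc)):
            if wt == 0.0:
                continue
            acc += wt * padded[pad + orow:pad + orow + h,
                               pad + ocol:pad + ocol + w]
        # snap float-precision residue so integer-valued samples stay
        # exact and the >= tie convention is stable
        near = np.rint(acc)
        stack[i] = np.where(np.abs(acc - near) < 1e-8, near, acc)
    return stack


def lbp_riu2(gray: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Rotation-invariant uniform LBP code image.

    Uniform patterns map to their bit count (0..P); non-uniform
    patterns map to P + 1.  A border of width ceil(R) is computed from
    edge-padded samples and should be excluded by callers.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a grayscale image")
    if min(gray.shape) < 2 * int(np.ceil(R)) + 1:
        raise ValueError("image smaller than the operator neighbourhood")
    neighbors = _sample_neighbors(gray, P, R)
    bits = neighbors >= gray.astype(np.float64)[None]
    transitions = np.zeros(gray.shape, dtype=np.int32)
    for i in range(P):
        transitions += bits[i] != bits[(i + 1) % P]
    counts = bits.sum(axis=0)
    codes = np.where(transitions <= 2, counts, P + 1)
    return codes.astype(np.int32)


def var_local(gray: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Rotation-invariant local variance of the P circular samples.

    Population variance (1/P normalization); invariant to any rotation
    of the sample order.  Border validity as for :func:`lbp_riu2`.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a grayscale image")
    if min(gray.shape) < 2 * int(np.ceil(R)) + 1:
        raise ValueError("image smaller than the operator neighbourhood")
    neighbors = _sample_neighbors(gray, P, R)
    mean = neighbors.mean(axis=0)
    var = (neighbors ** 2).mean(axis=0) - mean ** 2
    return np.maximum(var, 0.0)


def _valid_interior(shape: tuple[int, int], R: float) -> tuple[slice, slice]:
    b = int(np.ceil(R))
    return slice(b, shape[0] - b), slice(b, shape[1] - b)


def train_var_quantizer(training_images: list[np.ndarray],
                        P: int, R: float, Q: int = VAR_LEVELS,
                        tissue_masks: list[np.ndarray] | None = None,
                        ) -> VarQuantizer:
    """Learn equal-occupancy VAR cut points from training images.

    Pools VAR over the valid interior (optionally restricted to tissue
    pixels) of every training image and places cut points at the (k/Q)
    quantiles, k = 1..Q−1 (linear-interpolation quantiles).  Raises on
    a degenerate (e.g. all-constant) training pool whose quantiles
    collapse.
    """
    if not training_images:
        raise ValueError("need at least one training image")
    if Q < 2:
        raise ValueError("Q must be >= 2")
    pool = []
    for idx, img in enumerate(training_images):
        var = var_local(img, P, R)
        rows, cols = _valid_interior(var.shape, R)
        values = var[rows, cols]
        if tissue_masks is not None:
            mask = tissue_masks[idx][rows, cols]
            values = values[mask]
        pool.append(values.ravel())
    pooled = np.concatenate(pool)
    if pooled.size == 0:
        raise ValueError("no tissue pixels in the training pool")
    cuts = np.quantile(pooled, np.arange(1, Q) / Q)
    if not np.all(np.diff(cuts) > 0):
        raise ValueError(
            "degenerate training pool: VAR quantiles are not distinct")
    return VarQuantizer(cut_points=cuts)


def extract_element_feature(gray_element: np.ndarray,
                            quantizers: dict[tuple[int, float], VarQuantizer],
                            element_origin: tuple[int, int] = (0, 0),
                            scales: tuple[tuple[int, float], ...] = DEFAULT_SCALES,
                            normalize: bool = True,
                            ) -> TextureFeature:
    """Joint LBP/VAR histogram feature of one 80×80 element.

    For each (P, R) scale, a 2-D occurrence histogram over (LBP code,
    VAR bin) is accumulated from all valid interior pixels and
    flattened to a (P+2)×Q block; the blocks are concatenated and the
    result normalized to unit Euclidean norm (``normalize=False``
    returns the raw occurrence counts, whose per-block sum equals the
    number of valid pixels).
    """
    gray_element = np.asarray(gray_element)
    blocks = []
    for (P, R) in scales:
        quant = quantizers[(P, R)]
        codes = lbp_riu2(gray_element, P, R)
        variances = var_local(gray_element, P, R)
        rows, cols = _valid_interior(codes.shape, R)
        c = codes[rows, cols].ravel()
        v = quant.assign(variances[rows, cols].ravel())
        if c.size == 0:
            raise ValueError("element has no valid pixels")
        q = quant.n_bins
        hist = np.bincount(c * q + v, minlength=(P + 2) * q).astype(float)
        blocks.append(hist)
    vector = np.concatenate(blocks)
    if not normalize:
        return TextureFeature(vector=vector, element_origin=element_origin)
    norm = np.linalg.norm(vector)
    if norm == 0:
        raise ValueError("empty element feature")
    return TextureFeature(vector=vector / norm, element_origin=element_origin)


def enumerate_elements(gray: np.ndarray, tissue_mask: np.ndarray,
                       window: int = ELEMENT_SIZE, step: int = ELEMENT_STEP,
                       min_tissue: float = 0.5) -> list[tuple[int, int]]:
    """Origins of the sliding elements that contain enough tissue.

    Windows are placed row-major from the top-left corner with the
    given step (default 50% overlap); a window is kept iff at least
    ``min_tissue`` of its mask area is tissue.  Trailing pixels that do
    not fill a whole window are not covered.
    """
    h, w = gray.shape
    origins = []
    for r in range(0, h - window + 1, step):
        for c in range(0, w - window + 1, step):
            coverage = tissue_mask[r:r + window, c:c + window].mean()
            if coverage >= min_tissue:
                origins.append((r, c))
    return origins
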