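"""JPEG2000 compression and pyramid downscaling — the degradation operators.

Whole-slide archives store scans as JPEG2000 either losslessly
(reversible 5/3 wavelet) or rate-controlled lossy (irreversible 9/7
wavelet at a target compression ratio), optionally at reduced
resolution.  This module wraps the OpenJPEG codec (via Pillow) and a
deterministic box-filter pyramid, and accounts for stored file sizes so
degradation experiments can report storage savings alongside accuracy.

Ratios are defined against the raw RGB payload (``width*height*3``
bytes), the uncompressed-bitmap baseline.  Rate control is approximate;
achieved ratios land within about ±20% of the target on images with
realistic entropy, and small images bottom out at the codestream header
overhead (a few hundred bytes).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "CompressionSpec",
    "ScalingSpec",
    "CodecReport",
    "CodecError",
    "LOSSLESS",
    "compress_jp2",
    "decompress_jp2",
    "downscale",
    "degrade",
]

SCALING_FACTORS = (1, 2, 4, 8, 16, 32, 64, 128)


class CodecError(ValueError):
    """Raised when a JPEG2000 stream cannot be decoded."""


@dataclass(frozen=True)
class CompressionSpec:
    """Lossless, or lossy at a target compression ratio (e.g. 12, 25, 50)."""

    mode: str = "lossless"
    target_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("lossless", "lossy"):
            raise ValueError(f"mode must be 'lossless' or 'lossy', got {self.mode!r}")
        if self.mode == "lossy":
            if self.target_ratio is None or self.target_ratio <= 1:
                raise ValueError("lossy compression requires target_ratio > 1")

    @classmethod
    def lossy(cls, ratio: float) -> "CompressionSpec":
        return cls(mode="lossy", target_ratio=ratio)


LOSSLESS = CompressionSpec()


@dataclass(frozen=True)
class ScalingSpec:
    """Linear downscale denominator; power of two from 1 to 128."""

    factor: int = 1

    def __post_init__(self) -> None:
        if self.factor not in SCALING_FACTORS:
            raise ValueError(
                f"factor must be one of {SCALING_FACTORS}, got {self.factor}")


@dataclass(frozen=True)
class CodecReport:
    """Storage accounting for one encoded image."""

    raw_bytes: int
    stored_bytes: int
    codec: str = field(default="OpenJPEG (Pillow), default codeblock/wavelet settings")

    @property
    def achieved_ratio(self) -> float:
        return self.raw_bytes / self.stored_bytes


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit RGB image (H, W, 3) uint8, got shape "
            f"{image.shape} dtype {image.dtype}")
    return image


def compress_jp2(image: np.ndarray,
                 spec: CompressionSpec = LOSSLESS,
                 ) -> tuple[bytes, CodecReport]:
    """Encode an 8-bit RGB image as a JPEG2000 stream.

    Lossless mode round-trips bit-exactly.  Lossy mode targets
    ``spec.target_ratio`` against the raw RGB byte count.
    """
    image = _check_rgb8(image)
    buf = io.BytesIO()
    pil = Image.fromarray(image)
    if spec.mode == "lossless":
        pil.save(buf, format="JPEG2000", irreversible=False)
    else:
        pil.save(buf, format="JPEG2000", irreversible=True,
                 quality_mode="rates", quality_layers=[float(spec.target_ratio)])
    stream = buf.getvalue()
    report = CodecReport(raw_bytes=image.size, stored_bytes=len(stream))
    return stream, report


def decompress_jp2(stream: bytes) -> np.ndarray:
    """Decode a JPEG2000 stream to an 8-bit RGB array."""
    try:
        pil = Image.open(io.BytesIO(stream))
        pil.load()
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise CodecError(f"could not decode JPEG2000 stream: {exc}") from exc
    arr = np.asarray(pil.convert("RGB") if pil.mode != "RGB" else pil)
    return np.ascontiguousarray(arr, dtype=np.uint8)


def box_downscale(values: np.ndarray, factor: int) -> np.ndarray:
    """Area-average (box) downscale of a 2-D or 3-D uint8 raster.

    Output dimensions are ``ceil(input/factor)`` per axis; trailing
    blocks are edge-padded to full size before averaging.  Averages are
    rounded half away from zero to 8 bits, which keeps the operation
    bit-reproducible across platforms.
    """
    if factor == 1:
        return values.copy()
    h, w = values.shape[:2]
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds image dimensions {h}x{w}")
    hp = math.ceil(h / factor) * factor
    wp = math.ceil(w / factor) * factor
    pad = [(0, hp - h), (0, wp - w)] + [(0, 0)] * (values.ndim - 2)
    padded = np.pad(values, pad, mode="edge").astype(np.float64)
    blocks = padded.reshape((hp // factor, factor, wp // factor, factor)
                            + values.shape[2:])
    mean = blocks.mean(axis=(1, 3))
    return np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)


def downscale(image: np.ndarray, spec: ScalingSpec | int) -> np.ndarray:
    """Box-filter downscale of an RGB image by a power-of-two factor."""
    if isinstance(spec, int):
        spec = ScalingSpec(spec)
    image = _check_rgb8(image)
    return box_downscale(image, spec.factor)


def degrade(image: np.ndarray,
            compression: CompressionSpec = LOSSLESS,
            scaling: ScalingSpec | int = ScalingSpec(1),
            *,
            scale_first: bool = False,
            ) -> tuple[np.ndarray, CodecReport]:
    """Apply one (compression, scaling) degradation condition.

    By default the image is compressed first and the decoded image is
    then scaled down, matching an archive that stores full-resolution
    compressed scans and derives reduced-resolution versions on demand.
    ``scale_first=True`` swaps the order.

    The report accounts for the stored size of the final image: the
    compressed stream itself when no scaling is applied, otherwise the
    scaled image re-encoded under the same compression spec — i.e. the
    size of the file an archive would keep for that condition.
    """
    if isinstance(scaling, int):
        scaling = ScalingSpec(scaling)
    image = _check_rgb8(image)
    if scale_first:
        scaled = downscale(image, scaling)
        stream, report = compress_jp2(scaled, compression)
        return decompress_jp2(stream), report
    stream, report = compress_jp2(image, compression)
    out = decompress_jp2(stream)
    if scaling.factor > 1:
        out = downscale(out, scaling)
        stream2, report = compress_jp2(out, compression)
    return out, report
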