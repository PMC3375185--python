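"""Degradation study: how compression and scaling move automated results.

Orchestrates the two experimental arms on synthetic data:

* **IHC arm** — every core is degraded over a grid of JPEG2000
  compression ratios × power-of-two scaling factors, scored with the
  stain quantifier, dichotomized at the seventh decile of the
  *reference* condition (lossless, unscaled), and compared to the
  reference labels by percent agreement and Cohen's kappa.

* **Segmentation arm** — texture annotations are classified at each
  compression ratio (no scaling: the LBP operator is scale-variant)
  and per-ratio predictions are compared to the lossless predictions.

The dichotomization cut-off is computed once on the reference condition
and reused everywhere, so the comparison measures degradation rather
than cut-off drift, and the reference cell is exactly 100% / κ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import (cohens_kappa, contingency, dichotomize_decile,
                        percent_agreement)
from .codec import (CompressionSpec, LOSSLESS, box_downscale, compress_jp2,
                    decompress_jp2, degrade)
from .ihc import DEFAULT_THRESHOLDS, StainVectors, ThresholdConfig, quantify
from .segmentation import EPITHELIUM, SvmModel, classify_image
from .texture import VarQuantizer

__all__ = [
    "GridSpec",
    "ExperimentReport",
    "DEFAULT_GRID",
    "run_ihc_grid",
    "run_seg_series",
    "file_size_table",
]

RATIO_GRID = (None, 12, 25, 50)        # None = lossless
SCALE_GRID = (1, 2, 4, 8, 16, 32, 64, 128)


def _ratio_label(ratio: float | None) -> str:
    return "lossless" if ratio is None else f"C{ratio:g}"


def _spec_for(ratio: float | None) -> CompressionSpec:
    return LOSSLESS if ratio is None else CompressionSpec.lossy(ratio)


@dataclass(frozen=True)
class GridSpec:
    """The degradation grid of one experimental arm."""

    compression_ratios: tuple = RATIO_GRID
    scaling_factors: tuple = SCALE_GRID
    apply_scaling: bool = True

    def __post_init__(self) -> None:
        if not self.compression_ratios:
            raise ValueError("compression grid is empty")
        if not self.apply_scaling and tuple(self.scaling_factors) != (1,):
            raise ValueError(
                "scaling is disabled for this arm; scaling_factors must be (1,)")
        if not self.scaling_factors:
            raise ValueError("scaling grid is empty")


DEFAULT_GRID = GridSpec()


@dataclass
class ExperimentReport:
    """Agreement / kappa / size tables of one degradation run."""

    agreement: pd.DataFrame
    kappa: pd.DataFrame
    reference: str
    cutoff: float | None = None
    scores: pd.DataFrame | None = None
    sizes: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_csv(self, out_dir: str | Path, prefix: str = "report") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.agreement.to_csv(out_dir / f"{prefix}_agreement.csv")
        self.kappa.to_csv(out_dir / f"{prefix}_kappa.csv")
        if self.scores is not None:
            self.scores.to_csv(out_dir / f"{prefix}_scores.csv", index=False)
        if self.sizes is not None:
            self.sizes.to_csv(out_dir / f"{prefix}_sizes.csv")


def _grid_extents(image: np.ndarray, grid: GridSpec,
                  thresholds: ThresholdConfig,
                  vectors: StainVectors | None) -> dict:
    """Extent of staining for one core at every grid condition.

    Each ratio is encoded once and the decoded image is scaled down the
    series, which is equivalent to running :func:`slidequant.codec.degrade`
    per condition.
    """
    out = {}
    for ratio in grid.compression_ratios:
        stream, _ = compress_jp2(image, _spec_for(ratio))
        decoded = decompress_jp2(stream)
        for factor in grid.scaling_factors:
            scaled = box_downscale(decoded, factor)
            res = quantify(scaled, vectors, thresholds)
            out[(ratio, factor)] = res.extent
    return out


def run_ihc_grid(images: Sequence[np.ndarray],
                 grid: GridSpec = DEFAULT_GRID,
                 thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
                 vectors: StainVectors | None = None,
                 decile: int = 7) -> ExperimentReport:
    """Degrade, score and compare every IHC core over the grid.

    Continuous extents are collected per condition; all conditions are
    dichotomized with the cut-off derived from the reference condition
    (lossless, scale 1), and each condition's labels are compared to
    the reference labels.
    """
    if len(images) == 0:
        raise ValueError("no images supplied")
    conditions = [(r, s) for r in grid.compression_ratios
                  for s in grid.scaling_factors]
    extents = {cond: [] for cond in conditions}
    rows = []
    for idx, image in enumerate(images):
        per_image = _grid_extents(image, grid, thresholds, vectors)
        for cond, extent in per_image.items():
            extents[cond].append(extent)
            rows.append({"image": idx, "ratio": _ratio_label(cond[0]),
                         "scale": cond[1], "extent": extent})
    ref_cond = (None, 1)
    if ref_cond not in extents:
        raise ValueError("grid must include the lossless, unscaled reference")
    ref_values = np.asarray(extents[ref_cond])
    ref_labels, cutoff = dichotomize_decile(ref_values, decile)

    ratio_labels = [_ratio_label(r) for r in grid.compression_ratios]
    agreement = pd.DataFrame(index=ratio_labels,
                             columns=list(grid.scaling_factors), dtype=float)
    kappa = agreement.copy()
    for (ratio, factor), values in extents.items():
        labels = np.asarray(values) > cutoff
        table = contingency(ref_labels, labels)
        agreement.loc[_ratio_label(ratio), factor] = percent_agreement(table)
        kappa.loc[_ratio_label(ratio), factor] = cohens_kappa(table)
    return ExperimentReport(agreement=agreement, kappa=kappa,
                            reference="lossless, scale 1", cutoff=float(cutoff),
                            scores=pd.DataFrame(rows))


def run_seg_series(images: Sequence[np.ndarray],
                   model: SvmModel,
                   quantizers: dict[tuple[int, float], VarQuantizer],
                   ratios: tuple = (12, 25, 50),
                   ) -> ExperimentReport:
    """Classify every test annotation at each compression ratio.

    Reference predictions come from the uncompressed images (identical
    to a lossless round trip); per-ratio predictions are compared to
    them with percent agreement and kappa.  Mean element scores per
    image and condition are kept for score-histogram exports.
    """
    if len(images) == 0:
        raise ValueError("no images supplied")
    if model is None:
        raise ValueError("a trained model is required")
    rows = []
    ref_preds = []
    for idx, image in enumerate(images):
        res = classify_image(image, model, quantizers)
        ref_preds.append(res.predicted_class == EPITHELIUM)
        rows.append({"image": idx, "ratio": "lossless",
                     "mean_score": res.mean_score,
                     "predicted_class": res.predicted_class,
                     "band": res.band})
    ref_preds = np.asarray(ref_preds)

    labels = ["lossless"] + [_ratio_label(r) for r in ratios]
    agreement = pd.Series(index=labels, dtype=float)
    kappa = pd.Series(index=labels, dtype=float)
    table = contingency(ref_preds, ref_preds)
    agreement["lossless"] = percent_agreement(table)
    kappa["lossless"] = cohens_kappa(table)

    for ratio in ratios:
        preds = []
        for idx, image in enumerate(images):
            stream, _ = compress_jp2(image, _spec_for(ratio))
            degraded = decompress_jp2(stream)
            res = classify_image(degraded, model, quantizers)
            preds.append(res.predicted_class == EPITHELIUM)
            rows.append({"image": idx, "ratio": _ratio_label(ratio),
                         "mean_score": res.mean_score,
                         "predicted_class": res.predicted_class,
                         "band": res.band})
        table = contingency(ref_preds, np.asarray(preds))
        agreement[_ratio_label(ratio)] = percent_agreement(table)
        kappa[_ratio_label(ratio)] = cohens_kappa(table)
    return ExperimentReport(agreement=agreement.to_frame("agreement_pct"),
                            kappa=kappa.to_frame("kappa"),
                            reference="lossless",
                            scores=pd.DataFrame(rows))


def file_size_table(image: np.ndarray,
                    grid: GridSpec = DEFAULT_GRID) -> pd.DataFrame:
    """Stored bytes of one representative image per grid condition.

    Rows are compression levels (lossless first), columns scaling
    factors; each cell is the stored size of the degraded image under
    that condition's own encoding.
    """
    ratio_labels = [_ratio_label(r) for r in grid.compression_ratios]
    sizes = pd.DataFrame(index=ratio_labels,
                         columns=list(grid.scaling_factors), dtype=float)
    for ratio in grid.compression_ratios:
        for factor in grid.scaling_factors:
            _, report = degrade(image, _spec_for(ratio), factor)
            sizes.loc[_ratio_label(ratio), factor] = report.stored_bytes
    return sizes
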