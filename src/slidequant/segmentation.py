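"""Linear-SVM classification of tissue images into epithelium vs stroma.

Each annotated image is reduced to unit-norm LBP+VAR element features
(:mod:`slidequant.texture`); a linear soft-margin SVM (hinge loss,
capacity constant C = 300) scores every element, and the mean decision
value over all elements assigns the image class: epithelium if the mean
score is positive, stroma otherwise (zero counts as stroma).  Images
with a mean score in [-1, 1] are flagged as weak candidates — close to
the decision hyperplane — while scores beyond ±1 are strong.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .texture import (DEFAULT_SCALES, VarQuantizer, enumerate_elements,
                      extract_element_feature, preprocess,
                      train_var_quantizer)

__all__ = [
    "SvmModel",
    "SegmentationResult",
    "UnclassifiableImageError",
    "train_svm",
    "image_features",
    "classify_image",
    "decide_class",
    "fit_segmenter",
]

EPITHELIUM = "epithelium"
STROMA = "stroma"
DEFAULT_C = 300.0
WEAK_BAND = 1.0


class UnclassifiableImageError(ValueError):
    """Raised when an image yields no processable elements."""


@dataclass(frozen=True)
class SvmModel:
    """Trained linear classifier; epithelium scores positive."""

    weights: np.ndarray
    bias: float
    C: float = DEFAULT_C

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.bias

    def save(self, path: str | Path,
             quantizers: dict[tuple[int, float], VarQuantizer] | None = None,
             ) -> None:
        """Persist weights, bias, C and quantizer cut points as JSON."""
        payload: dict = {"weights": self.weights.tolist(),
                         "bias": self.bias, "C": self.C}
        if quantizers:
            payload["quantizers"] = {
                f"{p},{r}": q.cut_points.tolist()
                for (p, r), q in quantizers.items()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path
             ) -> tuple["SvmModel", dict[tuple[int, float], VarQuantizer]]:
        payload = json.loads(Path(path).read_text())
        model = cls(weights=np.asarray(payload["weights"]),
                    bias=float(payload["bias"]), C=float(payload["C"]))
        quantizers = {}
        for key, cuts in payload.get("quantizers", {}).items():
            p, r = key.split(",")
            quantizers[(int(p), float(r))] = VarQuantizer(np.asarray(cuts))
        return model, quantizers


@dataclass(frozen=True)
class SegmentationResult:
    """Element scores and the image-level decision."""

    element_scores: np.ndarray
    mean_score: float
    predicted_class: str
    band: str

    @property
    def n_elements(self) -> int:
        return len(self.element_scores)


def train_svm(features: np.ndarray, labels: list[str] | np.ndarray,
              C: float = DEFAULT_C, tol: float = 1e-6,
              max_iter: int = 100_000) -> SvmModel:
    """Fit the linear C-SVM on element features.

    Labels are class names; epithelium is oriented to positive decision
    values.  The underlying solver (liblinear-style hinge-loss dual)
    is run with a fixed seed and tolerance so training is
    deterministic.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray([1 if lab == EPITHELIUM else -1 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    svc = LinearSVC(C=C, loss="hinge", tol=tol, max_iter=max_iter,
                    random_state=0)
    svc.fit(features, y)
    # the solver orients the hyperplane toward label +1 = epithelium
    return SvmModel(weights=svc.coef_.ravel(),
                    bias=float(svc.intercept_[0]), C=C)


def image_features(image: np.ndarray,
                   quantizers: dict[tuple[int, float], VarQuantizer],
                   scales: tuple[tuple[int, float], ...] = DEFAULT_SCALES,
                   ) -> np.ndarray:
    """Element feature matrix (n_elements × 224) of one RGB annotation."""
    gray, tissue = preprocess(image)
    origins = enumerate_elements(gray, tissue)
    feats = []
    for (r, c) in origins:
        element = gray[r:r + 80, c:c + 80]
        feats.append(extract_element_feature(element, quantizers,
                                             element_origin=(r, c),
                                             scales=scales).vector)
    if not feats:
        return np.empty((0, 0))
    return np.stack(feats)


def fit_segmenter(images: list[np.ndarray], labels: list[str],
                  C: float = DEFAULT_C,
                  scales: tuple[tuple[int, float], ...] = DEFAULT_SCALES,
                  ) -> tuple[SvmModel, dict[tuple[int, float], VarQuantizer]]:
    """Train quantizers and SVM from labelled training annotations.

    The VAR quantizers are learned from the training images only
    (pooled over their tissue pixels) and frozen before the SVM sees
    any feature, so no information leaks from test-time inputs.
    Element features inherit the label of their source image.
    """
    pre = [preprocess(img) for img in images]
    grays = [g for g, _ in pre]
    masks = [m for _, m in pre]
    quantizers = {(p, r): train_var_quantizer(grays, p, r,
                                              tissue_masks=masks)
                  for (p, r) in scales}
    feats, elem_labels = [], []
    for (gray, tissue), label in zip(pre, labels):
        for (r, c) in enumerate_elements(gray, tissue):
            element = gray[r:r + 80, c:c + 80]
            feats.append(extract_element_feature(
                element, quantizers, element_origin=(r, c),
                scales=scales).vector)
            elem_labels.append(label)
    model = train_svm(np.stack(feats), elem_labels, C=C)
    return model, quantizers


def classify_image(image: np.ndarray, model: SvmModel,
                   quantizers: dict[tuple[int, float], VarQuantizer],
                   ) -> SegmentationResult:
    """Classify one annotation image by its mean element SVM score.

    Raises :class:`UnclassifiableImageError` when no element passes the
    tissue-coverage test, rather than silently assigning a class.
    """
    feats = image_features(image, quantizers)
    if feats.size == 0:
        raise UnclassifiableImageError(
            "image contains no elements with sufficient tissue")
    scores = model.decision_values(feats)
    mean_score = float(scores.mean())
    predicted, band = decide_class(mean_score)
    return SegmentationResult(element_scores=scores, mean_score=mean_score,
                              predicted_class=predicted, band=band)


def decide_class(mean_score: float) -> tuple[str, str]:
    """Class and confidence band of an image-level mean score.

    Epithelium iff the score is strictly positive (an exact zero is
    stroma); scores within [-1, 1] are weak candidates, beyond that
    strong.
    """
    predicted = EPITHELIUM if mean_score > 0 else STROMA
    band = "weak" if -WEAK_BAND <= mean_score <= WEAK_BAND else "strong"
    return predicted, band
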