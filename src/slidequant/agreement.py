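"""Agreement statistics for paired binary ratings.

Percent agreement and (unweighted) Cohen's kappa over a 2×2
contingency table, plus the seventh-decile dichotomization used to
turn continuous staining scores into low/high labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyTable2x2",
    "AgreementStats",
    "dichotomize_decile",
    "contingency",
    "percent_agreement",
    "cohens_kappa",
    "agreement_stats",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts cross-tabulating two binary raters.

    Rows are rater 1 (``a``, ``b`` = first class; ``c``, ``d`` =
    second), columns rater 2; ``a`` and ``d`` are the agreeing cells.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AgreementStats:
    percent_agreement: float
    kappa: float


def dichotomize_decile(values: np.ndarray, decile: int = 7,
                       ) -> tuple[np.ndarray, float]:
    """Split continuous scores at a decile cut-off (default seventh).

    The cut-off is the (decile/10)-quantile under the
    linear-interpolation quantile definition.  A value is labelled high
    (True) iff it exceeds the cut-off strictly; ties at the cut-off are
    low.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot dichotomize an empty sample")
    if not 1 <= decile <= 9:
        raise ValueError("decile must be in 1..9")
    cutoff = float(np.quantile(values, decile / 10.0))
    return values > cutoff, cutoff


def contingency(labels_a: np.ndarray, labels_b: np.ndarray,
                ) -> ContingencyTable2x2:
    """Cross-tabulate two equal-length binary label vectors.

    False counts as the first class, so ``a`` counts pairs where both
    raters said False and ``d`` pairs where both said True.
    """
    labels_a = np.asarray(labels_a, dtype=bool)
    labels_b = np.asarray(labels_b, dtype=bool)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors differ in length")
    return ContingencyTable2x2(
        a=int(np.count_nonzero(~labels_a & ~labels_b)),
        b=int(np.count_nonzero(~labels_a & labels_b)),
        c=int(np.count_nonzero(labels_a & ~labels_b)),
        d=int(np.count_nonzero(labels_a & labels_b)),
    )


def percent_agreement(table: ContingencyTable2x2) -> float:
    """Observed agreement, 100·(a+d)/n, in percent."""
    return 100.0 * (table.a + table.d) / table.n


def cohens_kappa(table: ContingencyTable2x2) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e).

    ``p_e`` is the product-of-marginals expected agreement.  Raises on
    degenerate marginals with ``p_e = 1`` (both raters constant), where
    κ is undefined.
    """
    n = table.n
    p_o = (table.a + table.d) / n
    p_e = ((table.a + table.b) * (table.a + table.c)
           + (table.c + table.d) * (table.b + table.d)) / (n * n)
    if p_e == 1.0:
        raise ZeroDivisionError("kappa undefined: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def agreement_stats(table: ContingencyTable2x2) -> AgreementStats:
    return AgreementStats(percent_agreement=percent_agreement(table),
                          kappa=cohens_kappa(table))
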