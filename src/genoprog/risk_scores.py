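"""Genetic risk scores, quantile stratification, and prevalence calibration.

A genetic risk score is the weighted sum of risk-allele counts,
GRS = sum_i w_i R_i with R_i in {0, 1, 2}; unweighted scores set every
w_i = 1. Scores are stratified into near-equal-size quantile bins (quintiles
in the classical presentation) and per-bin cumulative incidence is compared
with a reference bin as a fold-risk ratio. Models fit on case-control data
are calibrated back to the population scale by correcting the logistic
intercept for the case:control sampling ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "RiskScoreModel",
    "grs",
    "quantile_bins",
    "bin_risk_ratios",
    "calibrate_intercept",
]


@dataclass(frozen=True)
class RiskScoreModel:
    """Per-locus GRS weights; ``weights=None`` means unweighted (all 1)."""

    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.ndim != 1:
                raise ValidationError("weights must be a 1-d array")
            if not np.isfinite(w).all():
                raise ValidationError("weights must be finite")


def grs(model: "RiskScoreModel | Sequence[float] | None", risk_allele_counts) -> float:
    """Weighted sum of risk-allele counts for one subject.

    ``model`` may be a :class:`RiskScoreModel`, a bare weight sequence, or
    ``None`` for the unweighted score.
    """
    counts = np.asarray(risk_allele_counts)
    if counts.ndim != 1:
        raise ValidationError("risk allele counts must be a 1-d sequence")
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValidationError("risk allele counts must be in {0, 1, 2}")
    if isinstance(model, RiskScoreModel):
        weights = model.weights
    elif model is None:
        weights = None
    else:
        weights = np.asarray(model, dtype=float)
    if weights is None:
        return float(counts.sum())
    if weights.shape != counts.shape:
        raise ValidationError(
            f"weights length {weights.size} != counts length {counts.size}"
        )
    return float(np.dot(weights, counts))


def grs_matrix(model, risk_allele_counts) -> np.ndarray:
    """GRS for a (n_subjects, n_loci) count matrix."""
    counts = np.asarray(risk_allele_counts)
    if counts.ndim != 2:
        raise ValidationError("count matrix must be 2-d")
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValidationError("risk allele counts must be in {0, 1, 2}")
    weights = model.weights if isinstance(model, RiskScoreModel) else model
    if weights is None:
        return counts.sum(axis=1).astype(float)
    weights = np.asarray(weights, dtype=float)
    return counts @ weights


def quantile_bins(scores: Sequence[float], q: int = 5) -> np.ndarray:
    """Assign each score to one of ``q`` near-equal-size quantile bins.

    Bin 1 holds the lowest scores. With n = q*b + r subjects, the lowest r
    bins receive b+1 subjects each; ties are broken by stable input order.
    """
    scores = np.asarray(scores, dtype=float)
    if q < 2:
        raise ValidationError(f"q must be >= 2, got {q}")
    n = scores.size
    if np.unique(scores).size < q:
        raise ValidationError(
            f"need at least {q} distinct score values, got {np.unique(scores).size}"
        )
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, q)
    sizes = np.full(q, base)
    sizes[:rem] += 1
    bins = np.empty(n, dtype=int)
    bins[order] = np.repeat(np.arange(1, q + 1), sizes)
    return bins


def bin_risk_ratios(bins, labels, reference_bin: int = 1, positive=1) -> dict[int, float]:
    """Fold-risk of each bin relative to the reference bin.

    Risk is cumulative incidence (cases/total) per bin; the ratio is formed
    with exact rational arithmetic on the counts before the final division.
    """
    bins = np.asarray(bins)
    labels = np.asarray(labels)
    if bins.shape != labels.shape or bins.ndim != 1:
        raise ValidationError("bins and labels must be 1-d arrays of equal length")
    uniq = np.unique(bins)
    if reference_bin not in uniq:
        raise ValidationError(f"reference bin {reference_bin} is empty or absent")
    cases = {int(b): int(((bins == b) & (labels == positive)).sum()) for b in uniq}
    totals = {int(b): int((bins == b).sum()) for b in uniq}
    if cases[int(reference_bin)] == 0:
        raise ValidationError("reference bin has zero cases; fold-risk undefined")
    ref = Fraction(cases[int(reference_bin)], totals[int(reference_bin)])
    return {
        b: float(Fraction(cases[b], totals[b]) / ref) for b in map(int, uniq)
    }


def calibrate_intercept(
    beta0_cc: float, n_case: int, n_control: int, prevalence: float
) -> float:
    """Population-scale intercept from a case-control logistic intercept.

    beta0_pop = beta0_cc - ln(n_case/n_control) + logit(prevalence). The
    correction removes the case:control sampling odds and installs the
    population odds of disease.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValidationError("case and control counts must be positive")
    if not (0.0 < prevalence < 1.0):
        raise ValidationError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(
        beta0_cc
        - math.log(n_case / n_control)
        + math.log(prevalence / (1.0 - prevalence))
    )
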