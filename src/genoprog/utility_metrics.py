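"""Prognostic-utility metrics: ROC/AUC, predictive values, NRI, KL divergence.

AUC is computed in its pairwise form P(score_case > score_control) +
0.5*P(equal) — the Mann-Whitney statistic — either exactly on analytic score
distributions or empirically on labeled samples; both routes handle ties with
half weight. Predictive values follow the Bayes identities on sensitivity,
specificity and prevalence. The Kullback-Leibler divergence between the
posterior and prior probability-of-disease densities is offered in two
variants: ``literal`` (one posterior-only term per distinct posterior value)
and ``weighted`` (population-expected Bernoulli KL, nonnegative by Gibbs'
inequality and zero iff the posterior is everywhere equal to the prior).
All divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "LabeledScores",
    "ScoreDistribution",
    "auc",
    "auc_labeled",
    "roc_curve",
    "predictive_values",
    "PredictiveValues",
    "kl_divergence",
    "nri",
]


@dataclass(frozen=True)
class ScoreDistribution:
    """Discrete score distribution for one outcome class."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)
        if support.shape != mass.shape or support.ndim != 1 or support.size == 0:
            raise ValidationError("support and mass must be non-empty 1-d arrays")
        if np.any(mass < 0):
            raise ValidationError("mass values must be nonnegative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ValidationError(f"mass must sum to 1, got {mass.sum()}")


@dataclass(frozen=True)
class LabeledScores:
    """Real-valued predictions paired with binary (or multi-class) labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValidationError("scores and labels must be 1-d arrays of equal length")


def _as_support_mass(x) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a ScoreDistribution / PpdDistribution / sample array to
    (sorted support, mass)."""
    if hasattr(x, "support") and hasattr(x, "mass"):
        s = np.asarray(x.support, dtype=float)
        m = np.asarray(x.mass, dtype=float)
        order = np.argsort(s)
        return s[order], m[order]
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("score sample must be a non-empty 1-d array")
    vals, counts = np.unique(arr, return_counts=True)
    return vals, counts / counts.sum()


def auc(cases, controls) -> float:
    """P(case score > control score) + 0.5 P(equal).

    Accepts discrete distributions (exact) or raw score arrays (empirical
    Mann-Whitney with half-weighted ties) for either class.
    """
    s1, m1 = _as_support_mass(cases)
    s0, m0 = _as_support_mass(controls)
    cdf0 = np.concatenate([[0.0], np.cumsum(m0)])
    lo = np.searchsorted(s0, s1, side="left")
    hi = np.searchsorted(s0, s1, side="right")
    p_less = cdf0[lo]
    p_equal = cdf0[hi] - cdf0[lo]
    return float(np.dot(m1, p_less + 0.5 * p_equal))


def auc_labeled(scores: Sequence[float], labels: Sequence, positive=1) -> float:
    """Empirical AUC from a labeled sample; ``positive`` marks the case label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if not pos.any() or pos.all():
        raise ValidationError("AUC requires at least one case and one control")
    return auc(scores[pos], scores[~pos])


def roc_curve(cases, controls, thresholds: Sequence[float] | None = None) -> np.ndarray:
    """ROC points (1 - specificity, sensitivity) for strict-positive calls.

    A result is called positive when the score exceeds the threshold.
    Thresholds default to every distinct score value; the endpoints (0, 0)
    and (1, 1) are always included. Trapezoidal integration of the returned
    curve equals :func:`auc`.
    """
    s1, m1 = _as_support_mass(cases)
    s0, m0 = _as_support_mass(controls)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([s1, s0]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    sf1 = np.concatenate([[1.0], 1.0 - np.cumsum(m1)])  # survival lookup
    sf0 = np.concatenate([[1.0], 1.0 - np.cumsum(m0)])
    tpr = sf1[np.searchsorted(s1, thresholds, side="right")]
    fpr = sf0[np.searchsorted(s0, thresholds, side="right")]
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return np.unique(pts[order], axis=0)


class PredictiveValues(NamedTuple):
    ppv: float
    npv: float
    average: float


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> PredictiveValues:
    """PPV, NPV and their average at a given disease prevalence.

    PPV = se*p / (se*p + (1-sp)(1-p)); NPV = sp(1-p) / (sp(1-p) + (1-se)p).
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    se, sp, p = sensitivity, specificity, prevalence
    denom_pos = se * p + (1.0 - sp) * (1.0 - p)
    denom_neg = sp * (1.0 - p) + (1.0 - se) * p
    if denom_pos == 0.0:
        raise UndefinedMetricError(
            "PPV undefined: the test never returns a positive result"
        )
    if denom_neg == 0.0:
        raise UndefinedMetricError(
            "NPV undefined: the test never returns a negative result"
        )
    ppv = se * p / denom_pos
    npv = sp * (1.0 - p) / denom_neg
    return PredictiveValues(ppv=ppv, npv=npv, average=(ppv + npv) / 2.0)


def kl_divergence(dist, prior: float, variant: str = "weighted") -> float:
    """Divergence between the posterior-probability density and the prior.

    ``weighted`` (default) is the population expectation of the Bernoulli KL,
    sum_g P(g) [ p_g ln(p_g/K) + (1-p_g) ln((1-p_g)/(1-K)) ], nonnegative and
    zero iff every posterior equals the prior. ``literal`` sums only the
    disease term p ln(p/K), one term per distinct posterior value, with no
    population weighting; it is reported for comparability but is not a
    proper divergence. Result in nats.
    """
    if not (0.0 < prior < 1.0):
        raise ValidationError(f"prior must be in (0, 1), got {prior}")
    if variant not in ("literal", "weighted"):
        raise ValidationError(f"unknown KL variant {variant!r}")
    p = np.asarray(dist.support, dtype=float)
    m = np.asarray(dist.mass, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_pos = np.where(p > 0, p * np.log(p / prior), 0.0)
        term_neg = np.where(
            p < 1, (1.0 - p) * np.log((1.0 - p) / (1.0 - prior)), 0.0
        )
    if variant == "literal":
        return float(term_pos.sum())
    return float(np.dot(m, term_pos + term_neg))


def nri(old_category, new_category, labels, positive=1) -> float:
    """Net reclassification improvement over ordinal risk categories.

    NRI = [P(up|event) - P(down|event)] - [P(up|non-event) - P(down|non-event)],
    bounded in [-2, 2].
    """
    old = np.asarray(old_category)
    new = np.asarray(new_category)
    labels = np.asarray(labels)
    if not (old.shape == new.shape == labels.shape) or old.ndim != 1:
        raise ValidationError("categories and labels must be 1-d arrays of equal length")
    events = labels == positive
    if not events.any():
        raise ValidationError("NRI requires at least one event")
    if events.all():
        raise ValidationError("NRI requires at least one non-event")
    up = new > old
    down = new < old
    p_up_e = up[events].mean()
    p_down_e = down[events].mean()
    p_up_ne = up[~events].mean()
    p_down_ne = down[~events].mean()
    return float((p_up_e - p_down_e) - (p_up_ne - p_down_ne))
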