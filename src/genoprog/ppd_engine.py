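"""Posterior probability of disease (PPD) and its exact population distribution.

Under the Naive Bayes factorization, the posterior probability of disease for
a multilocus genotype is

    PPD = sigma( logit(K) + sum_i [ s_i*ln(g1_i/g0_i) + (1-s_i)*ln((1-g1_i)/(1-g0_i)) ] )

where K is the prior probability of disease and s_i the per-locus carrier
indicator. Because the population distribution of genotype vectors is a
product (or a two-component mixture of products) of independent Bernoulli
laws, the population distribution of PPD is discrete and can be computed
exactly:

* exchangeable models — the posterior depends only on the carrier count k,
  which is binomial, so the distribution has n+1 support points whatever n;
* heterogeneous models with n <= 20 loci — exact enumeration of all 2^n
  log-likelihood-ratio sums;
* larger heterogeneous models — dynamic-programming convolution of the
  per-locus two-point log-LR increments on a fixed grid (linear mass
  splitting between adjacent bins, which preserves the mean exactly);
* a seeded Monte Carlo fallback.

Three population modes define which genotype distribution the PPD density is
taken over: ``control`` (all loci at g0), ``marginal_independent`` (all loci
independently at g_pop = K*g1 + (1-K)*g0), and ``mixture`` (the generative
law: disease status drawn from the prior, then loci at g1 or g0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .errors import ValidationError
from .model_spec import (
    DiseaseModel,
    GenotypeVector,
    as_states,
    carrier_probabilities,
    exchangeable_model,
)

MAX_LOCI = 100_000
EXACT_ENUMERATION_MAX = 20
DEFAULT_RESOLUTION = 4096
MIN_RESOLUTION = 256

__all__ = [
    "PpdDistribution",
    "ThresholdReport",
    "ppd",
    "ppd_many",
    "ppd_distribution",
    "threshold_fractions",
    "scaled_posterior_ratios",
    "sweep_relative_risk",
    "sweep_prior",
    "sweep_locus_count",
]


@dataclass(frozen=True)
class PpdDistribution:
    """Discrete probability mass over posterior-probability-of-disease values."""

    support: np.ndarray
    mass: np.ndarray
    population_mode: str
    model_digest: str
    discretization_error: float = 0.0

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)
        if support.shape != mass.shape or support.ndim != 1:
            raise ValidationError("support and mass must be 1-d arrays of equal length")
        if np.any(mass < -1e-15):
            raise ValidationError("mass values must be nonnegative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ValidationError(f"mass must sum to 1, got {mass.sum()}")
        if np.any(np.diff(support) <= 0):
            raise ValidationError("support must be strictly ascending")
        if support.size and (support[0] < -1e-12 or support[-1] > 1 + 1e-12):
            raise ValidationError("support values must lie in [0, 1]")

    def mean(self) -> float:
        return float(np.dot(self.support, self.mass))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot(self.mass, (self.support - m) ** 2))


@dataclass(frozen=True)
class ThresholdReport:
    """Fractions of the population meeting the actionability conditions.

    C1: PPD > tau_pos (actionably high); C2: PPD < tau_neg (actionably low);
    the remainder satisfies neither. Inequalities are strict.
    """

    tau_pos: float
    tau_neg: float
    c1_fraction: float
    c2_fraction: float
    neither_fraction: float

    def __post_init__(self) -> None:
        total = self.c1_fraction + self.c2_fraction + self.neither_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"threshold fractions must sum to 1, got {total}")


def _posterior_from_log_lr(prior: float, log_lr_sum: np.ndarray) -> np.ndarray:
    """Map summed log likelihood ratios through the posterior transform."""
    if prior == 0.0:
        return np.zeros_like(np.asarray(log_lr_sum, dtype=float))
    if prior == 1.0:
        return np.ones_like(np.asarray(log_lr_sum, dtype=float))
    return expit(logit(prior) + np.asarray(log_lr_sum, dtype=float))


def ppd(model: DiseaseModel, genotype: "GenotypeVector | Sequence[int]") -> float:
    """Posterior probability of disease for one genotype vector (log-space)."""
    states = as_states(genotype)
    if states.size != model.n_loci:
        raise ValidationError(
            f"genotype length {states.size} != model locus count {model.n_loci}"
        )
    log_lr = sum(
        (np.log(l.lr_pos) if s else np.log(l.lr_neg))
        for l, s in zip(model.loci, states)
    )
    return float(_posterior_from_log_lr(model.prior, np.float64(log_lr)))


def ppd_many(model: DiseaseModel, genotypes: np.ndarray) -> np.ndarray:
    """Vectorized PPD for a (n_subjects, n_loci) 0/1 genotype matrix."""
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] != model.n_loci:
        raise ValidationError("genotype matrix shape does not match the model")
    lp = np.array([np.log(l.lr_pos) for l in model.loci])
    ln = np.array([np.log(l.lr_neg) for l in model.loci])
    log_lr = g @ lp + (1 - g) @ ln
    return _posterior_from_log_lr(model.prior, log_lr)


def _aggregate(support: np.ndarray, mass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort ascending and merge exactly-equal support values."""
    order = np.argsort(support, kind="stable")
    s, m = support[order], mass[order]
    if s.size == 0:
        return s, m
    keep = np.empty(s.size, dtype=bool)
    keep[0] = True
    keep[1:] = s[1:] != s[:-1]
    idx = np.cumsum(keep) - 1
    out_s = s[keep]
    out_m = np.zeros(out_s.size)
    np.add.at(out_m, idx, m)
    return out_s, out_m


def _exchangeable_log_lr(model: DiseaseModel) -> tuple[np.ndarray, float, float]:
    n = model.n_loci
    l0 = model.loci[0]
    lp, ln = np.log(l0.lr_pos), np.log(l0.lr_neg)
    k = np.arange(n + 1)
    return k * lp + (n - k) * ln, l0.g0, l0.g1


def _carrier_count_mass(n: int, p: float) -> np.ndarray:
    return stats.binom.pmf(np.arange(n + 1), n, p)


def _enumerate_log_lr(
    log_neg: np.ndarray, log_pos: np.ndarray, probs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the summed log-LR by full enumeration (n <= 20)."""
    sums = np.zeros(1)
    mass = np.ones(1)
    for ln_, lp_, p in zip(log_neg, log_pos, probs):
        sums = np.concatenate([sums + ln_, sums + lp_])
        mass = np.concatenate([mass * (1.0 - p), mass * p])
    return sums, mass


def _grid_convolve(
    log_neg: np.ndarray, log_pos: np.ndarray, probs: np.ndarray, resolution: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """DP convolution of two-point log-LR increments on a fixed grid.

    Tracks the sum of nonnegative offsets (x_i - min_i) on a uniform grid of
    ``resolution`` bins; a shift by a non-integer number of bins is split
    linearly between the two adjacent bins, which keeps the mean exact.
    Returns (log-LR grid, mass, worst-case support discretization error).
    """
    lo = np.minimum(log_neg, log_pos)
    d = np.abs(log_pos - log_neg)
    total_lo = lo.sum()
    span = d.sum()
    if span <= 0:
        return np.array([total_lo]), np.array([1.0]), 0.0
    width = span / (resolution - 1)
    mass = np.zeros(resolution)
    mass[0] = 1.0
    for d_i, ln_, lp_, p in zip(d, log_neg, log_pos, probs):
        # the branch at min contributes offset 0; the other contributes d_i
        p_hi = p if lp_ >= ln_ else 1.0 - p
        off = d_i / width
        j = int(np.floor(off))
        frac = off - j
        shifted = np.zeros(resolution)
        if j < resolution:
            shifted[j:] += (1.0 - frac) * mass[: resolution - j]
        if frac > 0:
            if j + 1 < resolution:
                shifted[j + 1 :] += frac * mass[: resolution - j - 1]
            else:  # clamp rounding overflow at the top edge
                shifted[-1] += frac * mass[: resolution - j].sum()
        mass = (1.0 - p_hi) * mass + p_hi * shifted
    grid = total_lo + width * np.arange(resolution)
    nz = mass > 0
    return grid[nz], mass[nz], float(width * len(d)) / 2.0


def _mode_distribution(
    model: DiseaseModel, mode: str, resolution: int, method: str, rng
) -> tuple[np.ndarray, np.ndarray, float]:
    """Distribution of the summed log-LR under one population mode."""
    n = model.n_loci
    log_pos = np.array([np.log(l.lr_pos) for l in model.loci])
    log_neg = np.array([np.log(l.lr_neg) for l in model.loci])

    def _per_locus_probs(which: str) -> np.ndarray:
        if which == "g1":
            return np.array([l.g1 for l in model.loci])
        if which == "g0":
            return np.array([l.g0 for l in model.loci])
        return carrier_probabilities(model, "marginal_independent")

    def _product_dist(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        if model.is_exchangeable:
            log_lr, _, _ = _exchangeable_log_lr(model)
            return log_lr, _carrier_count_mass(n, float(probs[0])), 0.0
        if method == "monte_carlo":
            draws = rng.random((100_000, n)) < probs
            sums = draws @ log_pos + (~draws) @ log_neg
            vals, counts = np.unique(sums, return_counts=True)
            return vals, counts / counts.sum(), 0.0
        if n <= EXACT_ENUMERATION_MAX and method in ("auto", "exact"):
            sums, mass = _enumerate_log_lr(log_neg, log_pos, probs)
            return sums, mass, 0.0
        if method == "exact":
            raise ValidationError(
                f"exact enumeration only supported for n <= {EXACT_ENUMERATION_MAX}"
            )
        return _grid_convolve(log_neg, log_pos, probs, resolution)

    if mode == "control":
        return _product_dist(_per_locus_probs("g0"))
    if mode == "marginal_independent":
        return _product_dist(_per_locus_probs("gpop"))
    # mixture: prior-weighted mixture of the all-cases and all-controls products
    s1, m1, e1 = _product_dist(_per_locus_probs("g1"))
    s0, m0, e0 = _product_dist(_per_locus_probs("g0"))
    sums = np.concatenate([s1, s0])
    mass = np.concatenate([model.prior * m1, (1.0 - model.prior) * m0])
    return sums, mass, max(e1, e0)


def ppd_distribution(
    model: DiseaseModel,
    resolution: int = DEFAULT_RESOLUTION,
    mode: str | None = None,
    method: str = "auto",
    seed: int | None = None,
) -> PpdDistribution:
    """Exact population distribution of PPD under a disease model.

    Parameters
    ----------
    model : DiseaseModel
    resolution : int
        Log-LR grid size for heterogeneous models with more than 20 loci
        (default 4096, minimum 256). Ignored for exchangeable models and for
        small models, which are enumerated exactly.
    mode : str, optional
        Population mode override; defaults to ``model.population_mode``.
    method : {"auto", "exact", "grid", "monte_carlo"}
        ``auto`` picks carrier-count arithmetic for exchangeable models,
        exact enumeration for n <= 20, and the grid convolution otherwise.
    seed : int, optional
        Required for ``monte_carlo``.
    """
    mode = mode or model.population_mode
    if mode not in ("control", "marginal_independent", "mixture"):
        raise ValidationError(f"unknown population mode {mode!r}")
    if model.n_loci > MAX_LOCI:
        raise ValidationError(f"models beyond {MAX_LOCI} loci are not supported")
    if method not in ("auto", "exact", "grid", "monte_carlo"):
        raise ValidationError(f"unknown method {method!r}")
    needs_grid = (
        method == "grid"
        or (
            method == "auto"
            and not model.is_exchangeable
            and model.n_loci > EXACT_ENUMERATION_MAX
        )
    )
    if needs_grid and resolution < MIN_RESOLUTION:
        raise ValidationError(
            f"resolution must be >= {MIN_RESOLUTION} for grid convolution"
        )
    rng = np.random.default_rng(seed) if method == "monte_carlo" else None
    if method == "monte_carlo" and seed is None:
        raise ValidationError("monte_carlo method requires an explicit seed")

    log_lr, mass, disc_err = _mode_distribution(model, mode, resolution, method, rng)
    support = _posterior_from_log_lr(model.prior, log_lr)
    support, mass = _aggregate(np.asarray(support, dtype=float), mass)
    mass = mass / mass.sum()
    # posterior-scale worst-case discretization error: sigma is 1/4-Lipschitz
    return PpdDistribution(
        support=support,
        mass=mass,
        population_mode=mode,
        model_digest=model.digest(),
        discretization_error=disc_err / 4.0,
    )


def threshold_fractions(
    dist: PpdDistribution, tau_pos: float = 0.95, tau_neg: float = 0.05
) -> ThresholdReport:
    """Fractions of the population with PPD > tau_pos (C1) or < tau_neg (C2)."""
    if not (0.0 <= tau_neg < tau_pos <= 1.0):
        raise ValidationError(
            f"thresholds must satisfy 0 <= tau_neg < tau_pos <= 1, "
            f"got tau_neg={tau_neg}, tau_pos={tau_pos}"
        )
    c1 = float(dist.mass[dist.support > tau_pos].sum())
    c2 = float(dist.mass[dist.support < tau_neg].sum())
    return ThresholdReport(
        tau_pos=tau_pos,
        tau_neg=tau_neg,
        c1_fraction=c1,
        c2_fraction=c2,
        neither_fraction=1.0 - c1 - c2,
    )


def scaled_posterior_ratios(
    model: DiseaseModel, genotypes: Iterable["GenotypeVector | Sequence[int]"]
) -> np.ndarray:
    """Posterior ratios scaled so the smallest posterior maps to exactly 1."""
    genotypes = list(genotypes)
    if not genotypes:
        raise ValidationError("genotype list must be non-empty")
    ppds = np.array([ppd(model, g) for g in genotypes])
    lo = ppds.min()
    if lo == 0.0:
        raise ValidationError("cannot scale ratios: minimum posterior is 0")
    return ppds / lo


def _sweep_frame(records: list[dict]) -> "object":
    import pandas as pd

    return pd.DataFrame.from_records(records)


def sweep_relative_risk(
    n: int,
    g0: float,
    prior: float,
    rr_grid: Sequence[float],
    taus: tuple[float, float] = (0.95, 0.05),
    mode: str = "marginal_independent",
    mapping: str = "freq_ratio",
):
    """C1/C2 fractions of an exchangeable model over a relative-risk grid."""
    tau_pos, tau_neg = taus
    records = []
    for rr in rr_grid:
        model = exchangeable_model(n, g0, rr, prior, mode=mode, mapping=mapping)
        rep = threshold_fractions(ppd_distribution(model), tau_pos, tau_neg)
        records.append(
            {
                "rr": rr,
                "c1": rep.c1_fraction,
                "c2": rep.c2_fraction,
                "neither": rep.neither_fraction,
            }
        )
    return _sweep_frame(records)


PRIOR_EPSILON = 1e-6


def sweep_prior(
    n: int,
    g0: float,
    rr: float,
    prior_grid: Sequence[float],
    taus: tuple[float, float] = (0.95, 0.05),
    mode: str = "marginal_independent",
    mapping: str = "freq_ratio",
):
    """C1/C2 fractions over a prior-probability grid.

    Priors of exactly 0 or 1 are ill-posed for threshold analysis (the
    posterior is degenerate); they are evaluated at the limits
    ``PRIOR_EPSILON`` and ``1 - PRIOR_EPSILON``.
    """
    tau_pos, tau_neg = taus
    records = []
    for prior in prior_grid:
        eff = min(max(prior, PRIOR_EPSILON), 1.0 - PRIOR_EPSILON)
        model = exchangeable_model(n, g0, rr, eff, mode=mode, mapping=mapping)
        rep = threshold_fractions(ppd_distribution(model), tau_pos, tau_neg)
        records.append(
            {
                "prior": prior,
                "c1": rep.c1_fraction,
                "c2": rep.c2_fraction,
                "neither": rep.neither_fraction,
            }
        )
    return _sweep_frame(records)


def sweep_locus_count(
    g0: float,
    rr: float,
    prior: float,
    n_grid: Sequence[int],
    mode: str = "marginal_independent",
    mapping: str = "freq_ratio",
):
    """PPD variance as the number of loci grows.

    Returns a DataFrame with columns ``n`` and ``ppd_variance``; the full
    distributions are attached under ``df.attrs["distributions"]``.
    """
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValidationError("n_grid must be strictly ascending")
    records, dists = [], {}
    for n in n_grid:
        model = exchangeable_model(int(n), g0, rr, prior, mode=mode, mapping=mapping)
        dist = ppd_distribution(model)
        dists[int(n)] = dist
        records.append({"n": int(n), "ppd_variance": dist.variance()})
    df = _sweep_frame(records)
    df.attrs["distributions"] = dists
    return df
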