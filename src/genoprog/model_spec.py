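"""Genetic architectures for multilocus disease-risk models.

A disease model is a prior probability of disease K = P(D=1) together with a
set of susceptibility loci. Each locus is reduced to a binary carrier state:
an individual either carries the predisposing genotype or does not. The locus
is parameterized by the frequency of the predisposing genotype in controls
(``g0``), the per-locus relative risk (``rr``), and a derived frequency in
cases (``g1``), from which the carrier and non-carrier likelihood ratios
follow. All downstream computation (posterior probabilities, population
distributions, classifiers) is driven by these per-locus quantities.

Two mappings from (g0, rr) to g1 are supported:

``freq_ratio`` (default)
    g1 = rr * g0, i.e. the relative risk is interpreted as the carrier
    likelihood ratio g1/g0 directly.
``epidemiological``
    rr is interpreted as the ratio of disease risk in carriers to disease
    risk in non-carriers, and g1 is solved from the prevalence-consistent
    system by fixed-point iteration.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConvergenceError, ValidationError

POPULATION_MODES = ("control", "marginal_independent", "mixture")
MAPPINGS = ("freq_ratio", "epidemiological")

_FP_MAX_ITER = 10_000
_FP_RTOL = 1e-12


@dataclass(frozen=True)
class LocusEffect:
    """One susceptibility locus under the binary carrier abstraction.

    Attributes
    ----------
    locus_id : str
        Unique label for the locus.
    g0 : float
        Frequency of the predisposing genotype in controls, in (0, 1).
    rr : float
        Per-locus relative risk of the predisposing genotype (> 0).
    g1 : float
        Derived frequency of the predisposing genotype in cases, in (0, 1).
    weight : float or None
        Optional genetic-risk-score weight w_i.
    """

    locus_id: str
    g0: float
    rr: float
    g1: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.g0 < 1.0):
            raise ValidationError(
                f"locus {self.locus_id!r}: g0 must be in (0, 1), got {self.g0}"
            )
        if not self.rr > 0.0:
            raise ValidationError(
                f"locus {self.locus_id!r}: rr must be positive, got {self.rr}"
            )
        if not (0.0 < self.g1 < 1.0):
            raise ValidationError(
                f"locus {self.locus_id!r}: derived g1 must be in (0, 1), got {self.g1}"
            )
        if self.weight is not None and not math.isfinite(self.weight):
            raise ValidationError(
                f"locus {self.locus_id!r}: weight must be finite, got {self.weight}"
            )

    @property
    def lr_pos(self) -> float:
        """Likelihood ratio for carriers, g1/g0."""
        return self.g1 / self.g0

    @property
    def lr_neg(self) -> float:
        """Likelihood ratio for non-carriers, (1-g1)/(1-g0)."""
        return (1.0 - self.g1) / (1.0 - self.g0)


def make_locus(
    g0: float,
    rr: float,
    mapping: str = "freq_ratio",
    prior: float | None = None,
    locus_id: str = "locus",
    weight: float | None = None,
) -> LocusEffect:
    """Build a :class:`LocusEffect`, deriving the case frequency ``g1``.

    Parameters
    ----------
    g0 : float
        Predisposing-genotype frequency in controls, in (0, 1).
    rr : float
        Relative risk (> 0). Under ``freq_ratio`` this is the carrier
        likelihood ratio; under ``epidemiological`` it is the ratio of
        disease risk in carriers to non-carriers.
    mapping : {"freq_ratio", "epidemiological"}
        How rr is translated into g1.
    prior : float, optional
        Disease prevalence K; required (and must lie in (0, 1)) for the
        epidemiological mapping.
    """
    if mapping not in MAPPINGS:
        raise ValidationError(f"unknown mapping {mapping!r}; expected one of {MAPPINGS}")
    if not (0.0 < g0 < 1.0):
        raise ValidationError(f"g0 must be in (0, 1), got {g0}")
    if not rr > 0.0:
        raise ValidationError(f"rr must be positive, got {rr}")

    if mapping == "freq_ratio":
        g1 = rr * g0
        if g1 >= 1.0:
            raise ValidationError(
                f"freq_ratio mapping requires rr*g0 < 1, got rr*g0 = {g1}"
            )
    else:
        if prior is None or not (0.0 < prior < 1.0):
            raise ValidationError(
                f"epidemiological mapping requires prior in (0, 1), got {prior}"
            )
        g1 = _solve_epidemiological(g0, rr, prior)
    return LocusEffect(locus_id=locus_id, g0=g0, rr=rr, g1=g1, weight=weight)


def _solve_epidemiological(g0: float, rr: float, prior: float) -> float:
    """Solve the prevalence-consistent carrier frequency in cases.

    Unknowns: population carrier frequency g and non-carrier risk p0, with
    carrier risk p1 = rr*p0, subject to

        prior = g*p1 + (1-g)*p0        (total prevalence)
        g0 = g*(1-p1) / (1-prior)      (carrier frequency among non-diseased)

    The case carrier frequency is then g1 = g*p1/prior. Solved by
    fixed-point iteration on g starting from g0.
    """
    g = g0
    for _ in range(_FP_MAX_ITER):
        p0 = prior / (g * rr + (1.0 - g))
        p1 = rr * p0
        if p1 >= 1.0:
            raise ValidationError(
                f"epidemiological mapping infeasible: carrier risk {p1} >= 1 "
                f"for g0={g0}, rr={rr}, prior={prior}"
            )
        g_new = g0 * (1.0 - prior) / (1.0 - p1)
        if abs(g_new - g) <= _FP_RTOL * max(abs(g_new), 1e-300):
            g = g_new
            break
        g = g_new
    else:
        raise ConvergenceError(
            f"epidemiological fixed point did not converge in {_FP_MAX_ITER} "
            f"iterations (g0={g0}, rr={rr}, prior={prior})"
        )
    p0 = prior / (g * rr + (1.0 - g))
    g1 = g * rr * p0 / prior
    if not (0.0 < g1 < 1.0):
        raise ValidationError(
            f"epidemiological mapping produced g1={g1} outside (0, 1)"
        )
    return g1


def population_frequency(locus: LocusEffect, prior: float) -> float:
    """Marginal carrier frequency in a population with disease prior ``prior``.

    g_pop = prior*g1 + (1-prior)*g0.
    """
    if not (0.0 <= prior <= 1.0):
        raise ValidationError(f"prior must be in [0, 1], got {prior}")
    return prior * locus.g1 + (1.0 - prior) * locus.g0


@dataclass(frozen=True)
class DiseaseModel:
    """A prior probability of disease plus an ordered set of loci."""

    prior: float
    loci: tuple[LocusEffect, ...]
    population_mode: str = "marginal_independent"

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior <= 1.0):
            raise ValidationError(f"prior must be in [0, 1], got {self.prior}")
        if len(self.loci) == 0:
            raise ValidationError("model must contain at least one locus")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("locus ids must be unique")
        if self.population_mode not in POPULATION_MODES:
            raise ValidationError(
                f"population_mode must be one of {POPULATION_MODES}, "
                f"got {self.population_mode!r}"
            )
        object.__setattr__(self, "loci", tuple(self.loci))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def is_exchangeable(self) -> bool:
        """True when every locus shares the same (g0, g1), so the posterior
        depends on the genotype vector only through the carrier count."""
        first = self.loci[0]
        return all(l.g0 == first.g0 and l.g1 == first.g1 for l in self.loci)

    def digest(self) -> str:
        """Short stable hash of the model parameters, for provenance."""
        h = hashlib.sha256()
        h.update(repr((self.prior, self.population_mode)).encode())
        for l in self.loci:
            h.update(repr((l.locus_id, l.g0, l.rr, l.g1, l.weight)).encode())
        return h.hexdigest()[:12]


@dataclass(frozen=True)
class GenotypeVector:
    """Per-locus carrier indicators (1 = carries the predisposing genotype)."""

    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s not in (0, 1) for s in self.states):
            raise ValidationError("genotype states must be binary (0/1)")
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))

    def __len__(self) -> int:
        return len(self.states)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.states, dtype=dtype)


def as_states(genotype: "GenotypeVector | Sequence[int] | np.ndarray") -> np.ndarray:
    """Coerce a genotype vector (object or sequence) to a validated 0/1 array."""
    arr = np.asarray(
        genotype.states if isinstance(genotype, GenotypeVector) else genotype
    )
    if arr.ndim != 1:
        raise ValidationError("genotype vector must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("genotype states must be binary (0/1)")
    return arr.astype(np.int8)


def exchangeable_model(
    n: int,
    g0: float,
    rr: float,
    prior: float,
    mode: str = "marginal_independent",
    mapping: str = "freq_ratio",
    weight: float | None = None,
) -> DiseaseModel:
    """Model with ``n`` identical loci (shared g0 and rr).

    The posterior then depends only on the number of predisposing genotypes
    carried, which the distribution engine exploits for carrier-count
    arithmetic at any ``n``.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    proto = make_locus(g0, rr, mapping=mapping, prior=prior, weight=weight)
    width = len(str(n - 1))
    loci = tuple(
        LocusEffect(
            locus_id=f"L{str(i).zfill(width)}",
            g0=proto.g0,
            rr=proto.rr,
            g1=proto.g1,
            weight=proto.weight,
        )
        for i in range(n)
    )
    return DiseaseModel(prior=prior, loci=loci, population_mode=mode)


def carrier_probabilities(model: DiseaseModel, mode: str | None = None) -> np.ndarray:
    """Per-locus carrier probability under the stated population mode.

    ``control`` uses g0; ``marginal_independent`` uses the marginal
    g_pop = K*g1 + (1-K)*g0. ``mixture`` has no single per-locus probability
    (the joint is a two-component mixture); callers handle it separately.
    """
    mode = mode or model.population_mode
    if mode == "control":
        return np.array([l.g0 for l in model.loci])
    if mode == "marginal_independent":
        return np.array(
            [population_frequency(l, model.prior) for l in model.loci]
        )
    raise ValidationError(
        f"no single carrier-probability vector for mode {mode!r}"
    )
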