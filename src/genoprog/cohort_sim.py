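"""Seeded cohort simulator matching the generative assumptions of the models.

Disease status is drawn from the prior (or fixed by design for case-control
sampling) and loci are conditionally independent given the status: carriers
arise at frequency g1 in cases and g0 in controls. Multi-class cohorts draw
categorical genotype states from a fitted or constructed
:class:`~genoprog.nb_classifier.ClassTable`. A single integer seed drives a
named generator (numpy PCG64) and is recorded, with the generating model
digest, in the cohort provenance, so identical configurations reproduce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __version__
from .errors import ValidationError
from .model_spec import DiseaseModel
from .nb_classifier import ClassTable, Cohort

GENERATOR = "numpy.random.PCG64"

__all__ = [
    "SimConfig",
    "simulate_population",
    "simulate_case_control",
    "simulate_multiclass",
]


@dataclass(frozen=True)
class SimConfig:
    """Resolved simulation parameters recorded alongside outputs."""

    design: str
    seed: int
    n_subjects: int
    model_digest: str


def _ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"S{str(i).zfill(width)}" for i in range(1, n + 1)])


def _provenance(design: str, seed: int, n: int, digest: str) -> dict:
    return {
        "design": design,
        "seed": int(seed),
        "generator": GENERATOR,
        "n_subjects": int(n),
        "model_digest": digest,
        "package_version": __version__,
    }


def _genotypes_given_labels(model: DiseaseModel, disease: np.ndarray, rng) -> np.ndarray:
    n = disease.size
    g0 = np.array([l.g0 for l in model.loci])
    g1 = np.array([l.g1 for l in model.loci])
    p = np.where(disease[:, None], g1[None, :], g0[None, :])
    return (rng.random((n, model.n_loci)) < p).astype(int)


def simulate_population(model: DiseaseModel, n: int, seed: int) -> Cohort:
    """Population sample: D ~ Bernoulli(prior), loci conditional on D."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    disease = rng.random(n) < model.prior
    genotypes = _genotypes_given_labels(model, disease, rng)
    return Cohort(
        ids=_ids(n),
        genotypes=genotypes,
        labels=disease.astype(int),
        locus_ids=tuple(l.locus_id for l in model.loci),
        provenance=_provenance("population", seed, n, model.digest()),
    )


def simulate_case_control(
    model: DiseaseModel, n_case: int, n_control: int, seed: int
) -> Cohort:
    """Case-control sample with fixed label counts (cases first)."""
    if n_case < 1 or n_control < 1:
        raise ValidationError("n_case and n_control must be >= 1")
    rng = np.random.default_rng(seed)
    disease = np.concatenate([np.ones(n_case, bool), np.zeros(n_control, bool)])
    genotypes = _genotypes_given_labels(model, disease, rng)
    n = n_case + n_control
    return Cohort(
        ids=_ids(n),
        genotypes=genotypes,
        labels=disease.astype(int),
        locus_ids=tuple(l.locus_id for l in model.loci),
        provenance=_provenance("case_control", seed, n, model.digest()),
    )


def simulate_multiclass(table: ClassTable, class_sizes, seed: int) -> Cohort:
    """Cohort drawn from class-conditional categorical genotype frequencies.

    ``class_sizes`` maps each class label of the table to a subject count
    (or is a sequence aligned with ``table.classes``).
    """
    if isinstance(class_sizes, dict):
        sizes = [int(class_sizes[c]) for c in table.classes]
    else:
        sizes = [int(s) for s in class_sizes]
        if len(sizes) != len(table.classes):
            raise ValidationError("class_sizes length must match table classes")
    if any(s < 1 for s in sizes):
        raise ValidationError("every class size must be >= 1")
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.concatenate(
        [np.full(s, c, dtype=object) for c, s in zip(table.classes, sizes)]
    )
    genotypes = np.empty((n, len(table.locus_ids)), dtype=int)
    row = 0
    for ci, s in enumerate(sizes):
        for j, (st, f) in enumerate(zip(table.states, table.freqs)):
            genotypes[row : row + s, j] = rng.choice(
                np.asarray(st), size=s, p=f[ci] / f[ci].sum()
            )
        row += s
    digest = "classtable"
    return Cohort(
        ids=_ids(n),
        genotypes=genotypes,
        labels=labels,
        locus_ids=table.locus_ids,
        provenance=_provenance("multiclass", seed, n, digest),
    )
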