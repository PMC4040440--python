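"""Naive Bayes genotype classifier for binary or multi-class disease labels.

Each locus carries a categorical genotype state (e.g. allele dosage 0/1/2);
states are modeled as conditionally independent given the class. Training
estimates per-locus, per-class state frequencies with an additive
pseudocount, and prediction accumulates log-likelihood ratios, skipping
missing genotypes (which is exact under the factorization). In the binary
case with one carrier/non-carrier state per locus, the classifier posterior
coincides with the posterior probability of disease computed analytically by
:mod:`genoprog.ppd_engine`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError
from .model_spec import DiseaseModel

MISSING = -1

__all__ = [
    "MISSING",
    "Cohort",
    "ClassTable",
    "fit",
    "predict",
    "cross_validate",
    "class_table_from_disease_model",
    "stratified_folds",
]


@dataclass
class Cohort:
    """Genotype matrix with class labels and generation provenance.

    ``genotypes`` is an integer (n_subjects, n_loci) array with ``MISSING``
    (-1) marking unobserved genotypes.
    """

    ids: np.ndarray
    genotypes: np.ndarray
    labels: np.ndarray
    locus_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        self.labels = np.asarray(self.labels)
        self.locus_ids = tuple(self.locus_ids)
        n, m = self.genotypes.shape
        if self.ids.size != n or self.labels.size != n:
            raise ValidationError("ids, labels and genotype rows must agree")
        if len(self.locus_ids) != m:
            raise ValidationError("locus_ids length must match genotype columns")
        if np.any((self.genotypes < MISSING)):
            raise ValidationError("genotype states must be >= 0 or MISSING (-1)")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]


@dataclass(frozen=True)
class ClassTable:
    """Fitted Naive Bayes parameters.

    ``freqs[j]`` is an (n_classes, n_states_j) array of genotype-state
    frequencies at locus j; ``states[j]`` gives the state labels in column
    order. Frequencies at each locus sum to 1 per class.
    """

    classes: tuple
    priors: np.ndarray
    locus_ids: tuple[str, ...]
    states: tuple[tuple[int, ...], ...]
    freqs: tuple[np.ndarray, ...]
    pseudocount: float

    def __post_init__(self) -> None:
        priors = np.asarray(self.priors, dtype=float)
        object.__setattr__(self, "priors", priors)
        object.__setattr__(self, "freqs", tuple(np.asarray(f, float) for f in self.freqs))
        if abs(priors.sum() - 1.0) > 1e-9:
            raise ValidationError(f"class priors must sum to 1, got {priors.sum()}")
        if len(self.locus_ids) != len(self.states) or len(self.states) != len(self.freqs):
            raise ValidationError("locus_ids, states and freqs lengths must agree")
        for lid, st, f in zip(self.locus_ids, self.states, self.freqs):
            if f.shape != (len(self.classes), len(st)):
                raise ValidationError(f"locus {lid!r}: frequency table shape mismatch")
            if np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-9):
                raise ValidationError(f"locus {lid!r}: frequencies must sum to 1 per class")

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes],
                "priors": self.priors.tolist(),
                "locus_ids": list(self.locus_ids),
                "states": [list(map(int, s)) for s in self.states],
                "freqs": [f.tolist() for f in self.freqs],
                "pseudocount": self.pseudocount,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassTable":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            priors=np.asarray(d["priors"], float),
            locus_ids=tuple(d["locus_ids"]),
            states=tuple(tuple(map(int, s)) for s in d["states"]),
            freqs=tuple(np.asarray(f, float) for f in d["freqs"]),
            pseudocount=float(d["pseudocount"]),
        )


def fit(cohort: Cohort, pseudocount: float = 0.5, priors=None) -> ClassTable:
    """Estimate class-conditional genotype-state frequencies.

    frequency = (count + pseudocount) / (class_n_observed + pseudocount *
    n_states), counting only non-missing genotypes per locus. Class priors
    default to class proportions; a locus with all genotypes missing in some
    class is dropped with a warning.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be nonnegative")
    classes = tuple(np.unique(cohort.labels).tolist())
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes to fit a classifier")
    class_masks = [cohort.labels == c for c in classes]
    counts = np.array([m.sum() for m in class_masks], dtype=float)
    if priors is None:
        priors = counts / counts.sum()
    else:
        priors = np.asarray(priors, dtype=float)
        if priors.size != len(classes):
            raise ValidationError("priors length must equal the number of classes")

    locus_ids, states, freqs = [], [], []
    for j, lid in enumerate(cohort.locus_ids):
        col = cohort.genotypes[:, j]
        observed = col != MISSING
        st = np.unique(col[observed])
        if st.size == 0 or any(not (observed & m).any() for m in class_masks):
            warnings.warn(
                f"locus {lid!r}: all genotypes missing in at least one class; dropped",
                stacklevel=2,
            )
            continue
        table = np.empty((len(classes), st.size))
        for ci, mask in enumerate(class_masks):
            vals = col[mask & observed]
            cnt = np.array([(vals == s).sum() for s in st], dtype=float)
            table[ci] = (cnt + pseudocount) / (vals.size + pseudocount * st.size)
            if pseudocount == 0 and vals.size == 0:  # unreachable after the guard
                raise ValidationError(f"locus {lid!r}: empty class with pseudocount 0")
        locus_ids.append(lid)
        states.append(tuple(int(s) for s in st))
        freqs.append(table)
    if not locus_ids:
        raise ValidationError("no usable loci after dropping all-missing loci")
    return ClassTable(
        classes=classes,
        priors=priors,
        locus_ids=tuple(locus_ids),
        states=tuple(states),
        freqs=tuple(freqs),
        pseudocount=pseudocount,
    )


def predict(table: ClassTable, genotypes) -> np.ndarray:
    """Per-class posterior probabilities for a genotype matrix.

    Missing genotypes are skipped (their likelihood factor is marginalized
    out, which is exact under conditional independence). A genotype state
    absent from the fitted table is an error rather than a silent zero.
    """
    g = np.atleast_2d(np.asarray(genotypes, dtype=int))
    if g.shape[1] != len(table.locus_ids):
        raise ValidationError(
            f"genotype columns {g.shape[1]} != table loci {len(table.locus_ids)}"
        )
    n, n_classes = g.shape[0], len(table.classes)
    with np.errstate(divide="ignore"):
        log_prior = np.log(table.priors)
    log_post = np.tile(log_prior, (n, 1))
    for j, (lid, st, f) in enumerate(zip(table.locus_ids, table.states, table.freqs)):
        col = g[:, j]
        observed = col != MISSING
        if not observed.any():
            continue
        st_arr = np.asarray(st)
        idx = np.searchsorted(st_arr, col[observed])
        bad = (idx >= st_arr.size) | (st_arr[np.minimum(idx, st_arr.size - 1)] != col[observed])
        if bad.any():
            unseen = sorted(set(col[observed][bad].tolist()))
            raise ValidationError(
                f"locus {lid!r}: genotype state(s) {unseen} not present in the "
                f"fitted table (fit with a positive pseudocount to allow them)"
            )
        with np.errstate(divide="ignore"):
            log_f = np.log(f)
        log_post[observed] += log_f[:, idx].T
    norm = logsumexp(log_post, axis=1, keepdims=True)
    if np.any(~np.isfinite(norm)):
        raise ValidationError(
            "all classes have zero likelihood for some subject "
            "(zero-frequency state under pseudocount 0)"
        )
    return np.exp(log_post - norm)


def class_table_from_disease_model(model: DiseaseModel) -> ClassTable:
    """Binary ClassTable equivalent to a carrier/non-carrier disease model."""
    freqs = tuple(
        np.array([[1.0 - l.g0, l.g0], [1.0 - l.g1, l.g1]]) for l in model.loci
    )
    return ClassTable(
        classes=(0, 1),
        priors=np.array([1.0 - model.prior, model.prior]),
        locus_ids=tuple(l.locus_id for l in model.loci),
        states=tuple((0, 1) for _ in model.loci),
        freqs=freqs,
        pseudocount=0.0,
    )


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1) per subject."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValidationError(
                f"class {c!r} has {idx.size} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def cross_validate(
    cohort: Cohort,
    k: int = 10,
    seed: int = 0,
    pseudocount: float = 0.5,
    auc_average: str = "macro",
) -> dict:
    """Stratified k-fold cross-validation.

    Returns per-fold and mean top-call accuracy, plus a one-vs-rest AUC on
    the pooled out-of-fold posteriors (macro-averaged over classes by
    default; ``auc_average="micro"`` pools all one-vs-rest decisions).
    """
    from .utility_metrics import auc as _auc

    if auc_average not in ("macro", "micro"):
        raise ValidationError(f"unknown AUC average {auc_average!r}")
    fold = stratified_folds(cohort.labels, k, seed)
    classes = tuple(np.unique(cohort.labels).tolist())
    n = cohort.n_subjects
    posteriors = np.empty((n, len(classes)))
    correct = np.zeros(n, dtype=bool)
    fold_acc = []
    for f in range(k):
        test = fold == f
        train = ~test
        table = fit(
            Cohort(
                ids=cohort.ids[train],
                genotypes=cohort.genotypes[train],
                labels=cohort.labels[train],
                locus_ids=cohort.locus_ids,
                provenance=cohort.provenance,
            ),
            pseudocount=pseudocount,
        )
        if table.classes != classes:
            raise ValidationError("a training fold lost a class; reduce k")
        post = predict(table, cohort.genotypes[test])
        posteriors[test] = post
        calls = np.asarray(classes, dtype=object)[np.argmax(post, axis=1)]
        ok = calls == cohort.labels[test]
        correct[test] = ok
        fold_acc.append(float(ok.mean()))

    y_true = cohort.labels
    aucs = []
    micro_scores, micro_labels = [], []
    for ci, c in enumerate(classes):
        is_c = (y_true == c).astype(int)
        aucs.append(_auc(posteriors[is_c == 1, ci], posteriors[is_c == 0, ci]))
        micro_scores.append(posteriors[:, ci])
        micro_labels.append(is_c)
    if auc_average == "macro":
        auc_value = float(np.mean(aucs))
    else:
        s = np.concatenate(micro_scores)
        l = np.concatenate(micro_labels)
        auc_value = _auc(s[l == 1], s[l == 0])
    return {
        "fold_accuracy": fold_acc,
        "accuracy": float(correct.mean()),
        "auc": auc_value,
        "auc_per_class": dict(zip(map(str, classes), map(float, aucs))),
        "folds": fold,
        "posteriors": posteriors,
        "classes": classes,
    }
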