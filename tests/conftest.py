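import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from genoprog import DiseaseModel, exchangeable_model, make_locus
from genoprog.model_spec import LocusEffect


@pytest.fixture
def single_locus_model():
    """One locus, g0=0.05, rr=2, prior=0.2: hand-checkable posteriors."""
    return exchangeable_model(1, 0.05, 2.0, 0.2)


@pytest.fixture
def null_model():
    """rr=1 everywhere: genotypes carry no information."""
    return exchangeable_model(10, 0.05, 1.0, 0.2)


def random_heterogeneous_model(rng, n_loci, prior=0.2, mode="marginal_independent"):
    """Random valid heterogeneous model for oracle comparisons."""
    loci = []
    for i in range(n_loci):
        g0 = rng.uniform(0.01, 0.4)
        rr = rng.uniform(0.3, min(2.4, 0.99 / g0))
        loci.append(make_locus(g0, rr, locus_id=f"R{i}"))
    return DiseaseModel(prior=prior, loci=tuple(loci), population_mode=mode)


def enumerate_ppd_distribution(model, mode=None):
    """Brute-force oracle: PPD and probability of every 2^n genotype vector.

    Stays independent of the distribution engine: probabilities are built
    directly from per-locus Bernoulli products (mixing over disease status
    for the mixture mode) and posteriors from Bayes' rule on raw products.
    """
    mode = mode or model.population_mode
    prior = model.prior
    g0 = np.array([l.g0 for l in model.loci])
    g1 = np.array([l.g1 for l in model.loci])
    support, mass = [], []
    for states in itertools.product((0, 1), repeat=model.n_loci):
        s = np.array(states)
        p_g0 = np.prod(np.where(s, g0, 1 - g0))
        p_g1 = np.prod(np.where(s, g1, 1 - g1))
        num = prior * p_g1
        den = num + (1 - prior) * p_g0
        support.append(num / den)
        if mode == "control":
            mass.append(p_g0)
        elif mode == "mixture":
            mass.append(prior * p_g1 + (1 - prior) * p_g0)
        else:
            gp = prior * g1 + (1 - prior) * g0
            mass.append(np.prod(np.where(s, gp, 1 - gp)))
    return np.array(support), np.array(mass)


def total_variation(s1, m1, s2, m2, atol=1e-12):
    """TV distance between two discrete distributions, matching support
    values within ``atol``."""
    vals = np.unique(np.concatenate([s1, s2]))
    # merge support values that coincide within atol
    groups = [vals[0]]
    for v in vals[1:]:
        if v - groups[-1] > atol:
            groups.append(v)
    groups = np.array(groups)

    def project(s, m):
        out = np.zeros(groups.size)
        idx = np.searchsorted(groups, s + atol / 2) - 1
        idx = np.clip(idx, 0, groups.size - 1)
        np.add.at(out, idx, m)
        return out

    return 0.5 * np.abs(project(s1, m1) - project(s2, m2)).sum()
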