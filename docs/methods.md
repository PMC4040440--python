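# Methods

## Model

`genoprog` studies how much a panel of susceptibility loci can move the
posterior probability of disease (PPD) away from the prior, and whether that
movement is clinically actionable. A disease model consists of a prior
probability of disease `K = P(D=1)` and `n` loci, each reduced to a binary
carrier state for a predisposing genotype. Conditional on disease status the
loci are independent (the Naive Bayes assumption), with carrier frequency
`g1_i` in cases and `g0_i` in controls. The posterior for a genotype vector
`s` is

    logit(PPD) = logit(K) + sum_i [ s_i ln(g1_i/g0_i) + (1-s_i) ln((1-g1_i)/(1-g0_i)) ]

accumulated in log space, so models up to 100,000 loci evaluate without
underflow. Priors of exactly 0 or 1 short-circuit to the prior.

### From relative risk to case frequency

Inputs specify each locus by `(g0, rr)`. Two mappings to `g1` are provided:

* **freq_ratio** (default): `g1 = rr * g0`, i.e. the relative risk is read as
  the carrier likelihood ratio. Requires `rr * g0 < 1`.
* **epidemiological**: `rr` is the ratio of disease risk in carriers to
  non-carriers. The carrier frequency `g` in the whole population and the
  non-carrier risk are solved from the prevalence-consistent system
  (`K = g*p1 + (1-g)*p0`, `g0 = g(1-p1)/(1-K)`, `p1 = rr*p0`) by fixed-point
  iteration to relative tolerance 1e-12 (max 10,000 iterations), then
  `g1 = g*p1/K`.

The two mappings agree when `rr = 1` (all derived quantities collapse to
their null values) and to first order for small priors and modest effects.
freq_ratio is the default because it reproduces the published threshold
dynamics of the highly polygenic reference architecture (see below); which
convention the original simulations used is not documented, so both are
exposed.

## Population distribution of the posterior

The PPD is a deterministic function of the genotype vector, so its population
density is discrete. Which population the density is taken over matters, and
three constructions are implemented and always labeled in outputs:

* **control** — every locus carried at frequency `g0` (a disease-free
  population);
* **marginal_independent** (default) — every locus independently at its
  marginal frequency `g_pop = K*g1 + (1-K)*g0`;
* **mixture** — the exact generative law: disease status from the prior,
  loci at `g1`/`g0` conditional on status.

marginal_independent is the default because it is the construction that
reproduces both published anchors of the highly polygenic model (C2 climbing
through 80% near per-locus relative risk 1.45 with 1000 loci at `g0 = 0.10`
and prior 0.20, and C1 never exceeding 0.02 across the 1.02–1.80 grid).
mixture is the statistically exact marginal and is the only mode in which
the law of total expectation holds (`E[PPD] = K`, asserted in tests).

Computation routes:

* **Exchangeable models** (all loci share `(g0, g1)`): PPD depends only on
  the carrier count `k`, which is binomial under control and
  marginal_independent modes and a prior-weighted mixture of two binomials
  under mixture mode. Support has at most `n + 1` points; exact for any `n`.
* **Heterogeneous models, `n <= 20`**: exact enumeration of all `2^n`
  log-likelihood-ratio sums.
* **Heterogeneous models, `n > 20`**: dynamic-programming convolution of the
  per-locus two-point log-LR increments on a uniform grid (default 4,096
  bins, minimum 256). A shift by a fractional number of bins is split
  linearly between the adjacent bins, which preserves the mean exactly; the
  worst-case support displacement is `n * width / 2` in log-LR units, and a
  quarter of that on the posterior scale (the logistic function is
  1/4-Lipschitz). The bound is carried on the result as
  `discretization_error`.
* **Monte Carlo** fallback (100,000 draws, explicit seed required) for
  spot-checks.

Equal posterior values are merged exactly, so the support is strictly
ascending and the mass sums to 1 (enforced to 1e-9).

### Thresholds and sweeps

The actionability conditions are strict: C1 holds when `PPD > tau_pos` and
C2 when `PPD < tau_neg` (defaults 0.95 and 0.05). Sweeps over relative risk,
prior, and locus count return plot-ready tables. Priors of exactly 0 or 1 in
a prior sweep are evaluated at `1e-6` and `1 - 1e-6`, since the threshold
analysis is degenerate at the endpoints.

A note on the locus-count sweep: the claim that PPD variance grows with the
number of informative loci is a statement about the generative population —
there the posterior is a martingale in the accumulating genotype
information, so its variance increases toward `K(1-K)`. Under the
marginal_independent population the variance peaks and then falls (almost
all marginal mass ends up near PPD 0 for architectures like `rr = 2`,
`g0 = 0.05`, `K = 0.2`). The monotonicity check therefore runs in mixture
mode; both behaviours are observable through the `mode` argument.

## Utility metrics

* **AUC** is the pairwise probability `P(score_case > score_control) +
  0.5 P(equal)`, computed exactly on discrete distributions via a CDF
  lookup, which on labeled samples coincides with the Mann-Whitney statistic
  with half-weighted ties. The ROC curve calls a result positive when the
  score strictly exceeds the threshold; trapezoidal integration of the curve
  reproduces the AUC.
* **PPV/NPV** follow the Bayes identities on sensitivity, specificity and
  prevalence; their average is reported as a single summary. Zero
  denominators raise an explicit undefined-metric error rather than NaN.
* **NRI** is the net correct movement between ordinal risk categories for
  events minus non-events, in [-2, 2].
* **Kullback-Leibler divergence** (nats) between posterior and prior
  densities, two variants: `weighted` (default) is the population-expected
  Bernoulli KL, `sum_g P(g) [p ln(p/K) + (1-p) ln((1-p)/(1-K))]`, guaranteed
  nonnegative and zero iff the posterior is everywhere the prior. `literal`
  sums only `p ln(p/K)` with no population weighting — the form sometimes
  quoted in the applied literature — evaluated with one term per distinct
  posterior value; it is not a proper divergence and is provided for
  comparability only. Outputs are always labeled by variant.

## Risk scores and calibration

`GRS = sum_i w_i R_i` with allele counts `R_i in {0,1,2}`; unweighted scores
set `w_i = 1`. Quantile stratification produces `q` near-equal bins (bin 1 =
lowest scores); with `n = qb + r` subjects the lowest `r` bins take the extra
subject, and ties are broken by stable input order — both choices made for
determinism since no convention is standard. Fold-risk per bin is cumulative
incidence (cases/total) relative to a reference bin, computed with exact
rational arithmetic before the final division; odds ratios are a trivial
caller-side variation and were left out of the core API.

Case-control logistic intercepts are calibrated to a target population by
`beta0_pop = beta0_cc - ln(n_case/n_control) + logit(prevalence)`, removing
the sampling odds and installing the population odds.

## Naive Bayes classifier

Genotypes are categorical states per locus (missing allowed). Fitting counts
states per class with an additive pseudocount (default 0.5 per state, a
Jeffreys-style choice; the comparison software's default is undocumented):
`(count + a) / (n_observed + a * n_states)`. Missing genotypes are excluded
from counts, and a locus with no observations in some class is dropped with
a warning. Prediction runs in log space, skips missing loci (exact under the
factorization), and errs on states absent from the fitted table rather than
silently zeroing them. In the binary carrier/non-carrier case the classifier
posterior equals the analytic PPD to 1e-12 (asserted in tests).

Cross-validation uses stratified folds with seeded shuffling (fold
construction in the source experiment is undocumented, so determinism was
prioritized); accuracy is the proportion of correct top-posterior calls —
the 3-class "accuracy" definition in the source material is ambiguous
between per-class and overall, and overall top-call accuracy is implemented.
The cross-validated AUC is one-vs-rest on pooled out-of-fold posteriors,
macro-averaged by default (micro available), which is the natural reading of
an "average AUC" over classes.

## Cohort simulator

The simulator emulates exactly the generative structure the analytic engine
assumes: disease status from the prior (or fixed counts for case-control
designs), loci conditionally independent given status, categorical states
from class tables for multi-class designs. One integer seed drives numpy's
PCG64 generator; seed, generator name, model digest and design are written
into cohort provenance, and identical configurations give byte-identical
files. It deliberately omits linkage disequilibrium, covariates,
genotyping error and population structure — so passing simulation-based
tests demonstrates internal consistency of the method chain, not performance
on real cohorts, where conditional independence is at best approximate.

## Problem sizes and tolerances in the shipped checks

Oracle equivalence compares the engine against exhaustive `2^n` enumeration
at `n = 10–12` (total variation < 1e-6). Monte-Carlo agreement uses 100,000
simulated subjects against analytic mixture-mode C1/C2 fractions within 3
binomial standard errors. Classifier recovery fits 50,000 subjects (every
frequency within 3 SE in the fixed-seed tests; the acceptance script reports
the RMS z-score over all 36 frequencies, ~1 for an unbiased estimator).
Intercept-calibration recovery averages 5 seeds of 4,000-subject
case-control fits applied to 20,000-subject populations. The permutation
null runs 10-fold CV on 5,000 label-shuffled subjects (AUC within 0.03 of
0.5).

## Known limitations

* Binary carrier abstraction in the analytic engine (the classifier handles
  multi-state genotypes); no allele-dosage penetrance within the PPD path.
* No linkage disequilibrium or epistasis anywhere; conditional independence
  is the modeling premise, not a finding.
* The grid convolution reports a worst-case, not actual, discretization
  bound; resolution should be raised for models mixing very large and very
  small effects.
* Published external-cohort results (biobank AUCs, fold-risks from consortium
  GRS panels) depend on data not distributed with their sources and are out
  of reproduction scope; the property-based checks above stand in for them.
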