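# Methods

This note documents the statistical machinery, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want stated.

## Calibration model

Item responses are modelled by the generalized partial credit model
(GPCM). For item *i* with categories 0..*m*, P_ik(θ) ∝
exp(Σ_{v≤k} a_i(θ − b_iv)); the step thresholds b_iv are not required to
be ordered (reversed steps are legitimate GPCM solutions). Probabilities
are computed with log-sum-exp stabilization, so logits up to |a·θ| ≈ 700
do not overflow.

Estimation is marginal maximum likelihood via EM. The latent trait is
integrated over a fixed grid of 61 equally spaced nodes on [−6, 6] with
N(0,1) prior weights renormalized to sum to one; this fixes the latent
scale (no post-hoc standardization of parameters). The E-step computes
each respondent's posterior over nodes, skipping missing responses in the
likelihood product; the M-step maximizes the expected complete-data
log-likelihood per item by bounded quasi-Newton (analytic gradients),
with discriminations confined to [0.05, 10] — an estimate at the upper
bound is reported as clamped, never silently accepted. Convergence is
declared when no parameter moves by more than 1e−4 between cycles, with a
500-cycle cap; non-convergence is flagged in the fit summary. The
marginal log-likelihood is non-decreasing across cycles (asserted in
tests). The PCM variant estimates a single common discrimination shared
by all items (updated by a one-dimensional search each cycle), which
makes the GPCM–PCM likelihood-ratio test well defined with
df = n_items − 1.

Person scores are EAP means on the same grid, with the posterior SD as
the standard error; an empty response set returns the prior (θ̂ = 0,
se = 1). The 0–100 reporting scale is the affine map θ ↦ 50 + 12.5·θ,
clipped — i.e. θ = ±4 anchors the endpoints. The source study does not
state its transformation constants, so this symmetric convention was
chosen once; the constants are stored in the bank JSON so any other
convention can be loaded.

Item fit uses plug-in EAP estimates (not jointly re-estimated θ):
infit_i = Σ(x − E)²/ΣW (information-weighted) and outfit_i = mean of
(x − E)²/W, with E and W the conditional mean and variance of the item
score at θ̂. Fisher information is I_i(θ) = a_i²·Var(K|θ); the test curve
is the sum over items, integrated by trapezoid on 241 points over [−6, 6]
for the share-in-range statistic.

## Screening and recoding

The redundancy screen computes pairwise-complete Pearson correlations of
the observed codes (polychoric correlations are available separately but
the descriptive screen follows common practice on raw codes) and removes
items iteratively: the item in the most pairs with r > 0.70 goes first,
ties broken by the smaller corrected item-total correlation, until no
pair exceeds the ceiling. Screening the survivors removes nothing
(idempotence). Constant items are removed up front with reason "zero
variance". Cronbach's α uses listwise-complete rows (the n actually used
is logged); correlations use pairwise deletion — each statistic states
its policy.

Sparse response categories are merged by a deterministic count rule
replacing the source study's visual inspection of item characteristic
curves: any category observed fewer than 10 times merges into the
adjacent category with the fewer observations (ties merge downward),
re-indexing codes to stay contiguous; a user-supplied map can override
the rule per item. Collapsing an item below two categories is an error.

## Dimensionality diagnostics

Unidimensionality is judged on three mutually supporting diagnostics
rather than a confirmatory SEM fit (WLSMV-style CFA indices are out of
scope; estimator internals make their exact values software-specific):

- eigenvalues of the polychoric correlation matrix and the λ1/λ2 ratio
  (default verdict threshold: ratio > 4);
- permutation parallel analysis: observed eigenvalues against the 95th
  percentile of eigenvalues from column-permuted data (marginals
  preserved), counted sequentially from the top. The permuted-data
  comparison uses Pearson correlations on both sides for tractability at
  100 replicates;
- exploratory bifactor indices: a minres EFA of the polychoric matrix
  with the requested number of group factors, promax-rotated, then
  Schmid–Leiman orthogonalized via a one-factor model on the primary
  factor correlations (with two primaries the second-order loadings use
  the √φ convention). ω_h = (Σ general loadings)²/model-implied total
  variance; ECV splits the common variance between general and group
  factors and sums to 100 by construction. Heywood cases are rescaled to
  unit communality and flagged.

Polychoric correlations are two-stage ML: thresholds from the marginals,
then ρ by bounded univariate likelihood optimization, with the bivariate
normal CDF evaluated by 24-point Gauss–Legendre quadrature of the
correlation integral (matches scipy's CDF to ~1e−10 but is vectorized).
Degenerate pairs fall back to Pearson with a warning. The varimax step
inside the rotation chain delegates to statsmodels' GPA rotation; promax
and Schmid–Leiman are implemented here and were validated against an R
factanal + promax reference during development.

A caveat measured during development and reflected in the tests: when
data are strictly unidimensional, forcing two group factors lets a
spurious singleton capture the second factor in roughly half of samples,
deflating exploratory-SL ω_h from its true ~0.95 to ~0.75 (R's
factanal + promax chain shows the same degeneracy). ω_h from this module
is therefore a conservative dominance index, not an unbiased estimate,
and the tests assert dominance (ω_h > 0.7, ECV > 70%) for pure
one-factor data rather than purity.

Local independence uses Yen's Q3: residuals x − E(θ̂) with plug-in EAP
estimates, correlated across item pairs (pairwise-complete), flagged at
|Q3| ≥ 0.20. No Q3* bias offset is applied; because plug-in Q3 is biased
by about −1/(k − 1), the maximum over 171 pairs crosses 0.20 in a
nontrivial minority of null samples at n = 499 — the flag threshold is a
screen, not a test with a controlled error rate.

Monotonicity bins respondents into rest-score deciles (rest score = mean
of the other observed items, on rows where the item is observed) and
counts adjacent-bin decreases in the mean item score beyond 0.05.

## Differential item functioning

For each item and grouping, three nested proportional-odds models are fit
on the item response: M1 (θ̂), M2 (θ̂ + group), M3 (θ̂ + group + θ̂ ×
group); multi-level groupings enter as indicator sets and the LRT degrees
of freedom scale accordingly. Overall DIF is M1 vs M3 at α = 0.01 (the
lordif convention); magnitude is McFadden ΔR² = (LL3 − LL1)/(−LL0)
against the intercept-only model, with 0.035 (Jodoin–Gierl) separating
"negligible" from "salient". The θ̂ used is the all-item EAP score,
without purification. The proportional-odds likelihood is maximized by
Newton–Raphson with step-halving (Hessian from finite differences of the
analytic gradient); fits that fail to converge (e.g. separation) mark the
item "untestable" rather than raising. The fitter agrees with
statsmodels' OrderedModel to ~1e−4 in log-likelihood on random data (the
cross-check lives in the test suite, keeping implementation and oracle
independent).

## CAT engine

Selection is maximum Fisher information at the current EAP estimate; the
first item is chosen at the prior mean θ = 0, ties break to the lowest
bank index. Interim and final scoring reuse the calibration quadrature
and prior, and the stopping SEM is the EAP posterior SD (not 1/√I),
keeping the scoring chain consistent; the session stops once se falls
below the threshold (after a minimum of 1 item), the bank is exhausted,
or an item cap is hit. A "not applicable" answer excludes the item
without rescoring and the next-best item is chosen. No exposure control
or content balancing is implemented. The study harness supports replay
(recorded response vectors) and generative (fresh GPCM draws at
θ ~ N(0,1)) modes and reports, per SEM scenario, the mean ± SD of the
transformed CAT score, Pearson r and θ-metric RMSE against full-bank EAP
scores (the reference the source study used), and the mean number of
items; generative mode can additionally report accuracy against the true
simulated θ.

## Synthetic data generator

The generator draws θ ~ N(0,1), samples each response from the exact GPCM
category distribution at the respondent's θ, applies
missing-completely-at-random cells, attaches categorical covariates, and
can inject DIF per item as a uniform threshold shift and/or a
discrimination multiplier for one covariate level. A single integer seed
determines everything. The study-like preset uses n = 499 respondents and
19 five-category items with a ~ U(1.0, 2.8) and four ordered thresholds
per item drawn uniformly on [−2.5, 1.5]; covariate margins mirror the
validation sample (sex ~50/50, age median split, 80/20
outpatient/inpatient, diagnosis 53/26/21).

The redundancy fixture appends six near-copy items: each copy reuses its
source's latent response quantile evaluated at θ + N(0, 0.3), which
pushes the copy–source correlation far above the 0.70 ceiling. Because
the screened study bank is non-redundant by definition, the fixture's
base bank caps a at 2.2 and is redrawn (deterministically under the seed)
until no base pair exceeds 0.70 in the realized sample — two strong GPCM
items can otherwise cross the ceiling through the common trait alone. A
limitation that follows from the same arithmetic: a 0.3-noise copy's
item-total correlation sits only a few percent below its source's, so
which member of a redundant pair the tie-break removes is
sample-dependent; the guaranteed invariant is one removal per planted
pair (six removals, nineteen survivors).

What the generator does not emulate: informative missingness (MCAR only),
multidimensional structure beyond planted nuisance factors, response
styles (acquiescence, extreme responding), and the response-bias
differences between recruitment channels reported for the real sample.
Passing tests therefore demonstrate the correctness of the machinery
under the model's own assumptions, not robustness to their violation.

## Problem sizes and known limitations

Simulation-backed tests use 10–200 replicates at the study's n = 499
(parameter recovery: 20 replicates; DIF type-I: 200 replicates × 19 items
on one grouping; DIF power: 200 replicates of the planted item; CAT
table: n = 500 × 3 scenarios × 3 replicates), sizes chosen so the whole
suite runs in minutes on one CPU while leaving the binomial/RMSE bounds
meaningful. The acceptance script scales the same computations to about a
minute (5 recovery replicates, 60 DIF replicates).

The real instrument's calibrated parameters are not distributed with the
package (the study data are available only on demand), so quantities that
depend on the actual bank — the published mean items per CAT session
(8.13/4.35/2.43) and the 61.0% information share in [−2, 2] — are not
reproduced by the synthetic preset, whose items are more discriminating
and more centrally concentrated than the real ones: it yields ~4.4 mean
items at SEM < 0.33 and an ~81% central information share, while matching
the published accuracy (r) and precision (RMSE) profile closely. Loading
a real calibrated bank JSON reproduces the full chain unchanged.
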