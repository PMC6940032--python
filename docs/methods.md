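# Methods

This note documents the models implemented in `irtqol`, the numerical and
design choices behind them, what the synthetic-data generator does and
does not emulate, and the problem sizes used by the test suite and the
acceptance script. It states no empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Measurement model

Item responses are ordinal codes 0…K−1 (K may differ per item; missing is
a dedicated sentinel). The functional model is the logistic graded
response model (GRM) in slope–intercept parameterization:

    P*(x_j >= k | theta) = expit(a_j . theta + d_jk),   k = 1..K-1,

with cumulative ("step") probabilities decreasing in k because the
intercepts d_j1 > … > d_j,K−1 are strictly ordered, and category
probabilities P(x_j = k) = P\*(≥k) − P\*(≥k+1). No logistic scaling
constant is applied; the likelihood is purely logistic, and the
normal-ogive constant 1.702 appears only in the standardized-loading
conversion (below). For K = 2 the model is exactly the two-parameter
logistic model; a deliberately separate 2PL code path exists solely as a
cross-check of this nesting. For unidimensional reporting, difficulties
are b_k = −d_k/a.

The slope-intercept form was chosen over the difficulty form because it
extends unchanged to multidimensional structures. The cumulative-logit
sign convention used here (positive intercept ⇒ step easily passed at
theta = 0) is stated explicitly because conventions differ across
software; all shipped parameter tables and serializations use it.

Assumptions inherited from the framework: conditional independence of
items given the latent vector, the logistic item-trait link, and a
multivariate normal latent distribution (standard normal margins; scale
fixed by the prior, so all latent variances are 1 and factor means 0).

## Latent structures

Four confirmatory families are supported: unidimensional;
correlated-traits (item clusters load on separate, mutually correlated
group factors); bifactor (one general factor for all items plus exactly
one orthogonal specific factor per item); and two-tier (several general
factors, orthogonal or oblique, plus orthogonal specifics). Specific
factors must partition the items — that is what makes dimension
reduction exact. A second-order model is a constrained two-tier model
and is intentionally not a separate code path. Named candidate sets per
instrument (16 for SF-36, 1 for EQ-5D, 9 for HADS) ship as presets; the
candidates beyond the handful the evaluation protocol describes
explicitly are documented reconstructions of structures the instruments'
literatures discuss, not ground truth.

A `positive_loadings` flag bounds every free slope at zero during
optimization; a slope estimated at the bound is reported as 0 with a
boundary note. This mirrors refitting a model "with loadings limited to
positive values" without changing the likelihood's form.

## Estimation

**Marginal maximum likelihood by EM.** The observed-data likelihood
integrates the conditional response probabilities over the latent prior.
Integration uses a fixed, equally spaced rectangular grid on ±6 per
dimension with (multivariate) normal weights renormalized to sum to one —
defaults 61/21/11 nodes per dimension for 1/2/3 integral dimensions. With
cluster-partitioned specifics, clusters are conditionally independent
given the generals, so the marginal likelihood factorizes as

    L(x) = ∫ phi(g) prod_c [ ∫ phi(s) prod_{j in c} P_j(x_j | g, s) ds ] dg,

capping the integral dimension at n_general + 1 (= 3 for every shipped
structure). A structure whose integral dimension exceeds 3 is rejected
rather than approximated: stochastic-approximation estimators for
higher-dimensional integrals are out of scope. The reduction is verified
in the tests against naive full-tensor-grid quadrature to 1e−6 relative
(it agrees to machine precision).

**E-step.** Response patterns are collapsed to unique rows with counts.
Within-cluster products of at most ~10 category probabilities are
computed in linear space (they cannot underflow float64 given the
grid's bounded linear predictors) and integrated over the specific grid
by matrix product; cross-node combination happens in log space.

**M-step.** Per item, a bounded quasi-Newton (L-BFGS-B) update of the
expected complete-data log-likelihood with analytic gradients, in a
parameterization with log-transformed intercept gaps so the intercept
ordering is enforced by construction rather than by post-hoc sorting.
The inner update is truncated (generalized EM); a candidate that does
not improve the expected log-likelihood is rejected, so every cycle is
monotone. Oblique general-tier correlations are updated by an exact
constrained M-step: the posterior-weighted log prior of the grid
(including its normalization) is maximized over correlation matrices
parameterized by hyperspherical Cholesky angles, and the update is
accepted only when it improves that objective. This preserves EM
monotonicity, which an unconstrained covariance update rescaled to a
correlation matrix would not.

**Acceleration.** Plain EM crawls near the optimum. Each cycle after the
third takes an over-relaxed step — the EM step scaled by an adaptive
factor (from 2, grown while steps keep succeeding) in the
slope/ordered-intercept parameterization — and the next E-step falls
back to the un-relaxed update whenever the log-likelihood would drop.
Monotonicity of the recorded log-likelihood history is asserted by the
tests for every fit (tolerance 1e−8).

**Starting values and identification.** Intercepts start at the logits
of observed cumulative category proportions; slopes at 1.0 on permitted
general loadings and 0.5 on specifics, multiplied by a small jitter drawn
deterministically from the fit's seed. The jitter matters: with exactly
symmetric starting values the EM map preserves the exchange symmetry
between the general factors of a two-tier structure, and the iteration
converges onto a degenerate invariant manifold where the generals
coincide and the specifics absorb the cluster variance. Note also that an
orthogonal two-tier structure in which every item loads on every general
factor identifies the general block only up to rotation (the likelihood
is rotation-invariant there); parameter-recovery checks therefore align
the general plane by orthogonal Procrustes before comparing, and each
specific factor's sign (indeterminate as well) is aligned by the loading
product.

**Convergence and missing data.** Convergence is declared when the
absolute change in marginal log-likelihood falls below `tol` (default
1e−4) within `max_iter` (default 500); non-convergence is returned as a
flag, never silently. Missing responses are ignorable (MAR) and skipped
in the likelihood; persons with no observed responses are dropped with a
logged count. Grid size, bounds, tolerances, and iteration caps are all
function arguments, not constants.

## Fit statistics

**Information criteria.** AIC = −2ℓ + 2q, BIC = −2ℓ + q·log N, with q the
count of free slopes + free intercepts + free correlations.

**Limited-information M2.** Computed on all univariate and bivariate
category margins with category 0 dropped (full cross-classification of
pairs). The statistic is N·e'Ce with e the observed-minus-implied margin
vector, C the inverse margin covariance projected off the model's
tangent space (Jacobian columns per free item parameter, analytic;
correlation parameters by central finite differences in the
Cholesky-angle parameterization), df = #margins − q, and a chi-square
reference. For a model evaluated with frozen (training) parameters no
projection is applied and df = #margins. The margin covariance needs
joint probabilities of up to four items, computed under the same
dimension reduction as the likelihood. Complete cases only: the
multinomial asymptotics of margin proportions assume a common N. The
construction cost grows with the square of the margin count, which makes
it practical up to roughly 20 mixed-category items — enough for EQ-5D and
HADS; for SF-36-sized scales the information criteria, residual
correlations, and SRMSR remain available. Type-I error of the statistic
is verified near nominal by simulation (200 replicates), and its power
against fitting bifactor data unidimensionally is verified ≥ 0.9.

**Derived indices.** RMSEA = sqrt(max(M2−df,0)/(df(N−1))) with a 90%
interval by noncentrality inversion at the 5th/95th percentiles;
TLI/CFI against an independence null (same structure, all slopes fixed
at 0, intercepts at the closed-form observed-margin MLEs). SRMSR and the
residual-correlation matrix compare observed and model-implied
product-moment correlations of raw 0…K−1 item scores (not polychorics;
a declared convention, with the polychoric variant a possible
extension). Residual-correlation summaries report the mean absolute
off-diagonal value, the count beyond a threshold (default 0.05) and the
maximum.

**Item fit.** For unidimensional models, a rest-score S-X2-type
statistic: the polytomous Lord–Wingersky recursion gives the rest-score
distribution over the grid, persons are grouped by rest score, and a
Pearson statistic compares observed to expected category counts with
adjacent score groups pooled until every expected cell is ≥ 1;
df = (#cells after pooling − #groups) − #item parameters. The recursion
is verified exactly against exhaustive pattern enumeration. For
multidimensional models the observed-vs-expected table by trait level is
the designated tool. That table conditions strictly on the *other* items
(leave-one-out EAP binning and leave-one-out posterior expectations):
conditioning on the studied item's own response makes even a correctly
specified model look misfitting, because bin membership and expectation
would then both depend on the response being predicted.

**Person fit.** Zh = (ℓ0 − E[ℓ0])/sd(ℓ0) at the person's trait estimate,
with moments over the model's category distributions and non-missing
items only; |Zh| < 2 is the conventional acceptability band (negative =
unpredictable, positive = overly deterministic). The statistic is exactly
calibrated at known theta (verified by enumeration and simulation). At
plug-in EAP/MAP estimates it acquires a positive mean bias (about +0.2
at 20 items in our simulations) because the estimate adapts to the same
responses the statistic evaluates — a known property of plug-in person
fit, flagged here as a limitation; the calibration study therefore
evaluates the statistic at the generating trait values.

## Scoring

EAP scores are posterior means with posterior-SD standard errors,
computed on the reduced grids (general-grid posterior for generals,
joint general × specific posterior per cluster for specifics). MAP
scores maximize the log posterior by vectorized damped Newton with
analytic Hessians, initialized at the EAP solution, with SEs from the
inverse curvature at the mode. The protocol switch — EAP for up to two
integral dimensions, MAP above — is the default of `irt_scores` and
overridable.

Empirical reliability of a factor is var(θ̂)/(var(θ̂) + mean SE²); it is
verified within 0.05 of the analytic marginal reliability
∫ I(θ)/(I(θ)+1) φ(θ) dθ at N = 5000. Standardized loadings convert
logistic slopes via λ_f = (a_f/1.702)/sqrt(1 + Σ_f (a_f/1.702)²); ECV of
a general factor is Σ_items λ_g² / Σ_items Σ_f λ_f². Note that ECV is
*not* exactly invariant to rescaling all slopes by a constant — the
per-item communalities reweight the sums — although each item's loading
direction is; the tests assert the latter, and verify the ECV formula
itself against the brute-force matrix computation. Score correlations
(convergent/discriminant validity) use complete cases by default, with a
pairwise-complete option, and report the n used.

## Cross-validation

Persons are split into k (default 5) random near-equal folds. Per fold:
fit on the other k−1 folds; evaluate the held-out fold with training
parameters frozen (marginal log-likelihood plus frozen-df M2 indices);
refit on the held-out fold without additional constraints; report
per-parameter deltas (standardized loadings; intercepts in logits) after
matching factors by structure position and flipping any factor whose
summed loading product is negative; and report the fraction of
validation persons whose general-factor scores move by less than one
(training-parameter) standard error between the two parameterizations.
Non-converging folds are flagged and the remaining folds proceed.

## Conventional scores

All coefficients live in editable YAML configs, never code. The EQ-5D
value set shipped is the published UK time-trade-off (MVH) tariff —
full-health 1.0, any-dysfunction constant 0.081, N3 term 0.269, and
per-dimension level decrements — whose anchors (1.0 for state 11111,
−0.594 for 33333) the tests recompute exhaustively over all 243 states.
SF-36 subscales use RAND-style linear 0–100 recoding of pre-keyed items
with the half-scale missing rule; the health-transition item is grouped
with general health to match the latent clustering, and the config notes
where licensed scorings differ. The component-summary weights are a
clearly labelled *synthetic* stand-in with the correct structure
(physical subscales weight positively on the physical summary and
slightly negatively on the mental one, and vice versa) because the
published norm coefficients are licensed; users substitute their own
file for norm-based scoring. HADS sums use the original alternating
item assignment, 0–21 per subscale, with no proration.

## Synthetic data

The generator draws latent vectors from the structure's prior, draws
responses from the GRM at each person's theta, and blanks cells
completely at random. Presets emulate the three instruments as fielded
in a large chronic-pain rehabilitation registry: SF-36 (36 items with
2/3/5/6 categories, two-tier with 2 orthogonal generals + 8 subscale
specifics, 15.9% partial missingness), EQ-5D (5 items, 3 categories,
unidimensional, 2.1%), HADS (14 items, 4 categories, bifactor with
anxiety/depression specifics, 5.4%); default n_persons is the registry
scale (35,908). Preset item parameters are *reconstructions* drawn once
from fixed plausible ranges (general slopes clearly dominant over
specifics; spread thresholds; EQ-5D margins shifted toward reporting
problems, most strongly for pain) with a fixed internal seed — identical
on every call and independent of user seeds.

A `sf36_reduced` preset (12 items, 2 generals + 4 specifics) is the
speed-scaled stand-in for two-tier studies. It samples three items from
each of four *polytomous* subscales: a cluster of three binary items
cannot pin down its specific factor at desk-scale N (we measured
specific-slope RMSE ≈ 0.36 with such a cluster at N = 2500), so the
reduced design uses the category-rich subscales.

What the generator does **not** emulate: informative (MAR/MNAR)
missingness — cells are MCAR, so tests say nothing about missingness
sensitivity; response styles, local dependence beyond the modeled
specifics, or DIF across subgroups; the registry's exact margins or
parameter values. Passing tests therefore demonstrate that the pipeline
is correct and well calibrated *under its own assumptions*, not that any
particular real questionnaire satisfies them.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is sharply testable: parameter
recovery and cross-validation at N = 2000–5000; M2 type-I error with 200
replicates of N = 500 (100 in the acceptance script); power and
model-selection studies with 30–50 replicates at N = 500–1000;
registry-scale simulation (N = 35,000) only for the category-coverage
screen, where no fitting is involved. Replicated studies use a relaxed
EM tolerance (1e−3) since their conclusions rest on likelihood
differences orders of magnitude larger.

## Known limitations

* No item-parameter standard errors (cross-validation supplies stability
  evidence instead); no measurement invariance / DIF machinery; no
  MH-RM, so genuinely ≥ 4-dimensional integrals are out of reach.
* M2 cost limits it to ~20 items; polychoric-based SRMSR variants are
  not implemented.
* Zh at plug-in trait estimates is biased upward (documented above).
* The rectangular grid with renormalized weights loses accuracy for
  |correlations| near 1 in oblique structures and for extreme slopes
  (> ~6) that concentrate posteriors between nodes.
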