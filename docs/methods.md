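# Methods

## Model

`bifcat` works with the bifactor graded response model (GRM) for ordinal
items. Latent traits are `θ = (θ_0, θ_1, …, θ_G)`: one general dimension
(index 0) and `G` group dimensions, all mutually uncorrelated and standard
normal. Each item loads on the general dimension and on at most one group
dimension, giving the linear score `z = a_g θ_0 + a_s θ_s`. Boundary
("operating characteristic") probabilities use the logistic link with no
scaling constant,

    P*_k(θ) = expit(z + d_k),  k = 1..K−1,   P*_0 = 1, P*_K = 0,

and category probabilities are the telescoping differences
`P_k = P*_k − P*_{k+1}`. Strictly decreasing intercepts `d_k` guarantee
nonnegative probabilities; the general slope is constrained positive to
fix the reflection of the general factor, and each group factor is
oriented so the sum of its slopes is positive. Parameters are stored in
slope–intercept form; difficulty-style tables (`b_k` increasing) are
converted by `d_k = −b_k‖a‖` with `‖a‖` the Euclidean norm of the item's
loading vector, and categories are coded 0-based internally.

The item Fisher information is rank one: with `q_k = P*_k(1 − P*_k)`
(`q_0 = q_K = 0`) and `w(z) = Σ_k (q_k − q_{k+1})² / P_k`, the matrix is
`w(z)·a aᵀ` on the item's two loaded dimensions. A floor of 1e-10 on
category probabilities inside logarithms prevents −∞ likelihoods at
extreme traits.

## Calibration

Estimation is marginal maximum likelihood by Bock–Aitkin EM with the
bifactor dimension reduction: the person likelihood factors into a
product over group factors of integrals that involve only `(θ_0, θ_s)`,
so only 1-D and 2-D quadrature grids are needed for any `G`. Quadrature
uses 21 equally spaced points per dimension on [−6, 6] with renormalized
normal-density weights — standard practice, accurate for slopes up to
about 5. Missing responses contribute nothing to the likelihood
(full-information treatment; no imputation).

The M-step maximizes each item's expected complete-data log-likelihood by
L-BFGS with analytic gradients, parameterizing the intercepts as
`(d_1, log decrements)` so monotonicity is maintained by construction.
EM stops when the largest absolute parameter change falls below 1e-4 or
the log-likelihood change below 1e-6, capped at 500 cycles; hitting the
cap flags the result as non-converged rather than returning silently.
Categories unobserved in the data are collapsed into the adjacent lower
category with a warning (strict mode raises instead). Initial values are
unit general slopes, 0.5 group slopes, and intercepts from empirical
cumulative proportions.

A known limitation: when a fitted group factor has no true variance
(all its true slopes are zero), individual group slopes are only weakly
identified — a single item's `(a_g, a_s)` pair can drift along a
likelihood ridge with negligible likelihood gain, so estimates of such
"empty" group factors should not be over-interpreted. When the structure
maps every item to the general factor the estimator reduces exactly to a
unidimensional GRM EM; the test suite verifies this reduction against an
independently coded 1-D estimator (agreement to ~1e-3).

## Local dependence and fit

Yen's Q3 is computed from residuals `x_ji − E_i(θ̂_j)`, where `E_i` is the
model-implied expected score and `θ̂_j` the full-pattern MAP estimate
(matching the scoring engine); Q3 of a pair is the Pearson correlation of
the residual columns over persons with both items observed (pairs with
fewer than three joint observations are reported unavailable). Flagging
uses the signed value above 0.20 by default, with an absolute-value
option. Flagged pairs are resolved greedily in descending Q3 order,
skipping pairs already resolved; within a pair the member with the lower
*prior-integrated information* — the trace of the item information matrix
averaged over the standard-normal prior on the item's loaded dimensions —
is removed (ties drop the later bank item). Integration, rather than a
point evaluation at θ = 0, reflects that the comparison concerns the whole
information function.

SRMSR is the root mean squared difference between observed
(pairwise-complete Pearson) and model-implied inter-item correlations;
model moments integrate over the dimensions a pair shares (a 2-D grid for
same-group pairs, the general dimension with group factors integrated out
otherwise). Limited-information fit statistics (M2-based RMSEA/CFI) and
item-level S-X2 are out of scope.

## Scoring and item selection

Trait estimates are multidimensional MAP: the mode of
`log L(θ) − ½‖θ‖²` under the fixed MVN(0, I) prior that matches bifactor
orthogonality. The optimizer is damped Newton on the observed Hessian with
a Fisher-scoring fallback whenever the observed Hessian is not positive
definite, backtracking line search, a [−6, 6] box per dimension (the
quadrature support), and a gradient tolerance of 1e-8; dimensions with no
administered information remain at the prior mode. Non-convergence raises
with diagnostics rather than returning a value.

The posterior information matrix is the prior precision (identity) plus
the accumulated item information at `θ̂`, in the expected-information
convention by default (observed information is available behind a
switch); squared standard errors are the diagonal of its inverse. Item
selection is the determinant rule: among unadministered items, maximize
`det(J + w_i a_i a_iᵀ) = det(J)(1 + w_i a_iᵀ J⁻¹ a_i)`, which the engine
evaluates through the rank-one identity (ties break to the lowest bank
index). With an empty state the rule is evaluated at θ = 0 with
prior-only information, so every respondent starts with the same item.

## Stopping rules

The bundled design crosses three criteria (2×2×2) plus a no-rule "full"
row: general-factor SE threshold 0.32 or 0.40, group-factor SE threshold
0.50 applied to every group dimension or absent, and a trait-change
threshold of 0.01 or absent. By `reliability = 1 − SE²` the thresholds
0.50, 0.32 and 0.40 correspond to reliabilities 0.75, 0.90 (rounded) and
0.84 — the last is conventionally quoted as the 0.85 target although the
formula gives 0.84 exactly. All inequalities are strict ("dropped
below"). The SE rule fires only when the general SE and, if set, every
group SE are below threshold; the change rule needs at least two
administered items (a previous estimate must exist) and compares the
maximal absolute change across *all* dimensions; the rules combine as a
disjunction, and rules are checked after every response including the
first. The SE of a never-probed group factor equals the prior SE of 1,
which is why a 0.50 group threshold mechanically forces sampling from
every group factor and, with small group factors, tends to exhaust the
bank. The engine draws no random numbers: identical inputs give identical
administrations.

## Synthetic data

The generator emulates the study conditions of a 44-item bifactor HRQOL
bank: ten group factors with 6/4/3/3/5/4/5/3/4/4 items (physical
function, role-physical, role-emotional, pain, emotional well-being,
energy, health perceptions, cognitive, health distress, sexual function)
plus three general-only items whose group assignment is treated as
unresolved; general slopes uniform on [0.92, 4.71] and group slopes on
[0.56, 5.19] (the calibrated ranges of the motivating instrument);
boundary difficulties drawn with guaranteed minimum gaps over [−2.5, 2.5]
and converted to intercepts; mixed 2/3/5/6-point formats. Traits are
independent standard normals (`n` respondents × `G+1` dimensions) and
responses are sampled from the model's category distributions; traits,
bank, and responses take separate seeds so the streams are independent.

What the generator does *not* emulate: the covariate structure of a real
clinical sample (age, disability, language), non-normal or correlated
traits, real-data misfit, and realistic missingness mechanisms (only
missing-completely-at-random thinning is provided for exercising the
estimator). Uniform slope draws also make the default synthetic bank more
informative on average than a typical calibrated bank, so adaptive runs
on it stop earlier (median ≈ 15 items under the SE-0.32-only row) than a
real instrument would; passing tests therefore demonstrate the
*mechanics and ordering* of the design rows, not the item counts to
expect on clinical data.

## Evaluation

Per design row: mean/median administered items, 25th–75th percentile IQR
(linear interpolation), item reduction `100(1 − mean/bank size)` computed
from the mean, the general-factor SE at termination (mean and range),
and per-dimension Pearson correlations and RMSD of final estimates
against the simulated truths; group-factor metrics are also averaged
across factors. Summaries can include differences against the full run.
Degenerate dimensions with no estimate spread report NaN correlations
rather than failing.

## Problem sizes and test design

The test suite regenerates every fixture programmatically: the factorial
design runs 1000 respondents against the default 44-item bank; parameter
recovery uses 20 items, two group factors, and n = 2000; the
unidimensional reduction check uses 16 items at n = 3000; Q3 type-I
behaviour uses n = 2000. Heavy computations are session-scoped fixtures
shared across test modules, so each runs once per session. All randomness
is seeded; the adaptive engine itself is deterministic.
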