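# Methods

## Sampling model and scale conventions

A table over categorical factors is modelled as one draw from a
multinomial distribution with cell probabilities `f` and total `N`
(equivalently, independent Poisson cells conditioned on the total).
Plug-in estimates `f̂ = n/N` feed every statistic.  All information
quantities are reported on the `2N·Î` scale in natural logarithms —
the G² likelihood-ratio statistic of the corresponding independence
hypothesis — so that printed values are directly chi-square referenced.
Cells with zero observed count contribute `0·log 0 = 0`; tiny negative
round-off (within 1e-8 of zero) is clamped to zero, anything more
negative raises, because it signals a real numerical failure rather
than round-off.

Degrees of freedom use **nominal** level counts throughout: an MI term
between groups with I and J level combinations has `(I−1)(J−1)` df, a
CMI term conditioned on K combinations has `(I−1)(J−1)K`, including
empty strata (which contribute zero to the statistic).  This is the
convention under which the chain identity's degrees of freedom add up
exactly, and it is what large conditioning products in real sparse
tables require for reproducible reporting.  A `df_observed` flag
substitutes observed-support counts for exploratory use on very sparse
tables; nothing else in the package depends on it.

## Factor groups and compounding

Composite variables (a conditioning pair `{Y, Z}`, a crossed predictor
`A3 × A14`) are handled by *compounding*: the merged factor's levels
enumerate the full Cartesian product of the original levels, including
combinations never observed.  Compounding is information-preserving —
every downstream statistic computed on the compounded table equals the
jointly-computed one — and using the full product keeps nominal df
arithmetic consistent (e.g. a 4-level factor conditioned on a 4×5
compound has `3·1·20 = 60` df).  Level order is first-appearance order
unless a `FactorSpec` pre-declares levels, so dummy coding and dfs are
reproducible; missing values are an error, never a silent extra level.

## IPF and the Pythagorean split

Hierarchical log-linear models are specified by maximal generator sets
and fitted by iterative proportional fitting: cyclic rescaling of the
fitted means to each generator margin, in declaration order, from a
uniform positive start.  Convergence is declared when the largest
relative margin discrepancy falls below `tol` (default 1e-8; default
cap 1000 cycles); a non-converged fit is returned with a warning and
`converged=False`, never silently.  Observed zero margins drive the
corresponding fitted cells to zero, which is the correct ML limit for
sampling zeros.  The residual df is `cells − 1 − p` with `p` the number
of independent parameters in the hierarchical closure of the
generators, under nominal level counts (sampling zeros do not reduce
df by default).

The conditional MI `I(X,Y|Z)` splits as `Int(X,Y,Z) + Par(X,Y|Z)`:

- `Int` is the deviance of the homogeneous-association model
  `{XZ, YZ, XY}` on the three-way table (composite groups compounded
  first), with `(I−1)(J−1)(K−1)` df;
- `Par` is obtained by subtraction, with `(I−1)(J−1)` df.

A small negative subtraction result (within 1e-6) is clamped to zero
with a warning; larger negatives raise, since the only way they can
arise is IPF failure.  Conditional independence is tested in two
orthogonal steps, Int at size α₁ and Par at size α₂ with
`α = α₁ + α₂ − α₁α₂`; since no preferred split is established for the
general case, the default is the equal split `α₁ = α₂ = 1 − √(1−α)`
(≈ 0.0253 at α = 0.05), and both sizes are configurable.

## Selection procedure

Forward selection gates every candidate on the significance (at the
overall α) of its CMI with the target given the current set; the
default ranking criterion is the smallest p-value (`min_p`), which
handles unequal dfs more gracefully than the raw MI ratio; the `mir`
criterion (joint MI per df) is available and the two usually agree.
Ties break by (smaller p, larger MIR, lexicographic name), fixed and
recorded.  Backward deletion repeatedly removes the predictor whose
leave-one-out CMI has the largest insignificant p-value.  Both steps
operate directly on case-level records when given them, tabulating only
the factors each statistic involves — a full joint tensor over many
candidates is never materialized.

The rearrangement step orders the final chain identity so that
interaction components that can be dropped sit outermost.  Because the
point of the ordering is parsimony of the final model, the search
objective is *the number of significant interaction components* (at
α₁), not any single p-value: for m ≤ 5 predictors every permutation is
profiled (three-way splits are cached across permutations, so this
costs far less than `m!` IPF fits) and ties are broken by
lexicographically larger interaction p-values from the outermost
position inward, then by name; for larger sets a greedy outermost-in
pass maximizes each interaction p in turn.  A pure greedy-p rule can
strand a significant interaction further in even when an ordering with
none exists; the count objective cannot.

Model construction keeps each significant Par term as a main effect and
each significant Int term as an interaction.  One documented heuristic:
a significant high-order interaction `Int(X_t, T, {X_1..X_t−1})` with at
least two conditioning factors is replaced by the set of three-way
interactions `{Int(X_t, T, X_j)}` when each member is significant at
α₁, their statistics sum to more than the high-order statistic, and
their combined df is no larger — a strictly better-supported, cheaper
description of the same heterogeneity.  The replacement can be disabled
(`interaction_replacement=False`).

## Logistic fits

Logistic models are fitted on the grouped table of distinct covariate
classes by IRLS (statsmodels GLM, binomial family), with reference
dummy coding: an L-level main effect contributes L−1 parameters, a
crossing entered as a compound (`A*B`) contributes `L_A·L_B − 1`, a pure
interaction (`A:B`) contributes `(L_A−1)(L_B−1)`.  The reported deviance
is G² against the saturated grouped model; its df is the **nominal**
covariate-class count minus the parameter count.  Populated-classes df
is available via `populated_classes=True`; the deviance itself is
identical either way because empty classes contribute nothing.  The
log-likelihood includes the binomial coefficients of the grouped
likelihood, and AIC is `−2·loglik + 2·parameters` (intercept included).
Fits from raw records sort each factor's levels so results are
invariant to record order; separation is detected (fitted class
probability within 1e-8 of 0 or 1 with a large coefficient) and warned
about, not fatal.

## Synthetic data

The generator draws tables `Multinomial(N, f)` from an explicit
probability tensor, from log-linear λ-terms (`f ∝ exp(Σλ)`, normalized —
equivalent to Poisson sampling at fixed N), or case-level records from
a logistic mechanism (predictors from a stated joint or independent
marginal distribution, binary target from the inverse-logit of a
reference-coded linear predictor).  One `numpy` Generator per scenario,
seeded explicitly; no global RNG state.

What the generator emulates: multinomial sampling noise, main-effect
and interaction structure of arbitrary strength, balanced or unbalanced
margins.  What it does not emulate: misclassification error, missing
data, clustered or longitudinal sampling, and covariate distributions
with real-world dependence structure.  Passing tests therefore
establish correctness of the estimators and calibration of the tests
under the assumed sampling model, not robustness to violations of it.

## Study sizes and default conditions

The reproduction script and the acceptance tests use: 500 random tables
(2–4 factors, 2–4 levels, N uniform in 100–5000, Dirichlet(1) cell
probabilities) for the identity suite; 200 all-positive 2×2×2 tables
(cells 1–5) for the oracle comparison; 2000 replicates at N = 2000 for
test-size calibration, with margins keeping every expected cell count
well above 5 so the chi-square reference is accurate; and 200
replicates at N = 2000 for selection recovery.  The recovery scenario
has three active binary predictors at |β| = 1.5 (mixed signs, intercept
−0.5) and one inert candidate: with entry gated at α = 0.05, each inert
candidate enters by chance with probability close to α, so exact
recovery is bounded by roughly `(1−α)^k` for k inert candidates — a
scenario with one inert candidate keeps the achievable ceiling near
95% while still exercising false-entry control.

## Numerical conventions and degenerate inputs

- Zero-df statistics (saturated models) report p = 1 by convention.
- `alpha1 = 0` degenerates the two-step test to a single Par test at α.
- Discretization bins are right-closed (`cut[b−1] < v ≤ cut[b]`), so a
  threshold coding such as "1 if ≥ 60" is expressed with a cut at the
  value just below the threshold on the left side.
- Empty tables, empty record sets, overlapping factor groups, unknown
  factor names, and non-normalizable probability tensors all raise
  immediately with the offending name or row index.

## Known limitations

- Chi-square p-values are asymptotic; there is no exact or permutation
  option, and no bias-corrected MI estimator — very sparse tables with
  nominal dfs will be conservative.
- IPF only (no Newton–Raphson), so no λ-parameter standard errors.
- Binary targets only in the logistic module; numeric covariates must
  be discretized first.
- No structural zeros, survey weights, or ordinal scores.
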