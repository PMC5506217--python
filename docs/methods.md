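# Methods

## Model

The indecision model treats a dual-presentation trial as a comparison of two
sensory effects. A stimulus at level *x* evokes *S* ~ N(μ(*x*), 1); the
decision variable *D* = *S*₂ − *S*₁ is therefore N(±Δμ, 2), and two
boundaries δ₁ ≤ δ₂ partition its range into "first", "undecided", and
"second" judgment regions. Judgment probabilities are differences of normal
CDF values with the mean of *D* equal to μ_s(*x*_s) − μ_t(*x*) when the test
comes first and its negative when the test comes second; asymmetric
boundaries (δ₁ ≠ −δ₂) produce decisional bias, displacing the two orders'
psychometric functions in opposite directions. All probabilities are kept
separated by presentation order throughout; nothing is aggregated.

The psychophysical function is μ(*x*) = log(1 + 2 exp((*x* − α)/β)):
zero at low levels, asymptotically linear with slope 1/β, μ(α) = log 3.
Assumptions inherited from this formulation: unit-variance normal sensory
effects (non-normal forms and unequal variances are out of scope), and a
single standard level per dataset, so that when test and standard follow
different psychophysical functions only the standard's subjective anchor
μ_s(*x*_s) is estimable, not α_s and β_s separately.

A response-error layer maps judgments onto responses: ε_X,m is the
probability of misreporting an X ∈ {F, U, S} judgment in presentation order
m, and κ_X−Y,m the bias toward misreporting it as Y (one free κ per
branching point; the complement is derived). The layer is a column-stochastic
3×3 matrix, so response probabilities always remain a probability vector.
With all ε = 0 the layer is the identity. Masking which ε's are included
yields 8 error models per order, 64 in total for ternary data; under the
binary formats only the format-free ε's can be masked (16 combinations),
because the format-fixed parameters (ε_U = 1 for 2AFC; ε_F = 1 for
same–different) cannot be "excluded". Error models are labelled by the
included ε's per order — "(0,0)" none, "(1,1)" all, "(FU,S)" and so on in
between.

## Identifiability

* Detection (null standard, anchor 0): α_t and β_t both identifiable.
* Suprathreshold discrimination: only differences μ_t(*x*) − μ_s(*x*_s)
  matter within the linear range, so α_t is unidentifiable. Estimates of
  α_t are arbitrary, may sit at a search bound (reported, but benign), and
  do not affect the remaining estimates or the fit.
* With unequal psychophysical functions the anchor μ_s(*x*_s) is a free
  parameter; at suprathreshold levels it trades off against α_t, but the
  PSE μ_t⁻¹(anchor) — the identifiable combination — is recovered well.
* δ₁ = δ₂ (width 0) is a valid degenerate point encoding the classical
  2AFC difference model. When the width is fixed at 0, p_U ≡ 0, so ε_U and
  κ_U−F drop out of the free set for every format (the reference treatment
  removes them for 2AFC; we generalize, since they multiply p_U ≡ 0
  regardless of format). Same–different data cannot be fitted with width 0
  (no "same" response could then occur except as a misreport); that option
  combination is rejected.

## Estimation

The multinomial negative log-likelihood of the 2×3×N count table (kernel
only; multinomial coefficients are constant in the parameters) is minimized
with L-BFGS-B under box constraints, started from every point of a factorial
grid and keeping the best solution. The boundaries are parameterized as
(δ₁, width) with width ≥ 0, making δ₁ ≤ δ₂ a box constraint. Predicted
probabilities are floored at 1e−12 inside the log, so a zero predicted
probability with nonzero counts yields a finite, heavily penalized
objective rather than an undefined one. Fitting is fully deterministic:
identical data and options give identical results.

Numerical choices:

* μ is evaluated through a softplus-style rearrangement
  (t + log 2 + log1p(e^(−t)/2) for large t = (x−α)/β), and its inverse
  through expm1, so arguments of several hundred do not overflow.
* p_U is computed as Φ(upper) − Φ(lower), never 1 − p_F − p_S, preserving
  nonnegativity in the tails.
* Normal CDF values come from the scipy `ndtr` kernel.

Default bounds and starting grids (all overridable): α bounds from the data
— detection [3x₁ − 2x_N, x_N]; suprathreshold discrimination
[3x₁ − 2x_N, 2x₁ − x_N], which keeps μ_t linear over the test range and
avoids a spurious local optimum at large α — with a single start at the
midpoint; β bounds [0.01, 1] (stimulus units per subjective log-unit; brackets
slopes from very steep to very shallow relative to a level grid of ~1 unit),
starts {0.05, 0.15}; δ₁ bounds [−8, 2], starts {−4, −2, −0.5}; width bounds
[0, 12], start 5; anchor bounds (1e−6, 100) with starts derived from μ at
the α midpoint and each β start; ε bounds are [0, 1] with start 0.01 (small
lapses) and κ bounds [0, 1] with start 0.5 (neutral bias). The grid shape
(1 α × 2 β × 3 δ₁ × 1 each for width/ε/κ) mirrors the reference fitting
routine; the numeric values are this package's own defaults, chosen to
bracket the simulation study's parameter ranges.

Model selection (`error_model="best"`) fits every enumerated error model
and keeps the winner by −2logL or BIC (BIC sample size = total trial
count; the omitted multinomial constant cancels in comparisons). Ties
within 1e−6 break toward fewest free parameters, then the smallest label.

Every estimated parameter is counted as free — including the
unidentifiable α_t — and the count is echoed in the output so users can
audit the degrees of freedom: df = Σ over occupied (order × level) cells of
(C_active − 1) minus the free-parameter count, with C_active = 3 for
ternary data and 2 for the binary formats (counting the structurally-zero
row would overstate df). Cells with expected frequency below 5 and below 1
are counted and reported, but never collapsed automatically. With df ≤ 0
the p-values are reported as undefined, with a warning.

## Derived measures

PSE, DL, and detection threshold are closed forms in the fitted
psychophysical function (see README). Criterion probabilities default to
0.75 (DL) and 0.84 (threshold) and are configurable. The DL is reported
both as the level x_DL and as the distance x_DL − x_PSE, removing the
ambiguity between the two conventions. PSE/DL are defined only for
discrimination, the threshold only for detection; requesting the wrong one
raises a dedicated error.

## Synthetic data and the format-comparison study

The simulator reproduces the conditions under which the model's estimators
were characterized: seven scenarios crossing task (detection,
discrimination), format (ternary, 2AFC, same–different) and
psychophysical-function assumption (same/different for discrimination).
True parameters per replicate: α_t ~ U[−3, −2], β_t ~ U[0.05, 0.10],
δ₁ ~ U[−4, −2], δ₂ ~ U[2, 4]; for unequal-function scenarios the anchor is
μ_t(*x*_s) plus U[−1, 1]; under error regime "model11" ε ~ U[0, 0.02] and
κ ~ U[0, 1], under "model00" all ε = 0 (κ's are still drawn — the 2AFC
guessing bias κ_U−F needs a value even without response errors). Responses
are multinomial draws of 40 trials per level per order at 11 levels spaced
0.1 apart, centered on the true α_t rounded to 0.1 (detection) or on the
standard *x*_s = −1 (discrimination, suprathreshold given the parameter
ranges). Test levels are deliberately not adapted to each replicate's β_t,
and adaptive stimulus placement is out of scope.

True parameters are drawn from a substream keyed by (seed, replicate) only,
so all scenarios see identical generating parameters at a given replicate
index; response noise uses a scenario-keyed substream. The study refits
each replicate with the bound rules above and compares estimates and
derived measures against the values computed identically from the true
parameters, summarizing bias, RMSE, and true-estimate correlation per
parameter.

What the generator emulates — and does not: stationary observers with
level-independent boundaries and error rates, equal trial counts per cell,
and a fixed level grid. Real data add non-stationarity (learning, fatigue),
adaptive and uneven sampling, and possibly non-normal sensory noise; passing
recovery tests here demonstrates correctness of the estimator under the
model's own assumptions, not robustness to their violation.

Problem sizes: the package runs the study at 100 replicates per scenario by
default (2,000 available through `n_replicates`), which is sufficient to
resolve the qualitative ordering of formats — the dominant finding that
estimation error ranks ternary ≤ same–different ≤ 2AFC for β_t, δ₁, δ₂ —
and the identifiability pattern of α_t.

## The 2AFC confound

With 2AFC data, decisional and bias parameters are confounded: data
generated with genuine indecision (δ₁ ≠ δ₂) and a guessing bias κ_U−F can
be accounted for by a never-undecided observer (δ₁ = δ₂, eliminating δ₂,
κ_U−F,1 and κ_U−F,2). The confound is *exact* when the guessing bias is
degenerate (κ_U−F ∈ {0, 1}: the observable curve is a single normal CDF at
one of the boundaries) and approximate otherwise; with an interior κ and a
wide indecision region the two-component mixture develops a visible plateau
and the accounts become distinguishable given enough trials. The package's
confound check therefore uses a degenerate guessing bias and noise-free
expected counts, isolating the identifiability claim from sampling
fluctuation (on noisy data the unconstrained model's three extra parameters
absorb noise, adding a χ²(3)-sized likelihood difference that has nothing
to do with the confound). The enforced single-boundary fit reports the
width at its (degenerate) upper bound, signalling that a better fit would
be available with δ₂ > δ₁ — mirroring the reference routine's behavior.

## Goodness-of-fit calibration

The suite verifies that X² and G² reject a true model at close to the
nominal 5% rate. The calibration design uses narrow boundaries relative to
the sensory-effect range (β = 0.3, δ₁ = −0.9, δ₂ = 0.7) and 200 trials per
level so every expected frequency exceeds ~7; at the study's own 40
trials/level, the structurally rare tail categories make G² severely
conservative — the familiar sparse-cell failure of the χ² approximation,
which is why the small-expected-frequency diagnostics are part of the
standard output.

## Known limitations

* No standard errors or confidence intervals on estimates (no bootstrap or
  Hessian machinery), and no Bayesian fitting.
* χ² p-values rely on asymptotics that sparse cells violate; the
  diagnostics flag this but the decision is the user's.
* Error-model selection refits up to 64 models and is the slowest path.
* The reminder paradigm (standard always first) and adaptive placement are
  not modelled.
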