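# Methods

## The model

Two coupled first-order updates on a 4-month grid (step `D = 4` months):

```
F(t) = (1 − a) F(t−1) + a U(t−1)
U(t) = σ(b F(t−1) − c)
```

`F` is normalized arm function, `U` normalized spontaneous arm use, both in
[0, 1]. The function update is a weighted average, so for `a ∈ [0, 1]` the
state stays in the unit square and, at steady state, `F* = U*` — a
consequence of the single-parameter parametrization, not a claim about
patients. With `U ≡ 0`, function decays geometrically with per-step factor
`1 − a` (continuous-time constant `D/a` months). The use update is the
logistic choice rule of value-based decision models: the affected arm's
"action value" is proportional to its function, the unaffected arm's value
is constant and absorbed (together with handedness) into `c`.

### Candidate family

Model comparison runs over 7 function candidates — linear in `F(t−1)`,
`U(t−1)` or both, with or without a constant, 1–3 free parameters, with the
weighted average above as the reference — and 4 use candidates — linear or
sigmoidal in the current or previous function, with the lagged sigmoid as
the reference. Score transforms: function is `−ln(WMFT seconds)` min–max
scaled against a dataset-wide reference range; use is the mean of 30
amount-of-use item ratings divided by 5.

## Fitting: evidence maximization

Each candidate is linearized (`y = Φw + ε`): the reference function model
as `F(t) − F(t−1) = a (U(t−1) − F(t−1))`; sigmoid use rows by taking the
logit of `U(t)` (clipped to `[ε, 1−ε]`, default `ε = 1e−4`, because the
use scale produces exact 0s and 1s); linear rows directly. All rows use the
`L = n − 1` transitions from the second point on. Noise is iid Gaussian
with precision `β`; the prior is iid Gaussian `N(m0, α⁻¹I)` with a nonzero
mean. `(α, β)` are set by maximizing the marginal likelihood via the
standard fixed-point iteration (posterior mean, effective degrees of
freedom `γ = Σ λᵢ/(α+λᵢ)` with `λᵢ` the eigenvalues of `β ΦᵀΦ`, then
`α ← γ/‖m_N − m0‖²`, `β ← (L−γ)/‖y − Φm_N‖²`), stopping when both
hyperparameters change by less than 1e−6 relative, or after 500
iterations. Degenerate updates (zero residual, posterior mean at the prior
mean, `γ` at its bounds) stop the iteration at the last finite state with
`converged=False`; such fits are exactly the "flat posterior" cases the
convergence cut-off later removes.

Because the model is linear-Gaussian the additive evidence expression is
exact; the implementation verifies it against an independent closed-form
oracle (the Gaussian density of `y` under `N(Φm0, β⁻¹I + α⁻¹ΦΦᵀ)`) to
1e−8 on random problems.

Prior means are pooled: all subjects' transitions are stacked and solved by
least squares, once per candidate — except the reference function model,
whose prior mean is fixed at 1 (full carry-over of use into function).
Initial hyperparameters are near-flat: `α₀ = 1e−11`, `β₀ = 1e−8`
(ratio 1e−3). Delayed-group fits pool prior means within their own phase
and reuse the same initialization.

### Comparing sigmoid and linear use models

The sigmoid rows are fitted on logit-transformed targets. A Bayes factor
against a linear row fitted on raw `U` would compare densities of two
*different* random variables, which systematically and spuriously favours
the linear rows. Evidences are therefore compared on the observation scale:
each logit-row evidence carries the change-of-variables term
`Σ −ln(U_t(1−U_t))`. With this correction, surrogate data generated from a
sigmoid use model select the sigmoid rows, and the initialization
sensitivity scan shows the sigmoid family dominating the linear family
across the whole `β₀` grid in the saturating parameter regime. Note that at
the cohort-median parameters (`b ≈ 2.2`, `c ≈ 1.4`) the sigmoid is nearly
linear over the realized range of `F`, and the lagged linear row is then
genuinely hard to distinguish at `L = 6` — the sensitivity scan reflects
that honestly.

### Model comparison and cut-offs

Bayes factors use the interval convention: `BF ≥ 3` is positive evidence
for the reference, `BF ≤ 1/3` for the alternative, otherwise inconclusive.
Group-level selection is the positive evidence ratio `x : y` (counts per
side; the rest undecided) — per-subject Bayes factors are never multiplied,
since a few non-converged outliers would dominate such a product. The
convergence cut-off keeps a fit when each posterior sd is below the
across-subject sd of the posterior means ("auto"), or below explicit
cut-offs (the published values 0.316 / 6.38 / 3.67 for `a`, `b`, `c` are
provided as constants). The sensitivity scan refits everything over a grid
of initial noise precisions and reports group *medians* of the log Bayes
factor, dropping non-finite entries.

## Evaluation

**Leave-one-out.** For a 7-point series, each interior point (2–6, 1-based)
is held out; both reference models are refitted on the remaining points
(regression rows consuming the held-out index are dropped; cohort-pooled
prior means are reused, not re-pooled), and the coupled fitted model is
simulated forward from the first observed point. The absolute error at the
held-out index is recorded separately for `F` and `U`. The first and last
points are never held out — they anchor the trajectory. A one-step-ahead
mode (predict from the observed predecessor) is available but off by
default. The randomized baseline predicts each subject's value by a
uniformly drawn *other* subject at the same index, seeded.

**Therapy effect.** Reference-model parameters are fitted separately on the
delayed group's pre- and post-therapy series, filtered by the convergence
cut-off in both phases, paired by subject, and compared with a classical
two-tailed paired t-test per parameter.

**Use trends.** Trajectories are classified increase / decrease / no-change
by the sign of the OLS slope of use against time when its p-value is below
a deliberately lenient 0.25 (a descriptive split, not a confirmatory test);
the classification is invariant to affine rescaling of time.

## Dynamics

Fixed points of the coupled map solve the scalar equation
`σ(bF − c) = F` on [0, 1] (steady-state `F* = U*`), located by a
2000-interval sign-change scan refined with Brent's method; at least one
root always exists. Stability comes from the Jacobian
`[[1−a, a], [b U*(1−U*), 0]]` (stable iff spectral radius < 1; the
fixed-point *set* is independent of `a`). For the saddle-node (limit)
points the tangency system `{σ(bF−c) = F, b σ′ = 1}` reduces exactly to
the scalar fold curve

```
c(F) = 1/(1−F) − logit(F),   b(F) = 1/(F(1−F)),
```

monotone on each side of its minimum `c = 2` at `F = ½`. Folds are
therefore computed by bracketed root-finding on each branch of this curve
rather than by general-purpose numerical continuation — an exact
reduction that also proves the cusp: folds exist iff `c > 2`
(equivalently `b > 4` at the fold), degenerating at `(b, c, F) = (4, 2, ½)`
because the logistic slope never exceeds ¼. "Asymptotic" states are taken
from forward simulation with a 10,000-step horizon and a 1e−10 step
tolerance, since realistic parameters can leave trajectories far from
equilibrium within a two-year window.

## Synthetic cohorts

The generator emulates the trial's two schedules: immediate group — one
7-point post-therapy series; delayed group — 4 pre-therapy + 4 post-therapy
points, the post phase continuing from the final pre-therapy state with an
optional additive shift of `b` (therapy modelled as a confidence change
only). Subject-level parameters are truncated normals centred on the
reported cohort medians (`a`: 0.64 on [0, 1], `b`: 2.20, `c`: 1.40);
spreads follow one rule — 0.2 for unit-scale parameters, 1.0 for
sigmoid-scale — since only medians are reported; they are synthetic
choices, exposed in `SynthConfig`. Initial states are wide truncated
normals over [0.05, 0.95] coupled at a cross-subject correlation of 0.58
(Gaussian copula), the reported baseline association between use and
function. Noise (default sd 0.05) is injected in regression-target space —
on the function value and on the logit of use — so the generative process
matches the fitted likelihood exactly and recovery studies test the
inference, not a model mismatch; an observation-space option exists for
robustness experiments. States are clipped to [0, 1]. Raw scores can be
back-filled: WMFT seconds by the exact inverse transform on a 5–1800 s
reference range, and 30 on-grid item ratings whose mean matches `U` to
within 1/60.

What the generator does **not** emulate: dropout and missing visits,
floor/ceiling effects of the raw instruments beyond the 120 s task cap, the
within-trial correlation structure of item ratings, and any secular drift
not captured by the model family. Passing recovery tests therefore show
that the inference machinery is sound under its own assumptions — not that
the model family is adequate for real patients.

`surrogate_study` generates a cohort from each candidate in turn (the
companion variable always follows the reference pair), fits the whole
family, and tallies pairwise positive-evidence counts plus, for the
reference pair, bias / RMSE / 2-sd coverage of `(a, b, c)`.

## Known limitations

* **Interval calibration at L = 6.** The noise-precision update
  `β = (L−γ)/‖resid‖²` inherits the small-sample bias of `1/χ²`
  (posterior sds underestimated by roughly `√((L−γ)/(L−γ−2))`, ~1.3× at
  `L = 6`), and the fixed prior mean `m0 = 1` shrinks the use-effect rate
  upward. Measured 2-sd coverage on surrogate cohorts is therefore ~0.65–
  0.86 rather than the nominal ~0.95, and the recovery-focused test in the
  acceptance suite documents this shortfall rather than hiding it.
* **Nested-family model recovery.** With cohort-pooled prior means, a
  superset of the generating candidate can win the positive-evidence tally
  by a small margin at low noise: the pooled prior centres the extra
  parameters near their true values, making them nearly free in the
  marginal likelihood. The use family recovers robustly; within the
  function family the reference weighted-average model can lose narrowly to
  its two-parameter superset under clean surrogate conditions, although it
  wins against every non-nested alternative.
* The 2-week therapy windows are collapsed onto the 4-month grid; the
  acute post-stroke phase and the unaffected arm's own dynamics are out of
  scope (the latter is a constant inside `c`).
* Problem sizes in the test and acceptance runs (cohorts of 48–200,
  50-subject recovery cohorts, 1,000 random evidence problems, 50×50
  dynamics lattices) are the package's default desk-scale study
  conditions; all are configurable upward.
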