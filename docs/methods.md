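# Methods

## The intervention and its estimand

`dietsub` targets the mean counterfactual outcome `μg = E(Yg)` under a
capped substitution strategy applied to discrete dietary exposures measured
in weekly servings. The observed record is `O = (L, A, B, C, Y)`: baseline
confounders `L`, the food to be replaced `A`, the substitute `B`, other food
groups `C` (left untouched), and a binary outcome `Y`. Planned and actual
intake are equated (determinism), so the strategy can be phrased on the
observed exposures: set `A† = 0`, `B† = d(A, B) = min(A + B, x)`, `C† = C`.
The cap `x ≥ 1` keeps the intervened substitute dose inside the support of
`B`; the strategy is a modified treatment policy because `B†` depends on the
natural values of two exposures.

Identification requires consistency, determinism, conditional
exchangeability `Yabc ⊥ (A, B) | (C, L)`, and positivity: every `(A=0,
B=b†)` cell reachable under the intervention must have observed support
within its `(C, L)` stratum — in particular some subjects must consume zero
servings of `A` in every relevant stratum. `positivity_diagnostics`
checks this empirically on coarsened `(C, L)` strata (exact levels of
discrete columns, quartiles of continuous ones, user-overridable): the
assumption concerns the true law, so the empirical check necessarily works
on finitely many cells and is a diagnostic, not a test.

Exposures must be non-negative integers on finite supports. Fractional
servings (e.g., derived from frequency questionnaires) must be rounded or
binned by the caller; the package refuses silent coercion because every
identification formula is a sum over the discrete support. Missing records
are rejected, not imputed.

## Nuisance functions

Three nuisance functions enter the estimators: the outcome regression
`m(A,B,C,L) = E(Y|A,B,C,L)` and the exposure pmfs `p(A|C,L)` and
`p(B|A,C,L)`. The induced intervened-dose pmf is

    q̃(b† | c, l) = Σ_a [ 1(a ≤ b† ≤ x) p_B(b†−a | a,c,l)
                        + 1(b† = x) (1 − F_B(x−a | a,c,l)) ] p_A(a | c,l),

with `F_B(t) = 0` for `t < 0`, so when `a > x` the entire conditional mass
of `B` lands on the cap. The `a`-summation runs over the finite support of
`A` (the formal "all a ≥ 0" sum has no extra terms).

Back-ends:

- `logistic` — formula-based logistic regression (statsmodels GLM) for the
  outcome; predictions are bounded to `[1e-6, 1−1e-6]` before any logit.
- `saturated` — empirical conditional pmfs on exact strata of the discrete
  conditioning variables (the nonparametric MLE). Strata never seen in
  training fall back to a uniform pmf; such strata can only be reached with
  zero companion probability when all models are fitted on the same sample.
- `binomial` — Binomial-logistic counts with size = max support.
- `multinomial` / `multinomial_spline` — multinomial logistic over the
  support (scikit-learn, weak ridge penalty `C = 1e6` for numerical
  stability), optionally on a cubic B-spline basis (5 knots) of continuous
  covariates. A support value absent from the training data receives
  probability zero.
- `gbt` — gradient-boosted trees for the outcome (max depth chosen from
  {2, 3} by 2-fold cross-validated log-loss, 200 iterations, seeded).

The flexible defaults (gbt outcome, spline multinomial exposures) stand on
their own as the package's flexible learner pair; the theory only needs the
product of nuisance convergence rates to be `o_p(n^{-1/2})`, which many
flexible learners achieve on low-dimensional problems. K-fold cross-fitting
(`crossfit_nuisances`, deterministic folds given a seed) provides
out-of-fold predictions when flexible learners are used.

## Estimators

- **ORE**: `μ̂ = Pn m̂(0, B†, C, L)`. Its reported SE treats `m̂` as fixed
  and is labelled naive (anti-conservative); a nonparametric bootstrap
  (`bootstrap_se`, default 500 seeded resamples refitting all nuisances) is
  recommended for ORE/IPW inference.
- **IPW**: the Hajek solution of `0 = Pn[Ŵ(Y − μ)]`, i.e. `ΣŴY/ΣŴ`, with
  `Ŵ = 1(A=0) q̃̂(B|C,L) / (λ̂_A(C,L) λ̂_B(A,C,L))`. Records with `A ≠ 0`
  get weight exactly zero without evaluating the denominator. Each
  estimated denominator density is floored at `1e-6` (counted and reported,
  no upper truncation by default): the floor guards against empirical
  positivity failures without silently changing the estimand.
- **TMLE**: one-step targeting. The initial `m̂` is fluctuated on the logit
  scale by a weighted intercept-only logistic update (clever covariate used
  as a weight): solve `Pn[Ŵ(Y − expit(logit m̂ + ε))] = 0`, set
  `m̂* = expit(logit m̂ + ε̂)`, report `μ̂ = Pn m̂*(0, B†, C, L)`. This
  solves the empirical efficient-influence equation exactly in one step, so
  no iteration is needed; `SE = SD(φ̂_eff)/√n`. The update could
  alternatively use the clever covariate as a regressor — both zero the
  same score; the weight form is used throughout.

The risk difference `Δ = E(Y) − μg` is estimated by `ȳ − μ̂` with
influence function `(Y − ȳ) − φ̂_μ`.

A useful algebraic fact: with saturated empirical exposure pmfs,
`Pn[Ŵ f(0, B, C, L)] = Pn[f(0, d(A,B), C, L)]` holds exactly for any `f`,
so the TMLE coincides with the Hajek IPW to machine precision. They
separate as soon as the exposure models are smooth or misspecified.

### MSM projections

For effect modification the conditional mean `E(Yg|Z)`, `Z ⊆ L`, is
projected onto `g(Z;θ) = expit{s(Z)ᵀθ}` under the logistic
quasi-likelihood; the least-false `θ` solves `E[s(Z)(ξ(L) − g(Z;θ))] = 0`
with `ξ(L) = E[m(0,B†,C,L)|L]`, whether or not the working model is
correct. `msm_ore` solves the plug-in projection score, `msm_ipw` the
weighted logistic score `Pn[s(Z)Ŵ(Y − g)] = 0` (the root is invariant to
rescaling of `Ŵ`, so plain and self-normalized weighting coincide and no
normalization flag is needed), and `msm_tmle` fluctuates `m̂` with a
p-dimensional update `expit(logit m̂ + s(Z)ᵀε)` before projecting. All
share one Newton solver (start at 0, step-halving on the score norm,
tolerance 1e-12 on the mean score, max 100 iterations).

The covariance is the sandwich
`Ĉ⁻¹ Pn[s(Z) s(Z)ᵀ φ̃²] Ĉ⁻ᵀ / n` with `Ĉ = Pn[s(Z)s(Z)ᵀ g(1−g)]` and
`φ̃ = Ŵ(Y − m̂) + m̂(0,B†,C,L) − g(Z;θ̂)` (for the targeted fit, with the
updated `m̂*`). For ORE/IPW the MSMEstimate instead carries the sandwich of
its own estimating equation, flagged `naive_score` since the nuisances are
treated as fixed.

## Synthetic data generators

Two generators emulate realistic food-frequency cohorts at adjustable `n`.
Both share a latent uniform preference factor `U` that jointly drives three
Binomial(3, expit(·)) exposures given `(L, U)` — so the exposures are
mutually dependent given the observed covariates alone and their observed-
covariate pmfs are *not* Binomial — and a Bernoulli outcome whose true
regression depends only on observables:

- Study 1: `L ~ Ber(0.5)`; `A ~ Bin(3, expit(−2+L+U))`,
  `B ~ Bin(3, expit(1−2L+U))`, `C ~ Bin(3, expit(−1+L+U))`;
  `Y ~ Ber(expit(−1−A+B+C−2L))`; MSM modifier `Z = L`.
- Study 2: `L1 ~ Ber(0.5)`, `L2 ~ Unif[0,2]`;
  `A ~ Bin(3, expit(−2+0.75L1+0.5L2+U))`,
  `B ~ Bin(3, expit(−1+0.5L1−0.25e^{L2}+U))`,
  `C ~ Bin(3, expit(−1+L1+U))`;
  `Y ~ Ber(expit(−1−A+B+C−2L1+L2−0.25e^{L2}+0.25L1L2))`; modifier `Z = L2`.

The cap is `x = 3 = max supp(B)` throughout. `U` is drawn internally and
never emitted. What the generators do **not** emulate: measurement error in
the exposures, missing data, survey design, informative censoring, or rare
outcomes — passing tests therefore speak to the estimators' statistical
properties under correct sampling, not to robustness against those
real-data features.

Three nuisance scenarios reproduce the printed study-1 arms: `correct`
(true-form logistic outcome model; saturated empirical exposure pmfs),
`mis_outcome` (logistic working model with terms `A`, `B:L`, `C:L` only)
and `mis_exposure` (Binomial-logistic `λ_a` on `C` only and `λ_b` on
`A + C` only). Because the exposures depend on the unobservable `U`, a
"correct" parametric exposure model in observed covariates does not exist;
the saturated empirical pmf is the natural observed-covariate notion of a
correctly specified exposure model for discrete strata and is what the
`correct` arm uses. Study 2's single arm uses the flexible learner pair.

## Numerical oracles

`true_mu_oracle` and `least_false_oracle` compute the true `μg`, `E(Y)` and
the least-false MSM parameters by exact enumeration of `(A,B,C) ∈ {0..3}³`
with Gauss–Legendre quadrature over `U` (and `L2`), default 96 nodes per
axis (minimum 16 enforced); `true_mu_oracle` verifies convergence by node
doubling (`< 1e-8`). The projection score is solved by Newton to norm
`< 1e-12`. Independent brute-force Monte-Carlo counterparts
(`mc_true_mu`, `mc_least_false`) cross-check the quadrature oracles: the
former simulates the full process including `U` and draws counterfactual
outcomes; the latter solves the empirical projection of the true regression
evaluated at the intervened exposures, with M-estimation standard errors.
Under the study-2 process the least-false parameters are
`(θ0, θ1) = (0.93251, 0.26843)`, i.e. `(0.933, 0.268)` at 3 decimals —
the package's headline reproducible quantity (`scripts/acceptance.py`).

`true_nuisances` exposes the exact data-generating nuisance functions (with
`U` marginalized out by quadrature) so tests can separate estimator error
from nuisance-estimation error.

The replication harness (`run_replications`) derives per-replicate seeds
counter-style from `(seed, replicate)`, making runs bitwise reproducible
and single replicates re-runnable; it reports bias, empirical SE, MSE and
95% Wald coverage against the oracles, records replicate-level failures,
and refuses to aggregate when more than 1% of replicates failed. The
default test and acceptance runs use n = 5000 with 250 replicates per
scenario, which resolves biases of ~0.02 and coverage to ±0.014.

## Known limitations

- The EIF-based sandwich assumes the nonparametric efficient regime. When
  the exposure models are misspecified while the outcome model is a
  correctly specified parametric fit, the TMLE point estimate remains
  consistent (double robustness) but `Var(φ̂_eff)` no longer matches the
  estimator's true asymptotic variance: the weight-form fluctuation then
  propagates less weight-noise than the EIF assumes, and the Wald intervals
  for the MSM parameters over-cover (observed up to 1.0 for the intercept
  in the study-1 `mis_exposure` arm at 250 replicates), while the scalar
  `μg` interval can under-cover. A nonparametric bootstrap is the
  principled alternative in that regime.
- ORE/IPW standard errors treat fitted nuisances as fixed ("naive"); use
  the bootstrap for those estimators.
- The multinomial back-end assigns probability zero to support values never
  observed in training; with cross-fitting and very sparse levels, prefer
  the `binomial` or `saturated` back-ends.
- Point interventions only: sustained/longitudinal strategies, survey
  weights, exposure measurement-error correction and time-to-event outcomes
  are out of scope.
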