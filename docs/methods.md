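# Methods

`misscausal` estimates the average potential outcome `E(Y^a)` — the mean
outcome had everyone received exposure level `a` — from i.i.d. records in
which the exposure `A` and a subset `L_M = (L_M1, ..., L_Mq)` of the
confounders are partially missing, while the outcome `Y` and the remaining
confounders `L_O` are fully observed.  This note records the model, the
estimators, the numerical choices, and what the synthetic-data study does
and does not demonstrate.

## Causal and missingness assumptions

The causal part is standard: consistency (`Y = Y^a` when `A = a`) and
conditional exchangeability (`Y^a ⊥ A | L` with `L = (L_O, L_M)`), plus
positivity.  Three missingness regimes are supported, each with its own
identifying functional evaluated exactly in `misscausal.oracle` and
estimated in `misscausal.estimators`:

* **MAR** — a single joint indicator `R` for `(A, L_M)` satisfies
  `R ⊥ (A, L_M) | Y, L_O`.  The identifying functional conditions on
  `(L_O, Y, R = 1)` and reweights by `1 / P(R = 1 | L_O, Y)`.  Estimation
  goes through multiple imputation followed by the complete-data TMLE; the
  direct influence-function route under MAR requires modelling the joint
  law of `(L_M, A)` and is not implemented.
* **IA** — separate indicators `R_A` for the exposure and a single block
  indicator `R_L` for all of `L_M`, with (i) `R_A ⊥ Y | A, L`,
  (ii) `R_L ⊥ Y | A, L, R_A` (outcome-independent missingness), and
  (iii) `R_L ⊥ L_M | L_O`.  `R_A` may depend on the exposure itself and on
  `L_M`, and may share unmeasured causes with `A` — an MNAR mechanism.
* **IB** — per-covariate indicators `R_L1..R_Lq` under block-conditional
  MAR: `R_Lk ⊥ (L_Mk, ..., L_Mq) | Rbar_L,k-1, Lbar_M,k-1, L_O`, again with
  outcome independence.  The ordering of `L_M` is part of the assumption:
  if `L_Mj` can affect the observation status of `L_Mk`, then `j < k` must
  hold.  When no ordering is supplied, the estimators default to increasing
  missingness fraction and warn, because only the analyst can know the
  causal ordering.  Estimation conditions on monotone patterns, so
  non-monotone input is coarsened first: `L_Mk` is treated as missing
  whenever an earlier-ordered coordinate is missing.

## Estimators

* **TMLE-A** (IA): fit `pi_A(L) = P(A = a | R = 1, L)`,
  `pi_RA(L) = P(R_A = 1 | R_L = 1, L)`, `pi_RL(L_O) = P(R_L = 1 | L_O)` and
  an initial outcome regression `T1(L) = E(Y | A = a, R = 1, L)`; update
  `T1` by an intercept-only logistic fluctuation with offset `logit(T1)`
  and weight `1/(pi_A pi_RA pi_RL)` among complete records at `A = a`;
  regress the update on `L_O` among `R_L = 1`; fluctuate again with weight
  `1/pi_RL`; average.  The construction makes the estimator solve the
  efficient-influence-function estimating equation, so it is multiply
  robust: consistent if the outcome regressions, or the probability models,
  or `T1` together with `pi_RL`, are correct.
* **TMLE-B** (IB): the same scheme through the coarsening levels — a top
  fluctuation with weight `1/(pi_A pi_RA prod_k pi_RLk)`, then backwards
  for `k = q..1` a sequential regression onto `(Lbar_M,k-1, L_O)` and a
  fluctuation with weight `1/prod_{j<=k} pi_RLj`.  With `q = 1` it reduces
  exactly to TMLE-A, and TMLE-A on fully observed data reduces exactly to
  the complete-data TMLE; both reductions are tested as identities.
* **ICE-A/B**: the same sequential regressions without weights or
  fluctuations — efficient when the outcome models are correct, biased
  otherwise.
* **IPW-A/B**: Horvitz–Thompson weighting of complete records at `A = a`
  by the inverse of the fitted exposure/observation probabilities — biased
  when the exposure model is wrong.
* **CC / MI**: complete-case TMLE (valid under MCAR) and chained-equations
  multiple imputation of `A` and `L_M` (each conditional on all other
  analysis variables including `Y`) with complete-data TMLE per completed
  set and Rubin's-rules pooling (valid under MAR).  Imputation draws model
  parameters from an approximate posterior — exact conjugate Beta draws per
  stratum for saturated binary models, a normal approximation around the
  MLE otherwise.

Inference: per-record influence values are evaluated from the
post-targeting fits; the asymptotic variance is estimated by the empirical
second moment `P_n[phi^2]`, giving a Wald interval.  A nonparametric
bootstrap (record resampling, all nuisances refit per resample, percentile
interval) is available for any estimator and is the recommended interval
when the nuisances are parametric; influence-function intervals are the
default because they are what the study harness can afford at scale.

## Nuisance regressions and numerical choices

* Link: logit for the binary outcome and all pseudo-outcome regressions on
  `[0, 1]`; pseudo-outcomes are clipped to `[1e-6, 1 - 1e-6]` before the
  link so offsets are finite.  An identity link is available.
* Three flavors: `parametric` (main effects of the stated conditioning set
  by default, user-extendable term lists; fit by Newton IRLS to score
  tolerance 1e-8, with step halving; statsmodels GLM serves as the
  cross-check oracle in the test suite), `saturated` (exact weighted
  stratum means over a discrete conditioning set — a fully interacted GLM
  without its separation failure mode), and a `learner` hook for any
  fit/predict regressor (used for flexible initial outcome fits).
* Fluctuations are solved by bracketed root finding (Brent, xtol 1e-12) on
  `[-10, 10]`; when all outcome mass sits on a bound the root diverges and
  epsilon is clamped at the bracket edge with a warning and a recorded
  residual.
* Probability truncation is one-sided: predictions are clipped below at
  `trunc` (default 0.01, 0 for exact-agreement tests) and never clipped
  above.  Inverse weights are unstable only near zero; a symmetric cap
  would shrink exact probabilities of 1 (e.g. a degenerate missingness
  model on fully observed data) to `1 - trunc` and visibly bias the IPW
  estimator in the no-missingness reduction.
* Positivity is surfaced, not patched: an empty conditioning stratum —
  no complete records at `A = a` in a covariate cell, an unseen stratum at
  prediction time, a zero missingness probability — raises a
  `PositivityError` naming the stratum.

## The synthetic-data generator

`misscausal.oracle.ScenarioDGP` encodes all-Bernoulli structural equation
systems for three missingness scenarios sharing one full-data law: binary
`L_O`, `L_M1`, `L_M2` with latent common causes linking `{L_O, L_M}`,
`{L_M, Y}` and `{L_O, Y}`; a binary exposure influenced by all three
confounders and by two further latent variables `u4, u5`; and a binary
outcome.  Scenario I draws a single joint indicator from `L_O` (MAR; an
`I-Y` variant adds dependence on `Y`, still MAR).  Scenario II draws `R_A`
from `(A, L_M1, L_M2, u4)` and a block `R_L` from `(L_O, u5)` — the IA
regime, with `u4, u5` acting as unmeasured common causes of the exposure
and the missingness process.  Scenario III splits `R_L` into `R_L1`
(from `L_O, u5`) and `R_L2` (from `L_M1, L_O, u5`) — the IB regime.

Default coefficients were fixed once, by exact computation on the
enumerated law rather than by simulation: missingness of `(A, L_M)` lands
at 24% (I, II) to 29% (III), exposure prevalence is non-extreme, the true
`E(Y^{a=1}) = 0.3046` (by enumeration, reproduced by `true_potential_mean`),
and the asymptotic biases of the naive estimators are material — the
complete-case analysis is off by +0.6 to +1.5 (x100) in every scenario,
and dropping `L_M` from the outcome (exposure) model moves ICE (IPW) by
+2.3/+2.8 (+0.9/+1.5).  All coefficients are overridable per equation, so
an externally specified parameterization can be dropped in unchanged.

Because every variable is binary, saturated nuisance models are exactly
correct while main-effects logistic forms are not (the latent causes bend
the conditional means); the study's "correctly specified" regime therefore
uses saturated models, and deliberate misspecification drops the `L_M`
terms — omitting real confounders.  A smooth "wrong transform" distortion
is unavailable on binary covariates; this is the one place the package's
misspecification menu is narrower than a continuous-covariate study could
be.

What passing the study does **not** show: the generator has binary
covariates only, a single `L_O`, `q = 2`, no interactions in the structural
equations beyond those induced by the latent causes, and moderate
missingness.  Real data with continuous confounders, many covariates,
near-positivity violations, or informative outcome-dependent missingness
under the IA/IB regimes are outside what these tests certify.

## Study harness and sizes

`run_study` simulates replicated datasets, applies every requested
estimator under every specification regime to the same draws, and reports
bias, empirical SE and 95% CI coverage (all x100) with Monte-Carlo standard
errors.  The package's own study sizes — `n = 2500` per dataset, 500
replicates, MI with `m = 10` and 5 chained-equation iterations in the
harness (the standalone MI estimator defaults to `m = 25`, 10 iterations) —
were chosen so a full three-regime, five-estimator grid runs in minutes on
one CPU while keeping the Monte-Carlo standard error of each bias near
0.05 (x100), an order of magnitude below the biases the grid must detect.
Coverage in the harness is computed for the estimators with analytic
intervals (IF-Wald for the TMLEs and the complete-case TMLE, Rubin for MI);
bootstrap intervals are exercised separately at small scale, since a
bootstrap CP column would require ~10^6 nuisance refits per study.

## Known limitations

* Binary outcome only in this version; the link-function hook is the
  intended extension point for other outcome types.
* No cross-validated learner selection; an optional learner hook stands in
  for flexible nuisance estimation, and cross-fitting is not implemented.
* The MAR influence-function estimator is deliberately absent (see above);
  MAR is served by MI + complete-data TMLE and by the exact oracle.
* Discrete-law oracles are capped at 10^6 states and do not support
  continuous variables; estimators support continuous covariates through
  the parametric/learner flavors, but the exact-agreement tests are
  necessarily discrete.
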