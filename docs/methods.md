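# Methods

## The model

KineFlux predicts genome-scale steady-state flux distributions from
quantitative proteomics alone, by learning how metabolite concentrations
modulate enzyme throughput. The starting point is the kinetic decomposition
of the flux through an enzyme-catalyzed reaction,

    v = kcat · E · η,

where `kcat` (h⁻¹) is the turnover number, `E` (mmol gDW⁻¹) the enzyme
abundance and `η ∈ (0, 1]` the *metabolite concentration effect* — the
fraction of maximal catalytic capacity realized in vivo (incomplete
substrate saturation, thermodynamic back-pressure, regulation). Since
systematic in vivo `kcat` measurements are unavailable, the condition-specific
apparent catalytic rate

    k_app^C = v^C / E^C        (h⁻¹)

is computed from matched fluxomic and proteomic data, and its maximum over
conditions, `k_app^max`, serves as a `kcat` proxy, giving

    η^C = v^C / (E^C · k_app^max) = k_app^C / k_app^max ∈ (0, 1].

Metabolite concentrations are proxied by flux-sums — the total production
turnover of each metabolite,

    φ_i = Σ_j max(S_ij, 0) · v_j,

with `S` the stoichiometric matrix of the irreversible network (every
reversible reaction split into `_f`/`_b` copies with non-negative flux).

For each reaction with enough observations, a logit regression

    η = 1 / (1 + exp(−(β + Σ_{k∈K} α_k φ_k)))

is trained with the reaction's substrates always in the predictor set `K`
and up to three additional metabolites chosen by exhaustive subset search,
scored by grouped five-fold cross-validation with the adjusted R² (replicates
of one strain never straddle a fold boundary). Flux prediction for a new
condition then solves

    min_v  Σ_{j∈P} (v_j − E_j·k_app^max_j·η̂_j(v))² + w·Σ_i v_i
    s.t.   S v = 0,  v_l ≤ E_l·k_app^max_l (l ∈ Q),  v_lb ≤ v ≤ v_ub,

where `Q` is the set of reactions with abundance and `k_app^max`, `P ⊆ Q`
the subset whose regression passed the quality threshold (CV adjusted
R² > 0.6 by default), `η̂_j(v)` the learned logistic evaluated at the
flux-sums `φ = S⁺v` of the candidate flux vector itself, and `w = 10⁻²` a
small parsimony weight.

## Fitting the logit model

The regression responses are bounded in (0, 1] and, because of the
max-normalization in the definition of η, every reaction has one condition
whose response is exactly 1. Two estimators are provided:

- **Transform + OLS** (`fit_logit`, `LogitLinearRegression(refine=False)`):
  clip the response to `[ε, 1−ε]` (ε = 10⁻⁶), transform with
  `log(y/(1−y))`, and solve ordinary least squares with intercept.
  Closed-form and deterministic; on data without boundary responses it
  recovers generating coefficients to machine precision.
- **η-scale nonlinear least squares** (`refine=True`, the default inside
  model selection): the OLS estimate initializes a Levenberg–Marquardt fit
  minimizing Σ(η − σ(β + Xα))² directly. This is the estimator used for
  screening, cross-validation scoring and the final refit, because the
  clipped boundary row is otherwise a high-leverage outlier on the logit
  scale (logit(1−10⁻⁶) ≈ 13.8) that can dominate the OLS fit whenever the
  saturated condition sits at an extreme of the predictor range.

Cross-validation folds partition *replicate groups*, shuffled
deterministically by a seed; the score is R² on the η scale per held-out
fold, adjusted by `(n−1)/(n−p−1)` when the fold is large enough (otherwise
the unadjusted value is used and logged). A fold whose held-out response is
numerically constant (sd ≤ 10⁻⁶) has no meaningful R² — its total sum of
squares is rounding noise — and is skipped. Candidate feature sets whose CV
scores differ by less than `score_tol = 10⁻⁴` are treated as tied and the
tie breaks toward fewer extra metabolites, then lexicographically; the
tolerance is needed because the NLS convergence noise (~10⁻⁷–10⁻⁶ in the
score) would otherwise let spurious extras win on noiseless data.

Because exhaustive triplets over all network metabolites are combinatorially
infeasible at genome scale, extra-metabolite candidates are pre-screened:
metabolites are ranked by the absolute Pearson correlation of their flux-sum
profile with the η-scale residuals of the substrates-only fit, and the top
`pool_size` (default 15) enter the subset search.

## Solving the flux-prediction problem

The optimization is non-convex (a logistic of linear functions of `v` inside
a quadratic). It is solved by damped fixed-point iteration: evaluate `η̂` at
the current flux-sums and freeze it; solve the resulting convex QP; relax
the flux-sums toward the new solution, `φ ← (1−λ)φ + λ S⁺v`; repeat until
the maximal relative change of `η̂` falls below `tol` (10⁻⁶ by default, at
most `max_iter` = 100 iterations; the returned `converged` flag is honest).
The relaxation is adaptive: a trial step that increases the composite
objective is rejected and retried with halved λ down to a floor of 0.02
(rejected trials only re-blend φ; the QP is not re-solved). At the floor the
step is accepted anyway and counted in `forced_steps` — with steeply
decreasing η models the undamped map oscillates, and monotone descent and
progress cannot always be had simultaneously. The accepted trajectory is
non-increasing whenever `forced_steps == 0`, and the final objective never
exceeds the initial one in practice.

The convex QP subproblem (diagonal quadratic + linear term, `Sv = 0`, box
bounds) is solved by an ADMM splitting: an equality-constrained ridge step
(one sparse KKT factorization per penalty value, reused across iterations)
alternating with a box projection, with residual balancing of the penalty
parameter; tolerances 10⁻¹¹. The subproblem is normalized by the target
scale so the solver sees O(1) quantities regardless of absolute flux
magnitude. Initialization of the outer iteration uses a pFBA solution under
the capacity caps when the model declares an objective reaction, else the
minimal-total-flux vertex; fixed points of non-convex problems can depend on
the start, which is why the choice is fixed and documented. With `P` empty
the problem is exactly the minimal-total-flux LP and is solved as such.

FBA and pFBA themselves are two-stage HiGHS linear programs: maximize the
objective flux; then pin it (equality at relative tolerance 10⁻⁶) and
minimize the plain flux sum, which on the irreversible network equals the
absolute-value sum. Steady state is enforced to
`‖Sv‖∞ ≤ 10⁻⁶·max(1, ‖v‖∞)`. Degenerate alternate optima return a
solver-dependent vertex; only the objective value is unique.

## Evaluation statistics

- Per-reaction Pearson r and MSE between predicted and estimated fluxes
  across conditions, restricted to reactions whose *estimated* flux is
  nonzero in ≥ 80 % of conditions.
- Per-condition Pearson and MSE on `log(v + 10⁻⁴)` (natural log; the
  constant keeps zero fluxes finite; correlations are base-invariant, MSE
  values are comparable only within this package).
- "Well-predicted" classification: an OLS line of estimated-on-predicted
  log flux, with the standard pointwise prediction interval at 90 %
  confidence (t quantile, n−2 df, leverage-adjusted); points inside the band
  are well-predicted. The regression direction (estimated on predicted) is a
  package choice.
- Subsystem enrichment of well-predicted reactions: upper-tail
  hypergeometric p-values, Bonferroni-corrected over tested subsystems,
  significant below 0.02.
- Method comparison: per-method mean ± SD of the per-condition log-flux
  Pearson/MSE plus two-sided paired t-tests; identical methods are a
  degenerate case reported as p = 1.
- Regulator candidates: a reaction's selected extra metabolites plus every
  metabolite whose flux-sum profile correlates with a selected one at
  Pearson > 0.8 (statistically interchangeable alternates). Overlap with
  externally supplied effector sets is reported both pooled over
  (reaction, metabolite) pairs and per reaction, since the two conventions
  differ.

## The synthetic study

The generator builds a branched network — uptake → hub → k parallel branches
(transport, kinetic reaction, drain) → biomass-like sink, with the first
branch draining through a pre-split reversible transport pair — and samples
matched abundance/flux data whose ground truth follows the generative model
exactly: η_j is a logistic in the branch's own substrate flux-sum (negative
coefficient — saturation falls as throughput rises) plus, for a configurable
fraction of branches, the flux-sum of an earlier branch's substrate (a
planted effector). Because each substrate's flux-sum equals the branch flux,
every condition's steady state is the unique root of a strictly decreasing
scalar map per branch, found by bisection to ~10⁻¹⁵; transports absorb the
stoichiometric slack so `Sv = 0` holds to machine precision, and the
recorded truth satisfies `v = kcat·E·η` identically.

Default study conditions: 7 kinetic branches (25 reactions, 17 metabolites),
30 conditions in 15 replicate groups of two, `kcat` log-uniform over 1–100
s⁻¹, abundances scaled so fluxes are of order 1 mmol gDW⁻¹ h⁻¹, a
log-uniform expression scale of 1.3–10× across groups, ±25 % per-reaction
group variation and 2 % log-normal replicate jitter. The lowest-expression
group is the *reference*: an exactly self-consistent fixed point at
essentially complete saturation (`eta_ref = 1 − 10⁻⁹`). This choice makes
`k_app^max` an exact `kcat` proxy and the max-normalized response an exact
member of the logistic family, which is what sharp noiseless-recovery tests
require; `eta_ref` is configurable (0.995 exercises the ≥ 99 % saturation
regime, where `k_app^max` recovers `kcat` to 0.5 %). Optional logit-scale
Gaussian noise perturbs the *observed* η (hence observed fluxes, with
transports re-balanced) and never the self-consistent truth. A
Michaelis–Menten mode generates η from saturation kinetics instead —
deliberately outside the logistic family — to probe misspecification;
Michaelis constants are capped below the lowest-expression capacity so a
positive steady state always exists.

What the generator does *not* emulate: measurement error on abundances,
missing data patterns, isozymes/complexes (abundance is one number per
reaction), thermodynamically infeasible loops, and realistic genome-scale
network redundancy. Passing tests therefore demonstrate correctness of the
computations and identifiability under the stated generative model, not
performance on real fluxomic/proteomic data.

The end-to-end harness splits replicate groups 70/30 into training and
held-out sets, computes `k_app` and η on all conditions (`k_app^max` must see
the saturating condition, as when it is determined over all strains of a
study before prediction), trains and selects models on the training
conditions only, predicts held-out fluxes from abundances alone, and scores
per-reaction Pearson correlations against the true fluxes.

## Numerical choices and degenerate inputs

- Logistic evaluation clamps its argument to [−700, 36.7] so results stay
  strictly inside (0, 1) in float64.
- `k_app` is missing (never zero) when abundance is missing or zero; η is
  missing when either factor is; reactions with no defined `k_app` anywhere
  are dropped with a log message, not an error.
- Measured bounds that contradict the model (lb > ub, or a capacity cap
  below a lower bound) raise immediately with the offending reaction named.
- Rank-deficient predictor matrices raise a `FitError` naming the collinear
  columns (QR with column pivoting); candidate sets that cannot be fit are
  skipped during selection.
- At flux scale O(1) the parsimony term `w·Σv` shifts the optimizer a few
  per cent below the kinetic targets (each unit of branch flux carries ~5
  units of path flux, so the shift is ≈ 5w/2 in absolute flux); per-reaction
  correlations are unaffected, and exact fixed-point recovery is verified at
  high flux scale where the term is negligible.
- Problem sizes throughout the test-suite and the acceptance script (25-
  reaction networks, 30 conditions, 100-replicate Monte-Carlo loops) are
  chosen so every check runs in seconds on a single core.

## Known limitations

- The non-convex optimization is solved to a fixed point of a damped
  iteration from one documented start; no global-optimality claim is made,
  and multi-start search is an extension point.
- The transform+OLS estimator is one reading of "logit regression" on a
  continuous bounded response; quasi-binomial alternatives would differ in
  the weighting of near-boundary observations.
- MSE values on the log scale depend on the log base and the additive
  constant and are not comparable across tools.
- SBML support covers Level 3 + FBC via cobrapy; the JSON dialect is the
  first-class fixture format.
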