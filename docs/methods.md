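# Methods

## Model

The nutritional status of a child is a three-state process — undernourished
(1), nourished (2), overnourished (3) — assumed to evolve as a
time-homogeneous continuous-time Markov chain.  All six off-diagonal
transitions are allowed by default; all states are transient.  The
intensity matrix Q has non-negative off-diagonal rates per month and
diagonal entries equal to minus the row sum, so P(t) = exp(tQ) is
row-stochastic.  Derived quantities:

- mean sojourn time in state h: −1/q_hh (infinite for an absorbing state,
  reported as such rather than raised);
- next-state (embedded jump chain) probabilities: q_hj/(−q_hh), undefined
  rows of absorbing states returned as NaN;
- total length of stay in state k over [t1, t2] from start h:
  ∫ P_hk(t) dt, by composite Simpson quadrature with step ≤ 0.1 month
  (validated against a step-0.001 Riemann sum to 1e-6; the three components
  sum to t2 − t1 by construction);
- expected prevalence at t: the initial state distribution propagated
  through P(t).

Covariates act proportionally on each transition intensity,
q_hj(Z) = exp(θ_hj + β_hjᵀ Z), with θ = log baseline rate.  The covariate
value over an interval is its value at the interval's left endpoint
(standard panel convention); age is therefore a time-varying covariate
updated at each observation.  Covariates are **not** mean-centred by
default — the evaluation covariate vector of every derived table is
explicit, because summaries evaluated silently "at covariate means" are a
common source of irreproducible tables.  Which covariates attach to which
transitions is explicit too (`covariate_map`); when a map is supplied it is
complete, so the model's degrees of freedom always equal the actual number
of free parameters (6 baselines + attached coefficients).

## Estimation

Surveys observe the state only at round times, so each consecutive pair of
observations on a child contributes the matrix-exponential entry
[exp(Δt·Q(Z))]_{s,s'} to the likelihood.  Maximisation is quasi-Newton
(L-BFGS-B) on the unconstrained scale (θ = log q, raw β), initialised from
crude rates (observed h→j pairs divided by observed time at risk in h,
with 0.5 substituted for zero counts); β starts at 0.  Stopping: relative
likelihood change below 1e-10 or projected gradient below 1e-6, max 500
iterations; a warm-started fit that fails its line search is restarted
from the crude initialiser before an error is raised.  Standard errors
come from the inverse observed information (finite-difference Hessian);
intensity CIs are computed on the log scale and exponentiated so bounds
stay positive, hazard-ratio CIs are exp(β̂ ± 1.96 se).  Children with a
single observation carry no transition information and are dropped with a
logged count.  A transition observed in the data but impossible under the
mask (unreachable in the transition graph) yields −∞ with a diagnostic
naming the offending pair.

Inside the likelihood, exp(Δt·Q) is evaluated per unique covariate vector
by eigendecomposition of Q, vectorised over interval lengths; the result
is accepted only if it is row-stochastic to 1e-8, otherwise the code falls
back to scipy's scaling-and-squaring per interval.  Outside the likelihood
the public `transition_probability` always uses scaling-and-squaring, with
drift from row-stochasticity above 1e-10 raised as an error rather than
silently renormalised.

Bootstrap CIs for derived quantities resample children with replacement,
refit (warm-started at the full-data estimates), recompute the statistic
and take percentile 2.5/97.5 bounds; more than 20% failed refits aborts
with a diagnostic.

## CIAF classification

Cut-offs are strict (a z-score exactly at −2 or +1 is not a failure),
following the inequality wording of the index definition.  Sixteen flag
patterns exist but only nine are CIAF groups.  Wasted+overweight patterns
cannot arise from z-scores (both are WHZ conditions), but three unlisted
patterns can (e.g. underweight+overweight); the default policy raises an
explicit error for them, and an opt-in `undernutrition-priority` policy
maps any unlisted pattern to the nearest undernutrition group by Hamming
distance on the three undernutrition flags (ties to the more severe group),
logging a warning — the index's claim of exhaustiveness does not hold
mathematically, and the policy keeps that visible.  Duplicate
anthropometric measurements closer than the instrument tolerance (0.01 cm
/ 0.01 kg) are averaged; otherwise a third measurement is required and the
median of the three is used (the protocol records a third but does not say
how it is combined; the median is the robust choice).  Reported
percentages round half-up to one decimal.

## Synthetic cohort generator

The generator emulates the survey design the analysis assumes: by default
3,044 children observed at 0/18/36 months; later rounds jittered by
N(0, 1 month) and kept ordered (survey windows span ~2.5 months);
independent 3% dropout per post-baseline round (matching the observed
attrition 3044→2973→2813); baseline state mix 39.7/46.5/13.9%; baseline
age uniform on [0, 35] months.  Binary covariates are Bernoulli with
marginals of the study population — female 48.5%, Oromia 43.9%, any
maternal schooling 27.2%, non-homemaker mother 32.1% — and household size
> 5 at 35% (not reported by the source; chosen once as realistic for rural
Ethiopian safety-net households).  Latent paths are Gillespie-simulated
from the baseline intensity matrix (defaults of the magnitude estimated
for this population, e.g. q21 = 0.0224/month), with optional
proportional-hazards modulation; when a covariate effect references age,
intensities are piecewise-constant between observation times with age
updated at each round, matching the fitted model's convention.  Z-scores
are drawn from truncated normals within each CIAF group's cut-off cell
(group weights inside each state reflect stunting-led failure), so
classification round-trips exactly to the generating state.

What the generator does **not** emulate: kebele-level clustering and
design weights, intervention arms, seasonality, measurement error in
z-scores, informative dropout (attrition is independent of state), and
correlation between covariates.  Passing recovery tests therefore shows
the estimator is correct under the model's own assumptions, not that the
model is correct for real survey data.

## Validation experiments and problem sizes

- **Recovery**: 7 independent cohorts of n=3000 are fitted and the
  per-transition *median* estimate compared to truth (tolerance 15%).
  Replication is essential: for the rarest transitions one cohort's own
  95% CI spans roughly ±25%, so a single draw cannot test a 15% band —
  the median over 7 fits isolates estimator error from one draw's noise.
- **CI coverage**: 100 cohorts of n=1000; the 95% Wald intervals for each
  q_hj should cover truth 88–99% of the time.
- **Covariate recovery**: hazard ratio 0.8 injected on the
  nourished→undernourished transition for a binary covariate; 100 cohorts
  of n=1000; the CI should cover 0.8 in ≥90% of replicates.
- **Simulator validity**: Kolmogorov–Smirnov test of holding times against
  the exponential law (10⁴ draws, α = 0.01) and Monte-Carlo occupancy at
  18 months vs exp(tQ) within 3 binomial SEs (2×10⁴ paths).

These sizes keep the whole suite within a few minutes on one CPU while
leaving each check well-powered.

## Observed prevalence

The observed prevalence curve uses last-observation-carried-forward: at
grid time t each child contributes its most recent observed state, and is
censored after its final observation.  Between rounds spaced 18 months
apart LOCF is a step function, so expected-vs-observed comparisons are
made at the round times themselves (where LOCF equals the cross-sectional
state distribution); the expected curve starts from the empirical baseline
distribution under the fitted Q.  Files carry probabilities to 6 decimals
(fixed formatting so CSVs round-trip exactly); console tables use 2.

## Known limitations

- Time-homogeneous intensities only; no splines, hidden states or
  misclassification model.
- Wald/percentile intervals only; no profile likelihood.
- The likelihood treats observation times as exact and non-informative.
- The degrees of freedom are computed from the actual specification; a
  model with all six covariates on all six transitions has 6 + 36
  parameters, and published df values that disagree with the displayed
  number of hazard ratios cannot be reproduced without knowing the exact
  attachment, which is why it is an explicit argument here.
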