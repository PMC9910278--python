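# Methods

This note documents the generative model behind the synthetic cohorts,
the scoring definitions, the drift–diffusion likelihood, the inference
machinery, and the numerical and design choices made where the design
was genuinely open.

## Synthetic cohort generative model

### Participants

Each participant carries:

| parameter | meaning | default distribution |
|---|---|---|
| `w_taste`, `w_health` | decision weights (log-odds per rating unit) | N(0.55, 0.12²), N(0.50, 0.12²) |
| `beta0` | choice intercept | N(0, 0.2²) |
| `ddm` | diffusion parameters | a = 1.5, z_rel = 1/3, t0 = 0.3 s, drift_scale = 1.0, σ = 1 |
| `delta_neg`, `delta_pos` | regulation efficacy (SAM units toward neutral) | N(1.56, 0.5²), N(1.88, 0.5²), clipped at 0 |
| hunger, BMI, restraint, gender | person-level covariates | uniform 0–100, N(23, 3²), N(0, 1), 21:17 f:m |

A single latent regulation-capacity factor `e ~ N(0,1)` drives both
deltas; the health-weight disturbance correlates with `e` at
`coupling_rho` (default **0**, i.e. no true cross-task association, the
empirical situation the default cohort emulates). Because both deltas
load on the same factor, the correlation between mean efficacy and
`w_health` equals `coupling_rho` up to the (rare) truncation of deltas
at zero. The covariates are generated but **inert** — their generative
coefficients are zero — so covariate regressions can be checked against
a known null.

### Food ratings

180 items per participant from a mixture over the four taste×health
quadrants plus a neutral band, masses (HTLH, LTHH, HTHH, LTLH, neutral)
= (0.42, 0.12, 0.22, 0.14, 0.10). Within a quadrant each attribute's
magnitude is uniform over a configured range: tempting HTLH items are
strongly unhealthy (health magnitude U(3, 5), taste U(0.5, 5)),
healthy-but-unpalatable LTHH items are strongly unpalatable (taste
U(3, 5), health U(0.5, 5)), aligned HTHH items are high on both
(U(3.5, 5)) and LTLH items mild (U(0.5, 2.5)).

These ranges are a deliberate design choice, not an estimate: no
empirical taste/health rating distribution is available to fit. Because
the choice drift is built from *mean-centered* ratings, the average
drift over a choice set is identically zero, and a quadrant-symmetric
sampler cannot produce the strong empirical asymmetry between refusing
temptations and accepting unpalatable-healthy foods. The asymmetric
magnitude structure above — which is also what real snack-pool ratings
look like — concentrates the positive drift mass in the (mostly eaten)
HTHH fillers and leaves both challenge types with net-negative drift.
Under the defaults the simulated cohort shows ≈64% overall challenge
success, ≈77% success by refusing HTLH items and ≈20% by accepting LTHH
items, and faster refusals than acceptances on challenge trials.

### Choices and response times

Per trial, drift = `drift_scale · (w_taste·tr_c + w_health·hr_c)` with
ratings centered within participant over the presented foods, fed
through the diffusion simulator (below) within a 3-s response window;
first passages beyond the window are recorded as *missed* with no
choice. Under the defaults roughly 0.2% of trials are missed.

### Emotion sessions

100 trials: 5 block types × 20 (view/reappraise × negative/positive,
plus neutral view; neutral stimuli never appear under reappraise).
In-scan ratings are a discretized truncated Gaussian on the 1–9 SAM
scale: `round(clip(N(m, 1.0²), 1, 9))` with `m` = condition mean
(defaults 2.69 / 5.26 / 7.09 for negative/neutral/positive view) plus a
participant baseline shift N(0, 0.4²); reappraise conditions shift `m`
toward 5 by the participant's delta. Every reappraised stimulus also
receives a post-scan rating drawn from the *unregulated* view
distribution — post-scan viewing is treated as the unregulated baseline.

Note a deliberate, documented artifact of the bounded scale: because
ratings are rounded and clipped near the scale floor/ceiling, measured
success scores attenuate slightly relative to the generating deltas
(e.g. mean measured negative success ≈ 1.3–1.6 for delta_neg = 1.56,
varying with the cohort draw). Recovery tests therefore compare against
Monte-Carlo expectations rather than raw deltas where exactness matters.

### Reproducibility

Every generator is a pure function of (config, seed). Each participant
owns an RNG stream derived from `SeedSequence([cohort_seed, index])`, so
any participant can be regenerated in isolation; profile draws use a
dedicated stream. Pipeline outputs are TSV with fixed float formatting,
and the manifest records SHA-256 content hashes; re-running a config
reproduces identical bytes.

## Scoring definitions

* **Neutral zone**: |r| ≤ 0.5 (5% of the 10-unit scale each side of
  zero). The boundary is **closed** — a rating of exactly 0.5 is
  neutral — the conservative exclusion where boundary handling is
  otherwise unspecified.
* **Weights (per participant)**: ML logistic fit of yes ~ 1 + taste_c +
  health_c by IRLS, ratings centered within participant over the
  presented foods (the fit is per participant, so within-participant
  centering keeps the intercept interpretable). On detected separation
  (e.g. a participant who never eats) the fit falls back to IRLS with a
  small ridge penalty (λ = 0.5 on all coefficients) and sets
  `separation_flag`; the pipeline excludes flagged participants.
  Separation is detected as an all-one-sided outcome, a non-converged
  IRLS, or any |coefficient| > 15.
* **SV** excludes the intercept: it is the sum of weighted taste and
  weighted health, not the linear predictor.
* **Conflict** = −|SV| ≤ 0, maximal at SV = 0.
* **Stakes** = |tr| + |hr| on challenge trials, 0 on aligned trials,
  undefined (error) in the neutral zone.
* **Orthogonalized stakes**: both vectors mean-centered first (standard
  parametric-modulator convention), then stakes residualized on
  [intercept, conflict] within participant over challenge trials only;
  the residual has zero mean and zero inner product with conflict, and
  is invariant to adding any affine function of conflict to the stakes.
* **Self-control success**: success iff (HTLH ∧ no) or (LTHH ∧ yes);
  missed challenge trials enter neither numerator nor denominator
  (success is defined over choices actually made).
* **Reappraisal success**: per-stimulus differencing before averaging
  (robust to missing post-scan ratings; coincides with the difference
  of condition means under complete data). Tie rule for per-trial
  success/failure labels: a tie is a **failure** — success requires an
  actual rating change. This is a stipulation; with complete data it
  only affects the trial labels, not the (difference-based) scores.

## Drift–diffusion model

Upper boundary = yes/eat, lower = refuse; z_rel is the fraction of `a`
from the lower boundary, so "bias toward refusing" means z_rel < 1/2
(default 1/3). σ is fixed at 1 (scaling convention). No inter-trial
variability parameters are included.

* **Density**: the first-passage density is evaluated via the
  small-time (image) and large-time (eigenfunction) series, choosing per
  evaluation point the expansion needing fewer terms for tolerance
  1e-7 (capped at 64 terms). The upper-boundary density uses the
  reflection (v, w) → (−v, 1−w).
* **Absorption probability**: closed form
  (1−e^(−2vz))/(1−e^(−2va)), computed with `expm1` for stability, a
  v→0 guard returning z_rel, and exponent arithmetic when the arguments
  would overflow.
* **Survival** (censored mass beyond t): term-wise integral of the
  large-time series at both boundaries, 128 terms; accurate for the
  censor times that arise here (t ≳ 1 s normalized by a² ≤ 25).
* **Simulator**: Euler–Maruyama with step 1 ms plus a Brownian-bridge
  crossing correction inside each step, which removes the leading-order
  discretization bias of naive Euler first-passage sampling; the
  resulting RT histograms match the analytic density within binomial
  error at 10⁶ paths.
* **Fitting**: censored MLE over (a, z_rel, t0, drift_scale) — density
  terms for responded trials, survival mass for missed — by L-BFGS-B
  from 3 starts (one canonical, the rest drawn from a seeded RNG),
  bounds a ∈ (0.3, 5), z_rel ∈ (0.02, 0.98), t0 < min RT, |drift_scale|
  ≤ 10. Fits with fewer than 20 responded trials are flagged
  non-converged (underdetermined); all-one-boundary data warn and pin
  z_rel near its bound. At 1000 trials per participant the mean
  recovered z_rel is within ±0.01 of the generating 1/3 (the acceptance
  check allows ±0.05).

## Inference

* **Correlations**: Spearman (rank) or Pearson (linear) point estimate
  with a BCa bootstrap 95% interval (default 10,000 resamples) and
  `pp_positive`, the fraction of the bootstrap distribution above zero.
  This is a deliberate substitution for fully Bayesian correlation
  inference: the point estimate is identical, the interval has
  comparable semantics, and `pp_positive` plays the role of a posterior
  probability, without an MCMC dependency. Degenerate bootstrap
  distributions (e.g. ρ ≡ 1 under perfect monotonicity) fall back to
  the distribution's extremes. Pairs with missing values are dropped
  (pairwise-complete); a constant input is an error. Under a null
  generator the interval covers zero at ≈95% of 500 replicates (n=38).
* **Two-stage group models**: per-participant regressions (logistic for
  choice/success outcomes, OLS for log-RT and ratings) summarized by
  the coefficient mean with a 95% t-interval across participants —
  an approximation to full hierarchical estimation chosen for
  testability at desk scale; between-participant SD of exactly 0 flags
  a degenerate interval. Person-level covariates (hunger, BMI,
  restraint, gender), being constant within participant, are tested at
  stage 2 by OLS of the per-participant coefficients on standardized
  covariates.
* **Parameter recovery**: fitted logistic weights are compared against
  the *effective* generating slopes `a · drift_scale · w` — for an
  unbiased diffusion the absorption probability is exactly logistic in
  the drift with slope `a`, so this is the quantity a logistic read-out
  of diffusion choices estimates; with the refusal-biased start the
  correspondence is approximate, which the recovery report's bias field
  makes visible.

## Problem sizes

Defaults used by the test suite and the acceptance script: cohorts of
38 participants × 100 choice trials and 100 emotion trials; diffusion
starting-point recovery at 38 × 1000 trials; density-vs-simulation
checks at 10⁶ paths; bootstrap coverage at 500 replicates × 2000
resamples. These sizes give Monte-Carlo error comfortably inside the
stated tolerances.

## Known limitations

* The rating sampler reproduces quadrant structure and magnitude skew,
  not the full empirical taste–health joint distribution of any real
  food set; absolute values of fitted weights depend on it.
* The diffusion model omits inter-trial variability (sv, st0, szr) and
  assumes drift proportional to the combined SV; an alternative with
  separate taste and health drift weights would be a straightforward
  extension (two drift coefficients instead of one) but is not fitted.
* Two-stage group inference ignores within-participant estimation
  uncertainty at stage 2 (it is conservative when trial counts are
  balanced, as here).
* Passing tests on synthetic cohorts demonstrates internal consistency
  of the pipeline and estimators, not fidelity to any particular
  empirical dataset; externally supplied tables can be dropped in for
  that purpose.
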