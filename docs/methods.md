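# Methods

`priortime` implements a complete, simulation-backed analysis pipeline for a
two-task interval-timing paradigm used to dissociate two routes to
over-reliance on prior expectations: degraded sensory resolution versus a
compressed representation of prior variance (the pattern associated with
hallucination proneness). Because no human data ship with the package, every
analysis stage is exercised on synthetic subjects whose generative model is
described below; what passing tests do and do not establish about real data
is discussed at the end.

## The ideal observer

A trial presents a sample interval `t_s` drawn from the active condition's
uniform prior. The observer measures it with scalar variability,

    t_m ~ Normal(t_s, (w_m * t_s)^2),

where `w_m` is the Weber fraction (dimensionless; subject trait, empirically
~0.03-0.37 with mean ~0.12). The Bayes least-squares (BLS) estimate is the
posterior mean

    t_e = ∫ t L(t_m | t) π(t) dt / ∫ L(t_m | t) π(t) dt,

with `L(t_m | t) = Normal(t_m; t, (w_m t)^2)` and `π` the (represented)
prior. The production adds scalar motor noise,

    t_p ~ Normal(t_e, (w_p * t_e)^2),   w_p = 0.1 by default,

truncated at zero by resampling (at most 100 attempts, then floored).
Because the posterior mean shrinks toward the prior mean, productions
regress toward the middle of the stimulus range; the slope of `t_p` on
`t_s` is below 1 and `1 − slope` quantifies central tendency.

Numerical choices:

* Posterior integrals use fixed trapezoid quadrature with ≥ 1001 nodes.
  Uniform priors integrate over their support; Gaussian priors over the
  prior mean and the measurement range extended by 6 noise SDs, so no
  posterior mass is truncated. Doubling the node count changes estimates by
  < 1e-6, and a constant-noise variant (`sigma_const`) reproduces the
  conjugate-Gaussian closed form to the same tolerance.
* With scalar noise the likelihood is a scale family, not a location
  family: for measurements far below the prior support the `1/t` density
  factor dominates and the posterior mean briefly *decreases* in `t_m`
  before turning monotone. Monotonicity therefore holds — and is tested —
  on the physically reachable measurement range (at and above the prior's
  lower bound); estimates are always clipped to the support of uniform
  priors.
* Interpretations where the source was silent: "motor noise 0.1" is read as
  a scalar coefficient (`w_p`, SD = `w_p * t_e`), matching the
  measurement-noise convention; prior compression "each bound by 10%" is
  read multiplicatively (`lower × 1.1`, `upper × 0.9`); the uniform prior
  is treated as continuous for estimation, the discrete bin grid being a
  stimulus-sampling device only.
* Condition response curves are linearized with a robust line (IRLS,
  bisquare weights, tuning constant 4.685, tolerance 1e-8, ≤ 200
  iterations) through per-bin mean productions of 20 simulated trials per
  bin; the fit is unconstrained and the indifference point — where the line
  crosses the identity — is computed afterwards as
  `intercept / (1 − slope)` (reported as the prior mean, flagged, in the
  measure-zero case `slope = 1`).

## Task conditions and session structure

Four uniform priors manipulate the stimulus distribution's mean ("length")
and range ("width"): NS (11 bins, 0.5-0.9 s), NM (11 bins, 0.7-1.1 s), NL
(11 bins, 0.9-1.3 s), WM (21 bins, 0.5-1.3 s); all bins are 0.04 s apart.
Each condition runs as 3 blocks of 6 repetitions per bin (66 trials per
narrow block, 126 per wide block; 972 per session); block stimulus order is
a seeded random permutation. The wide condition is scheduled first or last
(coin flip) and the three narrow conditions are contiguous in random order,
giving 12 equally likely schedules. Training blocks (42 trials wide, 44
narrow, with accuracy gates) are recorded as design metadata only — they
are not simulated and contribute no analysis data.

Positive feedback uses a window of full width `k * t_s` centered on `t_s`
(hit iff `|t_p − t_s| ≤ k t_s / 2`), with `k` adapted one-up/one-down by
0.015 per trial from `k0 = 0.1`, floored at one step. The staircase drives
any stationary observer to ~50% hits in the long run; starting below the
equilibrium `k`, whole-session hit percentages average slightly below 50%
for typical observers (≈ 47-50% across simulated cohorts). Feedback only
adapts `k`; it never changes the simulated observer's behavior.

## Synthetic population

Per-subject parameters (all drawn independently of each other, seeded):

* `w_m`: log-normal, median 0.11, log-SD 0.5, truncated to [0.03, 0.37] by
  resampling — matching the reported empirical range and mean.
* CAPS (hallucination-proneness score): zero-inflated, P(0) = 0.6, with a
  log-normal positive part (log-mean 3.5, log-SD 0.9, rounded, capped at
  512), reproducing the ~60% zeros and heavy right skew of the scale.
* Prior compression: `γ_i = γ_max · r_i` where `r_i` is the subject's CAPS
  rank (ties at the minimum) rescaled to [0, 1]; every zero scorer gets
  `γ = 0` and the top scorer `γ_max` (default 0.1). Compression applies to
  the *represented* prior of the wide condition only — stimuli always come
  from the true prior. Rank normalization keeps the generative link
  monotone in CAPS while robust to its skew; note the analysis model still
  uses the raw (z-scored) CAPS score, so the recovered interaction is
  attenuated relative to a rank-linear analysis, as it would be in real
  data.
* Optional prior adaptation: with rate `λ > 0` the subjective prior is a
  running uniform whose mean `m` and half-width `h` update after every
  observed sample (`m ← m + λ(t_s − m)`, `h ← (1−λ) h + λ · 2|t_s − m|`,
  initialized to the full stimulus range 0.9 ± 0.4 s), producing start- and
  transition-related slope shifts. The default is `λ = 0` (static priors),
  so BLS predictions are exact unless nonstationarity is requested.

## Temporal categorization and the Weber fraction

A 59-trial two-interval forced-choice session compares a 0.9 s reference
with a probe: 50 probes placed by a QUEST staircase plus 9 uniform fillers
on [0.5, 1.3] s interleaved at seeded random positions. The simulated
response follows from scalar variability on both intervals:

    P(probe judged longer) = Φ((i2 − i1) / sqrt(w_m^2 (i1^2 + i2^2))).

QUEST internals (not specified by the task description; standard practice,
guarded by recovery tests): 201 candidate PSE values on [0.5, 1.3] s,
Gaussian prior centered 0.9 s (SD 0.2 s), assumed psychometric slope
0.135 s (≈ 0.15 WF at 0.9 s), lapse 0.02, log-space updates with
renormalization and a boundary flag. Probes are placed at the
posterior-mean PSE offset alternately by ± Φ⁻¹(0.75) · σ_assumed (the
75%/25% "sweat points"): placing every probe exactly at the PSE would pin
responses at p ≈ 0.5 and leave the slope — hence the WF — barely
identifiable from staircase trials (WF recovery across subjects rises from
Spearman ≈ 0.5 to ≈ 0.78 with sweat-point placement).

Per subject, `P(probe longer | x)` is fitted as a cumulative Gaussian by
maximum likelihood, `λ/2 + (1−λ) Φ((x − PSE)/σ)` with the lapse fixed at
0.01 (configurable), L-BFGS-B from a fixed three-point start schedule
(deterministic refits), σ box-bounded at [1e-4, 1] with a flag when the
lower bound binds. Derived quantities: JND = `σ · Φ⁻¹(0.75)`
(Φ⁻¹(0.75) ≈ 0.67449 — the 75%-correct convention for the "scaling
factor"), WF = JND/PSE. Bootstrap CIs are nonparametric percentile
intervals over trial resamples.

Goodness of fit is `pseudo-R² = 1 − deviance / (2 n ln 2)`, the deviance
reduction relative to a coin-flip responder. Because the lapse is fixed and
σ bounded, the constant-p null is not nested in the family, so random
responders can score slightly *negative* pseudo-R²; chance-level cutoffs
are therefore empirical — coin-flip sessions at the subject's own stimuli
are refitted (10,000 iterations by default; configurable upward) and the
95th/99th/99.9th percentiles classify subjects as above chance. Split-half
reliability fits WF separately on odd- and even-indexed trials, correlates
the halves across subjects (Spearman), and applies the Spearman-Brown
correction `2ρ/(1+ρ)`.

## Trial censoring

Per subject, in fixed order, on the error `t_p − t_s`: (1) |error| > 3 s
("error superior to 3 s" is read as absolute — a signed reading could never
trigger for early responses); (2) |error − mean| > 4 SD of the subject's
whole-session error distribution (computed after stage 1; the whole-session
reading follows the "mean overall error" phrasing); (3) Cook's distance > 1
in a per-subject, whole-session regression of production on sample,
re-screened iteratively (≤ 10 passes) until stable. Cook's distances use
the hat-matrix formula and are verified against a leave-one-out refit
oracle to 1e-10. Fewer than 10 surviving trials is an error. On
well-behaved synthetic sessions the three stages remove < 2% of trials.

## Mixed-effects model ladder

The analysis model is a Gaussian linear mixed model of the reproduced
interval with per-subject random intercepts and random Sample slopes
(unstructured 2×2 covariance), fitted by maximum likelihood. Fixed effects
at the base level are `Sample * (Length + Width)` with Length coded by
medium/long dummies (short reference), Width by a wide dummy (narrow
reference); the effects of interest are the Length×Sample and Width×Sample
interactions (modulations of central tendency). The response stays in
seconds; continuous predictors are z-scored over the analysis rows (scaling
parameters recorded), preserving interpretable slopes.

Nonstationarity covariates, all derived from the session schedule: Start
(first block of the session), LengthTransition and WidthTransitionNtoW /
WtoN (first block after the respective condition change — unsigned
first-block indicators, since transition effects concentrate there), and
GlobalMean (running mean of all preceding sample intervals, z-scored; the
first trial, having no history, uses its own sample). The ladder's eight
levels add these cumulatively — main effects first (Start; the three
transitions; GlobalMean), then the Sample interactions of Start and the
transitions one at a time — ending at

    Response ~ 1 + Sample*(Length + Width + Start + LengthTransition
               + WidthTransitionNtoW + WidthTransitionWtoN) + GlobalMean
               + (1 + Sample | Subject).

The intermediate compositions are a package choice: only the endpoint
formulas are fixed by the analysis design, and any nested sequence through
the same covariate set supports the same comparisons. Covariates constant
on an analysis subset (e.g. Start after excluding first blocks) are dropped
with a warning; an exactly rank-deficient fixed design is an error naming
the aliased columns.

Model comparison reports AIC (`2k − 2 logLik`), BIC (`k ln n − 2 logLik`)
and likelihood-ratio tests against each level's predecessor; a winner is
declared only when AIC, BIC and stepwise LRT ascent agree, otherwise "no
consensus" is reported. Variance inflation factors are computed per
fixed-effect column (`1/(1−R²)`, intercept excluded as a target) with an
infinity marker for exact collinearity; dummy-by-continuous interaction
codings inflate some VIFs by construction, so the diagnostic reports and
flags rather than gates.

Fixed-effect t statistics use Satterthwaite degrees of freedom computed
in-package: the profiled ML likelihood over the variance components
θ = (g11, g12, g22, σ²) is differentiated numerically (central differences,
relative step 1e-4) to obtain the observed information and the gradient of
each coefficient's variance, giving `df = 2 g² / (∇g' Var(θ) ∇g)`, clamped
to [1, n − p]. When the information matrix is unusable the residual df
(n − p) is used instead; the `df_method` column records which. The profiled
likelihood is also checked against the fitted model's log-likelihood
(agreement ~1e-8), tying the df machinery to the actual fit.

Trait-modulation ("interindividual") models add, at any ladder level, the
six terms `Sample × {WF, CAPS}` and `{Length, Width} × Sample × {WF, CAPS}`
(plus implied lower-order terms). By default the WF entering these models
is the *estimated* Weber fraction from the categorization fit, not the
generative `w_m`, mirroring the two-task structure; subjects failing the
pseudo-R² chance gate (when enabled) are excluded. A sensitivity re-fit on
second-and-third blocks only checks that the effects of interest survive
without the nonstationarity-affected first blocks.

## Pipeline, seeding and problem sizes

`run_pipeline` sequences population → both tasks → WF fits (+ optional
chance gate) → censoring → slopes → ladder → comparison → trait model, and
writes CSV/JSON artifacts plus a config snapshot. Every random draw
descends from the single config seed via `numpy.random.SeedSequence`
spawning (one child stream per stage, then per subject), so identical
configs produce byte-identical CSVs. `recovery_experiment` repeats the
pipeline across seeds and tabulates WF recovery, the signs/p-values of the
trait interactions, and the slope orderings.

Problem sizes used by the shipped checks are the study's own where that is
affordable: full 972-trial sessions and n = 40 cohorts for the
trait-dissociation replications (20 seeded repetitions), 100 subjects for
WF recovery, 59-trial categorization sessions throughout. The null
distribution for chance-level classification defaults to 10,000 refits
(500,000 available via config); shipped calibration checks use 4,000 null
refits against 1,000 fresh responders.

## What the synthetic data do and do not establish

The generator reproduces the design's structure (trial counts, orderings,
adaptive feedback), scalar measurement/production noise, BLS biases, a
monotone CAPS-compression link, and optional prior adaptation. It does not
emulate lapses or attention failures in the reproduction task, feedback-
driven learning, reference biases in categorization, correlated trait
structure beyond the CAPS-γ link, or model mismatch between the observer
and the analysis (the simulated observer *is* a BLS observer). Passing
recovery tests therefore show that the pipeline detects these effects when
they exist as modeled and stays calibrated when they do not — not that the
corresponding empirical effects must exist, nor that the analysis is robust
to every real-data pathology. Known limitations: ML variance components are
biased low with few subjects (coverage checks use the Satterthwaite
t-intervals and many groups); the pseudo-R² of a true random responder can
be mildly negative (handled by empirical nulls); and the Cook's-distance
screen assumes an approximately linear production-sample relation, which
strong central tendency satisfies only locally.
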