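# Methods

## Scores

All four scores are deterministic functions of one participant's trial
sequence. The six-cell cross table (cue × response over rivalry trials;
mock trials never counted) feeds the two priming scores:

- original = (n_BB + n_RR) / (n_BB + n_RR + n_BR + n_RB), undefined when all
  rivalry trials were mixed;
- improved = (n_BB + n_RR + 0.5·n_BM + 0.5·n_RM) / N over all N rivalry
  trials, undefined only when N = 0.

Algebraically the improved score is a shrinkage of the original toward 0.5
by the factor (non-mixed / total): it is bounded in [0, 1], symmetric under
a global swap of the B/R labels, lies weakly between the original score and
0.5, never crosses 0.5 on mixed trials alone, approaches 0.5 monotonically
as mixed trials accumulate, and equals the original exactly when no mixed
trials exist. These are the invariants the property tests enforce.

Perceptual stability is the proportion of ordered pairs of successive
rivalry trials, both responses non-mixed, whose responses match. Pairs
containing a mixed response are dropped from numerator and denominator (no
half-weighting: the mixed-weighting argument is specific to the priming
score, where a mixed percept is itself evidence of no priming; for serial
dependence a mixed response is simply an unusable observation). By default
mock trials are transparent to adjacency — the rivalry trials on either side
of a mock still form a pair — because the imagery period between rivalry
presentations, not the mock display, is the hypothesized disruptor;
`ScoringConfig(break_at_mock=True)` breaks chains at mocks instead.

The difference score is improved − stability. Verbal descriptions of this
contrast sometimes run the other way ("stability versus priming"); we fix
the orientation so that the score *increases* with imagery vividness,
matching the positive sign of its regression slope on VVIQ. Aphantasics —
stability-dominant, priming-poor — therefore sit at the negative end.

Undefined scores are `None`, never an imputed number; the statistics drop
them pairwise and report the effective n.

## Validation rules

A mock trial is answered correctly when the response matches the displayed
color (a `mixed` response to an unambiguous display counts as an error).
The compliance gate admits sessions with at most one mock error (policy
default). Sessions without mock trials pass vacuously and carry a warning.
The 20% mixed-proportion threshold only *flags* by default: exclusion is
unnecessary under the improved score, and the legacy exclude-over-threshold
behavior is an explicit opt-in (`--legacy-exclude-mixed`).

The mock-trial imagery-consistency bias is operationalized per participant
as (proportion of mock trials answered with the cued color) − (proportion of
mock trials whose displayed color equals the cued color); zero means
responses track the display with no pull toward the imagined pattern. A
cohort-level one-sample t against zero is provided. This is one reasonable
operationalization; others (e.g., signed error-direction counts) exist.

## Cohort simulator

The generator emulates the task design: the trial stream inserts a mock with
probability 0.125 per slot and terminates once 32 rivalry trials are done,
so the mock count is random (≈4–5); the rivalry cue sequence is an exactly
balanced shuffled multiset. Per rivalry trial the response is mixed with
probability `mixed_base · (1 − v·κ)`, otherwise red with probability
`logistic(priming_gain · v · x_cue + stability_weight · (1 − v) · x_prev)`,
where `v ∈ [0, 1]` is latent imagery strength, `x_cue = ±1` encodes the cue
and `x_prev ∈ {±1, 0}` the previous non-mixed rivalry percept. The logistic
form and the `(1 − v)` damping of stability are modelling idealizations: the
task itself cannot separate priming from stability on cue-dominant trials,
but the generator makes them separable by construction so that recovery can
be measured against ground truth.

Group phenotype defaults were chosen once to reproduce the study-scale
descriptives of a 38-aphantasic / 73-control cohort: aphantasic
`v ~ N(0.08, 0.06)` and control `v ~ N(0.55, 0.18)` (clipped to [0, 1]) put
the aphantasic VVIQ mass at or below the diagnostic cutoff of 32 and make
the cohort VVIQ distribution bimodal; mixed-percept baselines of 0.22 / 0.19
match the observed group mixed proportions; `stability_weight = 2.0` gives a
v≈0 observer a repeat probability of logistic(2) ≈ 0.88 and hence stability
scores in the low 0.8s against mid 0.7s for controls; `priming_gain = 2.5`
puts strong imagers' priming scores in the 0.75–0.9 range. VVIQ is emitted
as `round(16 + 64 · clamp(v + ε, 0, 1))` with ε ~ N(0, 0.05) on the unit
scale — noise is on the latent scale *before* the 16–80 mapping, so a
noiseless v = 0.25 lands exactly on 32.

`simulate_validation_cohort` defines the conditions for parameter-recovery
studies: v uniform on [0, 1] and, crucially, κ = 1, coupling the
mixed-percept probability to absent imagery (`mixed_base · (1 − v)`). That
coupling — weak imagers produce the indecisive trials — is the hypothesized
mechanism that makes mixed trials informative. It is also necessary: if
mixed percepts occur independently of v (κ = 0), the improved score is a
randomly-shrunken copy of the original and recovers the latent trait no
better. With the coupling on, the improved score correlates with true v at
least as well as the original in effectively all replicates at
`mixed_base = 0.4`, and the two scores agree to |Δ| < 0.02 on average when
`mixed_base = 0.05`.

Seeding: one master `SeedSequence`; per-participant child streams are
spawned in participant order, so cohorts are reproducible trial-for-trial
and insensitive to scoring-side consumption of randomness.

What the generator does **not** emulate: piecemeal rivalry dynamics, eye
dominance drift (calibration is assumed to have removed it), response
latency, attention lapses, and any willingness-to-report bias that mimics
perceptual priming. Passing recovery tests therefore show that the scoring
machinery extracts a latent trait from data *of this structure*; they are
not evidence about mechanisms the generator does not contain.

## Statistics

- Correlations: `scipy.stats.pearsonr` on complete pairs; zero-variance
  input yields an undefined marker rather than an exception.
- Dependent-correlation comparison: Steiger's Z for two correlations sharing
  a criterion, using Fisher z transforms and the pooled-correlation estimate
  of their covariance. One-tailed p is the default — the question is
  directional (does the improved score explain *more* variance?) — with
  two-tailed by flag. Preconditions: n ≥ 10 and a positive semidefinite
  correlation triple. A Monte-Carlo test confirms the nominal 5% type-I rate
  under a trivariate-normal null (n = 200, 2,000 replicates).
- Group contrasts: Welch's unequal-variance t with Welch–Satterthwaite df
  (fractional df in reports signal this choice) and Hedges' g, i.e. pooled-SD
  Cohen's d with the small-sample correction 1 − 3/(4(n₁+n₂) − 9). Verified
  against pingouin to 1e-10.
- Median split: ties at the median go to the low subset; each subset reports
  both score-VVIQ correlations and their Steiger comparison.
- Meta-analysis: correlations are Fisher-transformed with within-study
  variance 1/(n − 3); the DerSimonian–Laird moment estimator of tau²
  (truncated at zero) comes from `statsmodels.stats.meta_analysis`; pooled z
  is back-transformed to r. Heterogeneity: Cochran's Q with df = k − 1 and
  I² = max(0, (Q − df)/Q)·100. Influence exclusion removes the study with
  the largest |standardized residual| (z_i − μ̂)/√(v_i + τ̂²) above the
  threshold, re-pools, and repeats until none exceed it or k = 2 — the
  threshold defaults to 3. Verified against `metafor::rma(method = "DL")`
  to machine precision on a two-study fixture.

## Bounded-pair simulation

If behavioral imagery performance can exceed self-report (unconscious
imagery) but self-report cannot exceed the imagery representations the task
detects, admissible (vviq_norm, br_score) pairs occupy the triangle
{x ≤ y} of the unit square. Uniform rejection sampling on that triangle is
the minimal generator consistent with that constraint; its Pearson
correlation is exactly 1/2 by moment integration (E[X] = 1/3, E[Y] = 2/3,
Var = 1/18 each, Cov = 1/36). The simulation (1,000 accepted pairs per
replicate, ≥ 20 replicates) reproduces this ceiling empirically; an
unconstrained control stays at r ≈ 0. No claim is made that 0.50 bounds
every conceivable generator — only the uniform-rejection model is
implemented and checked.

## Numerical and design notes

- Scores and flags are pure functions; CLI reruns are byte-identical.
- Session construction enforces strictly increasing unique trial indices and
  valid enum tokens; design-level expectations (cue balance within ±1, at
  least one rivalry trial, 33-trial sessions from over-collection) are
  reported by validation, not rejected, so real-world logs remain loadable.
- Log schema is fixed (`participant_id, trial_index, trial_type, cue,
  response`); case-insensitive token matching is an explicit dialect option,
  off by default.
- Test problem sizes (100-participant validation cohorts, 100 replicates for
  recovery, 2,000 replicates for test calibration) were chosen as the
  smallest scales at which the binomial/Monte-Carlo error bands in the
  assertions are comfortably interpretable.

## Known limitations

- The simulator's priming/stability separability is an idealization; on
  cue-dominant trials the real task confounds them.
- The mock-bias statistic is one operationalization among several.
- Whether to score cue-dominant and cue-suppressed subsets separately is an
  open design question; both priming scores here use all rivalry trials.
- Bayes-factor model comparison is out of scope.
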