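# Methods

This note documents the models, estimators and numerical choices behind
`encodelearn`, and what the synthetic-data validation does and does not
establish.

## The task and the data model

A same-different trial presents a first stimulus for a controlled encoding
duration *t* (ms), terminated by a backward mask, then a second stimulus;
the observer responds "same" or "different" within 5 s.  A trial log is a
delimited table of (participant, session, phase, trial, encoding duration,
pair type, response, response time).  The 11-session schedule interleaves
six training sessions (indices 2, 3, 5, 6, 8, 9; 360 trials at a fixed
100 ms) with four evaluation sessions (1, 4, 7, 10; 480 trials, 60 per
duration at 17, 50, 84, 117, 150, 234, 500, 1000 ms, half same / half
different) and one generalization session (11) with novel exemplars.  The
schedule is configurable; this one is the default.

Filtering keeps responses inside the closed interval [0.2, 5.0] s.  The
lower cut removes anticipations, the upper is the response deadline; the
endpoints are included so a response exactly at the deadline remains
analyzable.  Omitted responses (`response = none`) are never scored
correct, are excluded from hit/false-alarm counts, and are reported as
`n_omit`.  Participants are included when their pooled sensitivity
improves by at least 0.4 d′ between the baseline session (1) and the
criterion session (8); the comparison is inclusive and pooling uses all
RT-valid trials of each session.

## Sensitivity for same-different data

"Different" pairs are the signal class: a hit is a "different" response to
a different pair, a false alarm a "different" response to a same pair.
Three decision models convert corrected rates (h, f) to d′:

* **yes-no**: d′ = z(h) − z(f), criterion c = −(z(h)+z(f))/2.  A simple
  index that treats each trial as a single detection decision; it
  understates the underlying stimulus separation in a two-observation
  design but is what many published analysis scripts compute.
* **differencing**: respond "different" when |x₁ − x₂| > k;
  FA = 2Φ(−k/√2), H = Φ((d′−k)/√2) + Φ((−d′−k)/√2).  Inversion solves k
  from FA in closed form, then brackets d′ on [0, 10] (Brent, |residual| ≪
  1e−9).
* **independent observation** (default): each observation is categorized
  independently against a criterion k and the response is "different" when
  the categorizations disagree.  With a = Φ(−k), b = Φ(d′−k):
  H = a(1−b) + (1−a)b and FA = a(1−a) + b(1−b); the unbiased criterion
  k = d′/2 attains pc_max = Φ(d′/2)² + Φ(−d′/2)².  Inversion is closed
  form: s = a+b solves s² − 2s + (H+FA) = 0, p = ab = (s−H)/2, and a, b
  are the quadratic roots; d′ = z(b) − z(a) is identical for both s
  branches, and the conservative k = −z(a) is reported.

Two facts about the independent-observation model shape the estimator.
First, its reachable (H, FA) set is restricted: H + FA ≤ 1 always (with
equality exactly at the unbiased criterion), and a further fold excludes a
band of conservative rate pairs; a noisy data cell frequently lands
outside the manifold.  The implementation therefore verifies the exact
inverse by forward evaluation (residual < 1e−7) and otherwise resolves the
cell on the unbiased boundary, d′ = 2z((1+√(2pc−1))/2) with
pc = (h+1−f)/2, which is continuous with the exact inverse at H + FA = 1.
Second, d′ is *not* globally monotone in h at fixed f for this model (the
exact solution diverges at the fold edges); monotonicity holds along the
unbiased manifold and within the boundary regime, which is what the tests
assert.

Rate corrections: `half_count` (default) replaces 0 and 1 by 1/(2N) and
1 − 1/(2N) with each cell's own N; `log_linear` applies (count+0.5)/(N+1)
everywhere; `none` returns raw proportions flagged degenerate at 0/1.

`sensitivity_table` defaults to *signed* estimates: a cell with h < f gets
the negated mirrored solution rather than a hard 0.  A zero floor
rectifies noise around zero sensitivity and biases group means upward at
short durations (and fitted onsets downward by ~10 ms); signed estimates
average out.  The published group table is consistent with signed values
(a 17 ms mean of 0.169 with SD 0.303 implies individual values below
zero).  The raw model functions keep the d′ = 0 convention behind a
`signed` flag.

**Scale caveat.**  The choice among the three models changes the d′ scale,
and which formula the original study's script computed cannot be verified.
The published table's short-duration SDs (≈0.30 at 17 ms) sit well below
the sampling noise floor of the true independent-observation inversion at
30/30 trials (≈0.85) and match the yes-no formula's noise (≈0.32); its
maximum printed d′ (3.66) also sits under the yes-no half-count ceiling
2z(59/60) = 4.256.  Published trial-level sensitivities are therefore most
plausibly on the yes-no scale.  The package default remains the
independent-observation model (matched between the synthetic generator and
the estimator, so that parameter recovery is well defined); analyses of
real data that must match the published scale should set
`model="yesno"`.  The group-mean *fits* shipped with the package are
unaffected: they consume the published means directly.

## The shifted-exponential encoding curve

    d′(t) = A (1 − e^(−R(t − I)))   for t > I,   else 0

with A the asymptotic sensitivity (d′), R the extraction rate (per ms
internally; reported ×1000 as d′/s) and I the onset of information
availability (ms).

**Objective.**  The least-squares objective is the *smooth* expression
A(1 − e^(−R(t−I))) without the piecewise clamp — a Levenberg-Marquardt
solver requires a differentiable residual, and the clamped objective has a
different, flatter optimum whenever it can zero out the shortest-duration
point (for the untrained-session means it moves the onset from 14.7 ms to
28 ms).  All sensible optima keep every design duration in the smooth
regime, where the two forms coincide; `predict` on a fitted result always
returns the piecewise curve (exactly 0 at and below the onset).

**Search.**  Default bounds A ∈ [1, 10], R ∈ [1e−4, 10] per ms,
I ∈ [1e−7, 500] ms, enforced by the trust-region-reflective variant of LM;
64 Latin-hypercube starting points over the box (rate sampled
log-uniformly), lowest-SSE converged solution wins, SSE ties (< 1e−10)
broken by smaller I.  A solution at a bound is flagged (`at_bound`) —
the fully-trained sessions pin I at its lower bound.  `bounded=False`
switches to plain unbounded LM (the box then constrains only the starting
points); on all five shipped datasets the bounded and unbounded optima
agree.

**Uncertainty and fit quality.**  R² = 1 − SSE/SST with SST about the mean
of the observed values.  Standard errors are the linearized covariance
s²(JᵀJ)⁻¹ at the optimum with the analytic Jacobian and s² = SSE/(n−3);
they are cross-checked against a finite-difference Jacobian in the tests.
This is the conventional choice when a source reports parameter SEs
without stating a method, and it reproduces the published session-1 SEs
(0.12 on A, 0.93 d′/s on R, 6.5 ms on I) to the printed precision.

**Inversion.**  t = I − ln(1 − d′*/A)/R for 0 ≤ d′* < A.  The criterion
level d′ = 1.68 corresponds to 80% correct through the unbiased yes-no
correspondence d′ = 2z(pc).

**Known caveat.**  The generalization-session fit on the *published*
2-decimal means yields (A = 3.445, R = 14.45 d′/s, I = 4.0 ms,
R² = 0.978), whereas the source prints (3.473, 13.3, 0.0, 0.9757); the
printed parameters give a worse SSE on the printed means than our
optimum, so the source evidently fit unrounded means.  Two-decimal
rounding is enough to move the weakly identified R/I pair by ~9% / ~4 ms.
The three-decimal per-session tables reproduce the printed parameters to
the printed precision.

## Inference

The repeated-measures ANOVA is the univariate decomposition for complete
balanced data; each within-subject effect is tested against its own
effect-by-subject interaction, with partial η² = SS_effect/(SS_effect +
SS_error).  Greenhouse-Geisser ε = tr(M)²/(q·tr(M²)) from the covariance M
of orthonormally contrasted scores (Helmert basis; ε ∈ [1/q, 1], ε = 1
exactly when q = 1); corrected p-values scale both F degrees of freedom by
ε and are reported alongside uncorrected ones (convention: apply the
correction when Mauchly's p < .05).  Mauchly's W uses the chi-square
approximation with the second-order Anderson correction term.  For
two-factor designs, ε and W are computed per effect (marginal means for
main effects, doubly-contrasted cells for the interaction), which the
usual off-the-shelf routines do not provide.

Paired and one-sample t-tests report two-tailed p, 95% CI and Cohen's d
(paired: mean of differences over SD of differences — matching the
magnitudes printed alongside paired tests in this literature; users
comparing with pooled-SD variants should rescale).  Summary-statistic
input (mean, SD, n) is supported because printed tables are often the
only reproducible input.  Identical vectors return t = 0, p = 1, d = 0 by
convention; zero variance with a nonzero mean is an error.

Benjamini-Hochberg runs the step-up rule at q = 0.05 by default and
returns the per-rank thresholds (i/m)q, the rejection set, and
monotone-enforced adjusted p-values.  The pipeline applies BH within each
comparison family — successive training sessions; successive sessions per
duration (one family per session pair); successive durations per session;
generalization vs first/last evaluation session — because the original
correction families are not stated; the families are visible in the
report keys.

## Synthetic observers

The generator emulates the full study so that every stage is testable and
the estimator chain can be validated by parameter recovery:

* **Population.**  Per-participant encoding-curve parameters are drawn
  from truncated normals around session-dependent population means
  (defaults shaped like the published fits: A 2.88→3.60, R 7.1→15.0 d′/s,
  I 14.7→0 ms across training levels), truncated to the fit bounds.  Each
  participant has one latent quantile per parameter family shared across
  sessions, giving stable individual differences.  Between-subject SDs
  (sd_A = 0.5 d′, sd_R = 25% relative, sd_I = 5 ms; training d′ SD 0.5)
  are assumptions — the source prints only group-level SEs — chosen to
  produce group d′ SDs in the published 0.3–0.9 range.
* **Responses.**  Per trial, true d′(t) comes from the observer's curve;
  response probabilities from the configured decision model (default
  independent observation, matched to the default estimator) at criterion
  k = d′/2 + bias (bias 0 by default; for the differencing model the
  accuracy-maximizing k is found numerically).  With probability
  `lapse_rate` (default 0.01, typical for attentive trained adults) the
  response is replaced by a fair coin.
* **Training trajectory.**  True d′ at 100 ms follows a saturating
  exponential over training-session ordinal (start 1.0, end 2.1, rate
  0.45) — the published learning curve shows the shape but no generative
  model, so this is a simulator choice, not a claim about the source.
* **Response times.**  Lognormal (median 0.7 s, σ = 0.35), with 2% of
  trials redrawn outside the [0.2, 5.0] s window so the filter path is
  always exercised.
* **Generalization.**  Session 11 reuses each participant's session-10
  curve with an asymptote decrement (default 0.1) and includes the first
  16 participants.

Everything is deterministic given (config, seed): seeds are spawned per
(participant, session) from a `SeedSequence`, and regenerated studies are
byte-identical on disk.  The manifest records every generating parameter.

**What recovery shows.**  Fitting the group-mean d′ of simulated
untrained-session studies (27 observers, 60 trials per duration, seeds
0–19) recovers the *realized sample's* generating parameters — the mean
A/R/I of the drawn observers, as recorded in the manifest — within ±0.15
(A), ±15% (R) and ±10 ms (I) in 16/20 seeds.  Scoring against realized
rather than nominal population values separates estimator error from
participant-sampling error (the sample mean of A alone has SE ≈ 0.10 at
these settings, irreducible by any estimator).  Passing this does not
certify real-data behavior: real observers may lapse more, drift across a
session, respond with sequential dependencies, or follow none of the three
decision models, none of which the generator emulates.

## Problem sizes and runtime

Unit tests use scaled-down studies (6–10 participants, 20–30 trials per
duration) chosen to keep the full suite around a minute while leaving
every stage statistically identifiable; the recovery and Monte-Carlo
checks run at the full published design (27 observers, 60 trials per
duration; 10⁶ Monte-Carlo samples per decision rule).  The acceptance
script fits only the published 8-point group-mean curves and completes in
seconds.

## Known limitations

* The independent-observation inversion off the model manifold is a
  boundary projection, not maximum likelihood; at 30 trials per class the
  difference is well inside sampling noise.
* Per-participant curve fitting is available but not the default; the
  pipeline fits group means, so between-subject parameter variance is not
  itself estimated.
* The ANOVA requires complete balanced data (participants missing cells
  are dropped by the pipeline before testing); no mixed-effects fallback.
* No Huynh-Feldt correction, no unequal-variance or ROC-based SDT, no
  Bayesian fitting; alternative growth models would need a new model
  class.
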