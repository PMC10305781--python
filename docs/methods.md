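# Methods

This note documents the models, conventions and numerical choices behind
`bowmimic`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Bow kinematics

The bow-string contact point is computed as the pair of closest points
between two 3D segments: the bow axis (frog → tip markers) and the string
axis (bridge marker toward the scroll, truncated to a string length of
330 mm). The closest-pair parameters are obtained by the standard clamped
quadratic minimisation for segment-segment distance, vectorised over
frames. Two arclengths — contact point to frog along the bow, contact
point to bridge along the string — define the per-frame 2D bowing curve;
the bow-string angle (tilt) is carried alongside. This geometric definition
was chosen because it is canonical and oracle-checkable (the test suite
verifies it against dense two-segment grid sampling); distances are
invariant under rigid transformation of the whole marker set, which the
suite asserts.

Derivatives (bow velocity, acceleration, jerk) are taken after zero-phase
low-pass filtering: 4th-order Butterworth applied forward-backward, default
cutoff 12 Hz, standard practice in movement science and comfortably above
bowing frequency content at the 120 Hz capture rate. Differentiation is by
central differences (one-sided at the ends), a linear operator, which the
property tests exploit.

Joint angles follow the ISB convention of decomposing the distal segment's
orientation in the proximal segment's frame with fixed Euler sequences:
shoulder Y–X–Y (plane of elevation, elevation, axial rotation), elbow and
wrist Z–X–Y (flexion-extension first). Segment frames are built from
3-marker clusters; collinear clusters raise an error naming the segment.
Decompositions round-trip to 1e−9 away from the Y–X–Y singularity at zero
elevation (physiological bowing postures are far from it).

Loudness is linear RMS amplitude in centred windows (default 50 ms)
evaluated on the motion time grid. Linear rather than dB because the
downstream gate is a *ratio* against the median, and ratio gating is
scale-invariant only on a linear scale. A fundamental-frequency estimate
(windowed autocorrelation with parabolic peak refinement) is available but
carried as metadata only; no downstream statistic consumes it.

## Stroke segmentation and gates

Strokes are segmented on the **leader's** bow-position signal: moving
intervals (|v| > 10 mm/s) are split at velocity sign changes, then
sub-strokes shorter than 80 ms or with net excursion under 10 mm are merged
into their neighbours. The hysteresis thresholds sit well below any musical
stroke and exist to absorb tremor-induced micro-reversals. Stroke windows
are half-open `[start, end)` so consecutive strokes partition time.

Two gates then select the analysable strokes:

* **Length**: keep strokes whose excursion strictly exceeds 150 mm
  ("exceeding" read as strict inequality; configurable).
* **Loudness**: keep strokes whose mean in-window RMS reaches 15 % of the
  median per-frame loudness of the performance. The median is scoped per
  performance because gating happens before any cross-performance pooling.
  The gate is applied to the leader's audio by default — the gates define
  the analysable regions of the reference performance — with the follower's
  audio available as a configuration choice.

Both gates are order-independent (they commute), which the suite asserts
alongside brute-force enumeration of survivors.

Surviving leader windows are applied verbatim (same clock-time frames) to
the follower: the design assumes hardware-synchronized recordings, so no
elastic (DTW-style) alignment is performed — lag between performers is part
of the imitation error being measured. Both 2D curves and speed profiles
are linearly resampled to 100 points per stroke so Procrustes alignment
operates on matched point sets.

## Metrics

**Procrustes distance.** Both curves are centred and scaled to unit
Frobenius norm; the optimal orthogonal alignment (reflection allowed) comes
from the SVD of the cross-covariance, with the optimal uniform scale
s = Σσᵢ. The residual `PD = 1 − (Σσᵢ)²` lies in [0, 1], is symmetric, and
is invariant to translation, rotation, reflection and uniform scaling of
either curve — but not to anisotropic scaling or point reordering (asserted
with counterexamples). This is the standard "Procrustes distance" of the
shape-analysis literature (it equals scipy's `procrustes` disparity, which
the tests use as a library cross-check); scaling and reflection can be
switched off via arguments.

**SPARC.** The speed profile used is the absolute derivative of bow
position along the bow (the musically meaningful bowing speed), not the 2D
curve speed; this is configurable. Parameters follow the metric's
originating literature: cutoff 10 Hz, amplitude threshold 0.05, zero
padding to `2^(ceil(log2 N) + 4)`. The spectrum is normalised by its DC
value (hence amplitude invariance, exact to rounding), limited to the
cutoff band, truncated at the last frequency still reaching the threshold,
and the index is the negative arc length over that band with the frequency
axis rescaled to [0, 1].

One numerical caveat documented deliberately: at the canonical padding a
~1 s stroke leaves only a few dozen spectral samples in band, so the
discrete arc length is a few 1e−3 below its dense-grid limit. The oracle
tests therefore check (a) exact agreement (1e−9) with an independent
direct-DTFT evaluation on the same grid at the deployed defaults, and
(b) 1e−3 agreement with an 8×-oversampled dense spectrum when the metric is
run at `pad_level=8`, where the sum has converged. Comparisons between
performers always use identical parameters, so the offset cancels in dSI.

**dSI** = SPARC(follower) − SPARC(leader): positive means the follower
moved more smoothly than the reference. Swapping performers negates it
exactly.

## Calibration

Per-stroke metric values are z-scaled with the pooled mean and sample SD
over *all* strokes of all performances for that metric (per-performance
scaling is available but pooled scaling is the default, since the
downstream model compares cells on a common scale). One median per
participant × condition × trial cell gives the analysis dataset — 88 rows
for the default 11 × 2 × 4 design; empty cells are a hard error naming the
cell. Finally the (piece × violin-section) group median is subtracted,
leaving every group median exactly zero (to rounding for even-sized
groups), so systematic difficulty differences between stimuli cancel while
within-group differences are preserved exactly.

## Hierarchical model

The response per cell is modelled as Gaussian with condition cell means
(no intercept) and two additive varying-intercept groupings —
condition × participant and condition × trial (the grouping syntax
`(1 | condition:participant + condition:trial)` expands to two separate
intercept terms). Trials are treated as factors: order, not time, is the
meaningful axis. The covariate variants add condition × covariate fixed
effects plus covariate slopes varying by both groupings; the covariate is
standardised before entering. Slope and intercept variance components are
independent (no intercept–slope correlation) — a deliberate simplification
that keeps every Gibbs conditional conjugate; none of the reported
quantities (contrasts, Bayes-factor calibration) depends on that
correlation.

**Priors.** Condition means ~ Normal(0, (2.5·sd(y))²); every group SD and
the residual SD ~ half-Student-t(3, 0, 2.5·sd(y)). These are
weakly-informative defaults of the regression literature, configurable on
`ModelSpec`.

**Sampler.** A blocked Gibbs sampler, authored in-package: all Gaussian
coefficients are drawn jointly from their multivariate-normal full
conditional (Cholesky of the ~30–100-dim precision matrix); each scale
parameter uses the inverse-gamma auxiliary representation of the half-t
prior, making the conditionals exact. Because centred-parameterisation
Gibbs mixes slowly for weakly identified variance components, each
iteration adds an interweaving (ASIS) step: every group SD is re-drawn in
the non-centred parameterisation — where it enters the likelihood linearly
— by univariate slice sampling against its Gaussian-times-half-t
conditional, then the effects are rescaled. This brings split-R̂ below 1.01
and bulk ESS above ~1000 at 4 chains × 1000 draws. Convergence is always
computed (ArviZ split-R̂ and ESS per parameter) and a failed fit is flagged
on the summary, never silently returned.

Defaults are 4 chains × 1000 warmup × 1000 draws — at the sampler's ~1–2 s
per fit this makes the whole workflow interactive; larger runs
(e.g. 5000 warmup / 35000 draws per chain, mirroring heavyweight NUTS
practice) are one `SamplerSettings` away and change nothing at the
tolerances used here. Everything is seeded: identical inputs give
bit-identical posteriors.

**Model comparison.** Conditional on the scale parameters the coefficients
integrate out analytically, so the marginal likelihood is a
low-dimensional integral over 3–5 SDs. It is estimated by importance
sampling with a Gaussian proposal in log-SD space fitted to the Gibbs
posterior (covariance inflated 1.5×), with the importance-sampling ESS
attached as a diagnostic (a warning below ESS 100). The Bayes factor is the
ratio of the two marginal likelihoods; PSIS-LOO (ArviZ) supplies the
supplementary predictive check with the standard error of the pointwise
ELPD difference. Calibration is verified by simulation: on nested synthetic
data the true simpler model wins in ≥80 % of replicates, and a strongly
informative covariate flips the factor.

**Contrasts.** Cell posteriors are β_c (+ w_{c,t} when a trial is named).
The grammar `cXY` / `cXtAB` / `cXYtA` maps to draw-wise differences;
estimates are posterior medians with 95 % equal-tailed intervals, and the
probability of direction is P(contrast > 0) — so a value of 0.02 is read as
0.98 certainty in the negative direction. Telescoping
(`c1t12 + c1t23 = c1t13`) and duality (`pd(A−B) = 1 − pd(B−A)`) hold
exactly on the draws. Bayesian R² is the per-draw
var(predicted)/(var(predicted)+σ²), with group effects included
(conditional) or excluded (marginal); posterior medians are reported.
Posterior predictive checks compare observed mean/SD/quantiles against 500
replicated datasets.

## Questionnaires

Scales are scored as per-administration item means (WPQ 1–7, MPQS and MPQP
1–5); the MPQ composite is the mean over the pooled MPQS + MPQP items.
Missing items are prorated (mean of available items) and logged — no
imputation. Cronbach's α uses the sample-variance form
`k/(k−1)·(1 − Σᵢ var(itemᵢ)/var(total))`, identical to the
covariance-matrix closed form to 1e−10 and cross-checked against pingouin.
Perceived difficulty (0–100) passes through untransformed.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Leader**: bow displacement per stroke follows the minimum-jerk profile
  `x(τ) = L(10τ³ − 15τ⁴ + 6τ⁵)` — the standard smooth-reaching model in
  motor control, chosen because real leader kinematics were never
  specified, only recorded. Bridge distance wanders slowly (0.3 Hz) so the
  2D curve is non-degenerate. Audio is a 440 Hz tone gated to strokes with
  10 ms ramps — only its RMS envelope matters downstream. Arm clusters are
  posed plausibly from bow position so the joint-angle path is exercised.
* **Follower**: the leader's bow signal, lagged (linear interpolation),
  gain-scaled about its mean, offset, plus white Gaussian noise low-passed
  at 20 Hz (rescaled to the requested SD, so the knob is interpretable) and
  a sinusoidal tremor that selectively degrades smoothness. Neutral
  parameters return the leader bit-for-bit, giving the end-to-end
  PD = dSI = 0 identity. Noise and tremor raise PD and lower SPARC
  monotonically, which the suite verifies over seeded replicates.
* **Cohort**: 11 participants × 2 conditions × 4 trials by default, with
  the piece/violin-section assignment cycling a fixed two-section pattern
  (two pieces per section, four piece × section groups). Per-participant
  baseline fidelity is log-normal around the design baseline (spatial noise
  4 mm, lag 40 ms, tremor 1.5 mm at 8 Hz), keeping magnitudes positive.
  The default condition effect multiplies noise and tremor by 1.5 in the 2D
  condition and shifts latent presence by −0.6 Likert units — the
  "stereoscopy helps imitation and presence" scenario. Every cell's
  realised parameters and deltas are returned as a ground-truth ledger.
  Pieces are ~8–12 s with 12–16 strokes: long enough for ~15 gated strokes
  per cell, short enough that the full 88-cell pipeline runs in seconds —
  a deliberate problem-size choice.
* **Questionnaires**: latent presence per administration = scale base +
  condition shift + participant offset (SD 0.5) + cell noise (SD 0.35);
  items add independent noise whose variance is solved from the
  Spearman-Brown/α algebra so the *expected* Cronbach's α matches the
  requested reliability, net of the ~1/12 discretisation variance
  introduced by rounding to Likert points (round half up, clipped).

What passing tests therefore show: the pipeline recovers known effects of
realistic size at the design's scale, with calibrated type-I behaviour.
What they do not show: real violinists' error structure (the noise model is
a modelling choice, documented as such), marker occlusion/gap-filling,
asynchronous clocks, room acoustics, or real questionnaire response styles
(acquiescence, ceiling effects beyond clipping).

## Known limitations

* The loudness gate's audio source (leader vs follower) and the z-scaling
  scope are protocol ambiguities; the defaults above are documented
  choices, both configurable.
* The Gibbs sampler covers the Gaussian likelihood used here; other
  likelihoods would need a different engine.
* Prior-sensitivity of the Bayes factor is real: factors are reported with
  the priors above, and the importance-sampling ESS diagnostic should be
  checked before quoting them.
* Joint angles are computed and exported but no downstream statistic
  consumes them; they exist for parity with the kinematics export format.
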