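# bowmimic

Motor-imitation analytics for bowed-string performance.

When an orchestral violinist rehearses with a (virtual) section leader, the
quality of the imitation lives in the bow arm: how closely the follower's
bowing gesture tracks the leader's, and how smoothly it is executed.
`bowmimic` implements that analysis end to end, for researchers in movement
science and music-performance studies who have synchronized leader/follower
motion-capture and audio recordings — or who want to prototype such a study
on synthetic data with known ground truth:

1. **Kinematics** — from 3D marker trajectories (bow frog/tip, violin
   bridge/scroll, right-arm clusters) to the bow-string contact point: the
   distances from the contact point to the frog and to the bridge form a 2D
   bowing curve per performance; ISB-style wrist/elbow/shoulder angles are
   computed from 3-marker segment clusters.
2. **Stroke segmentation and gating** — strokes are bounded by bow-velocity
   reversals on the *leader's* signal (with hysteresis against
   micro-reversals); only strokes exceeding 150 mm of bowing length and
   reaching at least 15 % of the performance's median loudness are analysed.
3. **Per-stroke metrics** —
   - **PD**, the Procrustes distance between leader and follower bowing
     curves: both N×2 curves are centred, scaled to unit norm and optimally
     aligned (rotation/reflection via SVD, optimal uniform scale), leaving
     the residual `PD = 1 − (Σᵢ σᵢ)² ∈ [0, 1]`, where σᵢ are the singular
     values of the cross-covariance. PD = 0 means identical gesture shapes.
   - **SPARC**, the spectral arc length of a speed profile: the negative
     arc length of the amplitude-normalised magnitude spectrum over an
     adaptively truncated low-frequency band; **dSI** = SPARC(follower) −
     SPARC(leader), so dSI > 0 means the follower moved more smoothly.
4. **Calibration** — per-stroke values are z-scaled, reduced to one median
   per participant × condition × trial cell, and centred by the
   (piece × violin-section) group median to cancel stimulus difficulty.
5. **Hierarchical Bayesian contrasts** — the calibrated dataset is fitted
   with a Gaussian cell-means varying-intercept model,

   ```
   y ~ 0 + condition + (1 | condition:participant) + (1 | condition:trial)
   ```

   optionally extended with a covariate (perceived difficulty, or PD for
   the presence models) in interaction with condition and with varying
   slopes. Models are compared by Bayes factor (marginal likelihoods with
   coefficients integrated analytically) plus a PSIS-LOO check, diagnosed
   with split-R̂ / ESS / Bayesian R² / posterior predictive checks, and
   summarised as directed contrasts: `c12` (condition 1 − condition 2),
   `c1t12` (trial 1 − trial 2 within condition 1), `c12t1` (condition
   contrast at trial 1), each with a 95 % credible interval and the
   probability of direction `pd = P(contrast > 0)`.
6. **Questionnaires** — presence scales (WPQ on 1–7, MPQS/MPQP on 1–5) are
   scored as per-administration means with Cronbach's α reliability, and
   run through the same contrast workflow.

A synthetic-data module (`bowmimic.synthetic`) generates leader
performances (minimum-jerk bow strokes, stroke-gated audio), followers with
controllable fidelity (tracking lag, gain error, offset, low-passed spatial
noise, high-frequency tremor), full cohort designs with per-participant
baselines and condition effects, and Likert questionnaire responses with a
target reliability — everything seeded and bit-reproducible, with a
ground-truth effect ledger for recovery tests.

## Worked example

The numbered scripts under `analysis/` run the default study — 11
participants × 2 conditions (2D / 3D avatar rendering) × 4 trials, where
the 2D condition degrades tracking fidelity (spatial noise and tremor
×1.5) and lowers latent presence:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_extract_metrics.py --seed 0
python analysis/03_calibrate.py       --seed 0
python analysis/04_fit_contrasts.py   --seed 0
```

Output of steps 2–3 (seed 0):

```
1300 strokes survived the gates across 88 cells (2.7 s)

mean metric by condition (raw, per stroke):
               PD     dSI
condition
2D         0.0188 -0.4154
3D         0.0171 -0.3531

calibrated dataset: 88 rows (one per participant x condition x trial)
max |group median| after calibration: 5.55e-17
```

The follower tracks the leader less faithfully in 2D (higher PD) and less
smoothly (lower dSI), and calibration leaves every piece × section group
centred at zero. Step 4 fits and contrasts every response; for the
smoothness metric it prints (seed 0):

```
== dSI ==
  Bayes factor (simple / covariate): 4049.68  elpd diff +4.55 +- 2.74
  converged: True (max R-hat 1.0063); R2 conditional 0.78, marginal 0.48
  c12 (2D - 3D): -0.415 [-0.783, -0.022], post prob 0.021
```

read as: perceived difficulty adds nothing (Bayes factor ≫ 1 for the
simpler model), and the 2D-minus-3D smoothness contrast is negative with
probability 0.979 — the injected "3D is smoother" effect is recovered with
strong directional evidence. Contrast tables
(`results/contrasts_<response>.csv`) have columns `Label, Estimate,
CI.Lower, CI.Upper, Post.Prob`.

The same pipeline is exposed as a CLI (`bowmimic simulate|extract|strokes|
metrics|stats|run`) for file-based use on real recordings (marker TSV +
PCM WAV).

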