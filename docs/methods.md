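# Methods

This note documents the models, estimators and numerical choices behind
`coupledraw`: what the synthetic task generator produces and why, how each
neural feature family is computed, how the multivariate network is trained
and evaluated, and where the design was genuinely open.

## 1. The simulated circle-line session

One session is 240 trials, 60 per condition (line-line, circle-circle,
line-circle, circle-line), in pseudo-random order with no condition
repeated more than 4 times consecutively (rejection-sampled permutations).
Trial durations are truncated-normal, mean 7.26 s, sd 1.91 s, floor 3 s;
trials are separated by 5 s of rest, and the first trial starts after 5 s
so every epoch has its full pre-onset baseline.

### Trajectories

Both hands draw 6 iterations of their instructed shape at a 60 Hz pen
rate. The nominal line is vertical (zero horizontal extent); the nominal
circle has radius 190 px, so an ideal circle's horizontal extent is
380 px, matching the magnitude of real circle-circle drawing. Interference
is a convex blend: each hand draws
(1−w)·own shape + w·other hand's shape, with w the condition's coupling
strength (default 0.3). In incongruent trials this bulges lines and
flattens circles; in congruent trials it is a no-op.

Motor variability has four components, all Gaussian:

| parameter | default | role |
|---|---|---|
| common trial scale sd | 0.03 | arousal-like common amplitude factor |
| hand asymmetry | 0.05 | right hand draws systematically larger |
| per-hand scale sd | 0.006 | residual independent amplitude noise |
| line bow | 50 px ± 2 %, +12 % right | horizontal postural sway (additive, outside the blend) |
| pen jitter | 2 px | per-sample digitisation noise |

The bow gives drawn "lines" their realistic ~100 px extent and is additive
rather than blended so the coupling morph stays strictly monotone in w.
The systematic hand asymmetries keep the congruent curvature difference
bounded away from the 1 px floor of the coupling index: CI = 1/|ΔC| is a
reciprocal, and without them occasional ΔC ≈ 0 trials would produce CI
outliers (0.5–1.0) that dominate every Pearson correlation — a regime real
participants do not show (their congruent CI is a tight 0.09 ± 0.02).
With these values a session yields mean CI ≈ 0.07–0.09 congruent versus
≈ 0.0075 incongruent, and per-condition extents near the real task's.

The per-trial **true CI** is computed from the generated (noisy)
trajectories by the same formula the analysis uses. The **latent coupling
drive** that the EEG encodes is z = tanh of the session-standardised
log₁₀ CI: monotone in CI, bounded in (−1, 1) so it can multiply envelope
gains, and correlated r ≈ 0.8 with raw CI (the tanh saturates for the
most extreme trials; this is the recovery ceiling any decoder inherits).

### EEG forward model

256 Hz, nine 10-20 motor channels (FC3 FCz FC4 C3 Cz C4 CP3 CPz CP4),
units µV. Each channel is

* pink (1/f-amplitude) background noise — 40 % of its amplitude shared
  across channels, which keeps baseline cross-channel coherence
  non-degenerate, the rest independent;
* alpha (8–13 Hz) and beta (13–30 Hz) band-limited Gaussian oscillations
  whose rest amplitude is snr × the in-band RMS of that channel's
  background (snr default 1).

During every trial each band envelope drops by a generic
movement-related factor 0.8 (raised-cosine ramps, 0.25 s). On top of that
the encoding mode decides how the drive modulates envelopes:

* `none` — no dependence anywhere.
* `univariate` — C3-alpha envelope gain 1 + 0.6·z, constant over the
  trial: classical single-channel ERD carries the drive linearly.
* `distributed_linear` — a fixed six-component channel-band mixture
  carries the same constant-gain code.
* `distributed_nonlinear` — the **latency code**: every channel-band
  shows a Gaussian desynchronisation dip (depth 0.6 of the envelope, sd
  0.12 of the normalised trial) centred at normalised time
  0.5 + 0.25·z plus per-channel-band jitter (sd 0.15, clipped to
  0.12–0.88). Dip depth and area are fixed, so *trial-mean* band power —
  the only thing ERD sees — is independent of the drive, and band-limited
  coherence is untouched; the drive lives solely in *when* the dip occurs,
  a nonlinear functional of the envelope time course, and the per-channel
  jitter makes any single channel-band an unreliable reader — recovery
  requires pooling latency estimates across several channel-bands. A
  matched-filter oracle (`nonlinear_oracle_readout`) that knows the
  mechanism but not the jitters decodes the drive at r ≈ 0.7–0.9 against
  true CI, which bounds what the network can achieve.

An earlier candidate for the nonlinear code — carrier pairs modulated by
per-trial random signs, with the drive in the within-pair product —
satisfies the same marginal-null property and is decodable in closed form,
but is *not learnable* by a 3600-input shallow network from 204 training
trials: parity-style codes present no first-order gradient signal, and
both our trainer and an adam-trained reference network score r ≈ 0 on held
-out trials. The latency code was adopted instead; it also matches the
motivation for keeping temporal dynamics in the multivariate features at
all.

All randomness flows from one master seed through named substreams
(schedule / trajectories / EEG / per-iteration training), so a session and
every downstream result is bit-reproducible.

### What the generator does not emulate

No ocular or muscle artifacts (the preprocessing hook for artifact removal
is a pass-through), no volume-conduction mixing beyond the shared noise
term, no 64-channel montage, no biomechanics. Passing tests therefore show
that the estimators and the decoding procedure behave correctly under a
controlled forward model — not that real recordings contain such a code.

## 2. Feature extraction

* **Filtering** — zero-phase (forward-backward) 4th-order Butterworth
  band-pass 0.5–35 Hz; the double pass gives 48 dB/octave effective
  roll-off and removes DC. Note a 50 Hz mains component, only half an
  octave above the corner, is attenuated to ~8 %, not eliminated.
* **Re-referencing** — subtraction of the mean of named reference
  channels; the generator emits already-referenced data, so the default
  is a pass-through.
* **Epochs** — −2 s to trial offset, sample-accurate; trials without the
  full pre-onset context are excluded with a log entry.
* **Time-frequency** — Morlet wavelets on 50 linearly spaced frequencies,
  1–35 Hz. Cycles scale as clip(f/2, 3, 7): a fixed 7-cycle wavelet at
  1 Hz would be ~11 s long and could not fit the shortest admissible
  epoch (3 s trial + 2 s pre-onset); 3 cycles at the low end (≈4.8 s
  support) just fits, and ≥14 Hz uses the conventional 7.
* **Baseline** — per-frequency *geometric* mean power over −2000…−500 ms,
  i.e. value(t,f) = log₁₀ P(t,f) − mean log₁₀ P_baseline(f). With
  single-trial wavelet power (≈exponentially distributed) an
  arithmetic-mean baseline sits ~0.25 log₁₀ units above the mean of the
  log, so it would report spurious suppression of ~−0.25 even for
  stationary noise; the geometric mean zeroes this bias (measured
  |mean ERD| < 0.05 on stationary input) and changes nothing about
  cross-trial correlations beyond a per-frequency constant. Negative
  values mean suppression (ERD), positive enhancement.
* **Time normalisation** — each trial's onset→offset log-ratio matrix is
  linearly interpolated onto 200 equally spaced normalised time points,
  giving the 200 × 50 per-trial, per-channel map.
* **ERD value** — mean of the map over all 200 time points and the
  in-band frequencies. Band membership is half-open [lo, hi) so a grid
  point at the shared 13 Hz edge belongs to alpha only; the top band is
  closed. A `results-variant` preset (alpha 8–12, beta 15–30) mirrors an
  alternative band definition that appears in the literature for this
  task.
* **Feature vector** — per channel and band, the in-band mean at each of
  the 200 time points (temporal dynamics kept), concatenated
  channel-major, band-minor: 9 × 2 × 200 = 3600 values per trial. By
  construction each ERD value equals the time-mean of its 200-point
  block, which the tests assert.
* **Coherence** — Welch magnitude-squared coherence, 1 s Hann windows,
  50 % overlap, over the trial window only; band-averaged, then averaged
  over the three pairs of each electrode triplet. Trials shorter than two
  windows are excluded (single-window coherence is identically 1). The
  estimator parameterisation is a declared choice; the conventional
  window/taper settings are exposed as arguments.

## 3. The multivariate network

Architecture 3600-100-1: tanh hidden units, identity output. Training is
classical full-batch gradient descent on MSE with momentum 0.9 and a
variable learning rate — lr₀ = 0.01, ×1.05 after an epoch whose training
error fell, step rejected and lr ×0.7 (momentum cleared) when the error
grows by more than 4 %. Inputs are min-max scaled to [−1, 1] per feature
*on the training set only*; the CI target is scaled the same way and
predictions are mapped back — mirroring the defaults of the MATLAB-style
feedforward tooling this training family comes from, and necessary for a
well-conditioned loss given CI's ~0.01–0.1 physical scale.
Initialisation is Nguyen-Widrow-style: hidden weight rows of norm 0.7,
biases uniform in (−0.7, 0.7), small symmetric readout.

Early stopping: training halts after `patience` consecutive epochs
without a new best validation MSE and returns the best-validation
parameters. The default is patience = 20 (max 300 epochs). The
conventional value of 6 was tried first and abandoned: on these inputs
the 12-trial validation error plateaus for the first ~10 epochs before
the network begins extracting the temporal code, so patience 6 aborts
most runs at r ≈ 0, while 20 trains to the same optimum as 50 on every
probe split (typically 60–140 epochs).

The session-level procedure draws random 85/5/10 splits — exactly
204/12/24 for 240 trials, remainder-to-train for other sizes — with a
fresh initialisation per iteration, records test-set predictions, and
averages each trial's predictions over the iterations in which it was in
the test set (never train or validation; the tests verify the appearance
counts against independently regenerated splits). The full-length
procedure is 1000 iterations with a minimum of 5 test appearances per
trial enforced (expected 100; the budget is extended if violated, and a
hard failure is raised if coverage still fails). Scaled-down runs (50
iterations in the analysis scripts and acceptance, where the expected
count is 5) scale the minimum accordingly. Reported metrics: per-iteration
Pearson r between predicted and actual CI on the 24 test trials, their
mean across iterations, and the r of the averaged predictions.

## 4. Evaluation

Pearson r with two-sided p from the t transform at n−2 df. Feature
reports carry uncorrected p (α = 0.01) plus a Bonferroni column;
zero-variance features are reported as undefined rather than dropped.
Because "all 24 univariate correlations are null" is a familywise claim,
the null reference is the permutation distribution of the *maximum* |r|
over the family under joint permutation of CI (preserving between-feature
correlation); its 95th percentile is ≈ 0.19–0.20 at n = 240, versus
0.127 for a single feature. A truly null family still exceeds its 95 %
bound in 5 % of sessions by construction — single-seed checks in the
tests use seeds where the property's typical behaviour is visible, and
the acceptance script reports both the observed maxima and the bound so
the comparison is explicit.

## 5. Problem sizes and runtime

The analysis scripts and the acceptance run use full-size sessions
(240 trials, ~50 min of 9-channel EEG) and 50 ANN split iterations — the
time-frequency chain takes ~16 s and the ANN stage ~1 minute on one core,
so the complete acceptance recomputation stays near two minutes. The
1000-iteration procedure is available behind `--iterations 1000`
(~15–20 min). Test fixtures reuse one full nonlinear session and one
univariate session per pytest run.

## 6. Known limitations

* The coupling index is a floored reciprocal; its heavy right tail near
  equal curvatures makes Pearson-based evaluation sensitive to a handful
  of trials. The generator's hand asymmetries keep sessions out of that
  regime; analyses of real data would want a robustness check (ranks or
  log CI).
* The interference phenomenology (extent ordering, congruent > incongruent
  CI) holds for coupling strengths below ~0.5; at w ≥ 0.5 the convex
  morph makes the two hands' shapes converge and incongruent CI rises by
  construction.
* Wavelet edge effects touch the first ~0.3 s of the baseline window at
  in-band frequencies (more below 6 Hz, which no feature uses); epochs are
  not padded.
* The latency code is one concrete instance of a distributed nonlinear
  coupling representation, chosen to be recoverable by the specified
  architecture at the specified sample size; real EEG need not encode
  anything this way.
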