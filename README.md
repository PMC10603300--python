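# coupledraw

Decoding trial-by-trial **bimanual coupling** from motor-strip EEG, three
ways: univariate event-related desynchronisation (ERD), distributed-
univariate cross-channel coherence, and a multivariate shallow neural
network — together with a fully synthetic generator of the circle-line
drawing task, so every stage of the analysis can be validated against a
known ground truth without any human recording.

## The scientific problem

When people draw a line with one hand and a circle with the other, the two
movements interfere: lines bulge, circles flatten. The behavioural
signature of this interlimb coupling is the per-trial **coupling index**

&nbsp;&nbsp;&nbsp;&nbsp;C<sub>t</sub> = |max(x) − min(x)| (horizontal extent of the drawn shape, px)
&nbsp;&nbsp;&nbsp;&nbsp;CI<sub>t</sub> = 1 / max(|C<sub>t,left</sub> − C<sub>t,right</sub>|, 1 px)

— the more similar the two shapes, the larger the CI. The question this
package operationalises: *which representation of the EEG predicts CI
across trials?* Candidates are

* **ERD** — trial-mean log₁₀ band-power change vs. a −2000…−500 ms
  pre-movement baseline, per channel and band (9 motor channels ×
  alpha 8–13 Hz / beta 13–30 Hz = 18 features);
* **coherence** — magnitude-squared coherence |S<sub>xy</sub>|²/(S<sub>xx</sub>S<sub>yy</sub>)
  averaged within frontal-central, central and central-parietal electrode
  triplets (3 groups × 2 bands = 6 features);
* **ANN** — a 3600-100-1 feedforward regressor (tanh hidden layer, linear
  output) over the per-trial band-power *time courses* (9 channels ×
  2 bands × 200 normalised time points), trained by variable-learning-rate
  backpropagation with early stopping over iterated random 85/5/10
  train/validation/test splits (204/12/24 of 240 trials), each trial's
  prediction averaged over its test-set appearances.

The synthetic generator plants a coupling code that only the multivariate
reading can recover: every channel-band shows a desynchronisation dip of
fixed depth whose *timing* within the trial follows the latent coupling
drive (plus per-channel jitter). Trial-mean power — all ERD can see — is
then independent of the drive, while the time-resolved features carry it.

## Worked example

The numbered scripts under `analysis/` run the whole study on one
simulated session:

```bash
python analysis/01_simulate_session.py --seed 1
python analysis/02_behavioural_coupling.py
python analysis/03_spectral_features.py
python analysis/04_coherence_features.py
python analysis/05_ann_decoding.py
python analysis/06_compare_approaches.py
```

At seed 1 the behavioural stage prints the canonical interference pattern
(per-hand horizontal extents in px, mean over 60 trials each):

```
    condition  c_left_mean  c_right_mean  ci_mean
  line-circle       159.17        306.92     0.01
  circle-line       291.20        171.41     0.01
    line-line       107.47        119.52     0.09
circle-circle       400.06        421.03     0.05
mean CI congruent 0.072 vs incongruent 0.0076
```

— curvature is smallest for line-line, intermediate for the incongruent
conditions and largest for circle-circle, and the coupling index is an
order of magnitude higher in congruent trials. The comparison stage then
prints the central contrast:

```
 approach  max_abs_r  n_significant  n_features
      erd      0.101              0          18
coherence      0.150              0           6
      ann      0.643              1           1
familywise 95% null bound for the 24 univariate features: 0.196
mean test-set r across iterations: 0.571
```

Every trial-mean ERD and coherence correlation with CI stays inside the
familywise permutation null (max |r| = 0.15 < 0.196), while the network's
averaged test-set predictions correlate at r = 0.64 (mean per-iteration
r = 0.57 over 50 splits): the distributed temporal code is invisible to
single-value features but recoverable multivariately.

The same pipeline is scriptable through the `coupledraw` command
(`simulate`, `behaviour`, `spectral`, `coherence`, `ann`, `evaluate`,
`run`), and as a library (`coupledraw.synthetic`, `.behaviour`,
`.spectral`, `.coherence`, `.neuralnet`, `.evaluation`, `.pipeline`). EEG
moves between stages as a bit-exact `.npz`+JSON archive or as EDF.

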