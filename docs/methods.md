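# Methods

This note records the models implemented, the defaults chosen where the
underlying study design leaves a constant open, and what the synthetic
generator does and does not establish.

## Signal models

### Modified Beer–Lambert law (fNIRS)

Optical density change per optode and wavelength is
`ΔOD(λ) = −log10(I(λ) / Ī₀(λ))`, with `Ī₀` the mean detector intensity over
a reference window at the start of the recording (default 30 s, before the
first stimulus; configurable). Concentration changes solve the 2×2 system

```
ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · L · DPF(λ)
```

per sample. Defaults: extinction coefficients from a standard in-vitro
hemoglobin compilation, in 1/(mM·cm) — ε(730) = (0.390, 1.1022) and
ε(850) = (1.058, 0.6913) for (HbO, HbR) — differential pathlength factor
6.0 at both wavelengths, source–detector separation 2.5 cm. Concentrations
are expressed in µM. These constants are config-exposed and shared exactly
with the generator's inverse model, which is what makes the noise-free
round trip close to ≤1e-9. The ambient channel, when present, is
subtracted from both wavelength intensities before conversion. Total
hemoglobin (HbT = HbO + HbR) and oxygenation (Oxy = HbO − HbR) are derived
properties, never stored, so the two identities hold exactly at every
stage by construction.

Note two distinct baselines exist: the reference window defining `Ī₀`
(recording start) and the 5-s pre-trial window subtracted from each trial
slice. The analysis chain is conversion → 0.1 Hz low-pass → ICA → per-trial
baseline subtraction.

### Hemodynamic response function

The canonical double-gamma form

```
h(t) = A · [ g(t; α₁, β₁) − c · g(t; α₂, β₂) ]
```

where `g` is the gamma density with shape α and rate β. Defaults A = 1,
α₁ = 6, β₁ = 1, α₂ = 16, β₂ = 1, c = 1/6 (the widely used convention):
response peak at 5.0 s, undershoot past ~10 s, h(0) = 0 for shapes > 1.
The model regressor is the discrete convolution of the trial boxcar with
the sampled HRF, so a one-sample stimulus reproduces the sampled kernel.

### ICA stages

*fNIRS*: FastICA per chromophore across the 4 optode channels; each
component is regressed on the model regressor and the component with the
highest |t| is always retained, plus any with two-sided p < 0.05; all
others are zeroed before reconstruction. With one channel the stage is a
no-op. Whether the source analysis decomposed chromophores jointly or
separately is not documented; per-chromophore was chosen and is flagged
here.

*EEG*: FastICA over the 14 channels; artifact components are those with
excess-kurtosis z-score > 3 across components (spikes/pops) or more than
60% of spectral power below 3 Hz (blink/movement proxy). Thresholds are
config-exposed since the original artifact recipe is not reproduced in the
available text. Order of operations is filter → ICA → per-trial baseline;
it is configurable because the source order is unstated. The unmixing
matrix is estimated on an evenly strided subsample (≤30k samples) and
applied to the full recording — the mixing is time-independent, so this is
unbiased and keeps hour-scale sessions tractable. FastICA non-convergence
triggers seeded retries and finally a logged pass-through; on the
near-Gaussian synthetic background non-convergence is expected and the
last-attempt estimate is used.

### EEG features

Welch PSD with 2-s Hann windows and 50% overlap (neither estimator nor
windowing is fixed by the design; these are standard choices). Band power
is the mean PSD over bins with lower < f ≤ upper (half-open, matching the
band notation); features are natural logarithms. Asymmetry is
right-minus-left log power for the four homologous frontal pairs — the
sign convention is fixed and documented, and the listed four pairs are
used (they produce the 4 × 4 = 16 asymmetry count; "all possible pairs"
would give more and is not what the feature arithmetic implies).

### Facial affect

The 7-class per-frame probability stream is calibrated by subtracting the
mean profile of the 5 s before stimulus onset, clipping at 0 and
renormalizing each frame onto the simplex (how negative calibrated values
should be handled is unspecified; clipping keeps the clip-level sums
meaningful). Frames fully cancelled by calibration become uniform.
Aggregation sums calibrated frame probabilities per emotion; ties in the
argmax break by the documented emotion order (Anger, Disgust, Fear,
Happiness, Neutral, Sadness, Surprise). The affect ratio uses happiness
mass against the *maximum* single negative-emotion mass; equal ratios
break positive. Calibrated (not raw) probabilities feed the aggregation —
the alternative is not distinguishable from the available description.

### Classification

Leave-one-trial-out: for each of the 20 trial indices within a content
type, train on the other 19 indices pooled over all participants and test
on every participant's held-out trial (n_participants observations per
fold; 240 at 12 participants). Features are z-scored with training-fold
statistics only; the SVM is polynomial (degree 3, C = 1, scaled gamma,
coef0 = 1 — only the kernel family is fixed by the design). ROC uses the
signed decision-function distance; AUC by the rank (Mann–Whitney)
formulation with ties counted ½; SE by Hanley–McNeil; 95% CI as
auc ± 1.96·SE clipped to [0,1]. "Twenty-times iterations" is read as the
20 leave-one-trial-out folds. Image and video trials are evaluated as
separate 20-fold experiments.

### Similarity

Phi is computed from the 2×2 contingency table; its p-value uses the
χ² statistic n·φ² with 1 d.f. without continuity correction (the test
behind the published p-values is unstated); Fisher's exact test is
available for small n. Continuous facial affect (signed rating
P_pos − P_neg) correlates with ground truth by Pearson; binary labels with
band log-powers by point-biserial correlation, reported with
Benjamini–Hochberg q-values across the 56 channel-band features.

## The synthetic world

The generator is the test harness: no recordings from this design were
deposited, so every default is a stated modeling choice, made once.

* **Protocol** — 12 participants; 20 image trials (5 s) and 20 video
  trials (duration uniform on [10, 17] s, the only stated range), each
  balanced 10 positive / 10 negative; 30 s initial rest; 10 s inter-trial
  gap (covers the 5-s baseline plus the question/self-report period).
  Stimulus valences and video durations are stimulus properties shared
  across participants. Likert self-reports are 8–10 for positive and 1–3
  for negative trials with 10% label noise (self-report is imperfect; the
  exact level is free). Face frame rate 30 fps (typical webcam; unstated).
* **fNIRS** — target HbO is boxcar ⊛ HRF, peak-normalized, with amplitude
  `effect_fnirs` (default 0.3 µM, a typical cortical response magnitude)
  on the hemisphere matching trial valence (left for positive) and 40% of
  it contralaterally; HbR = −HbO/3. Intensities are the exact MBLL
  inverse, plus Gaussian detector noise (sd 0.5% of baseline intensity)
  and a slow sinusoidal drift (1%, 1–3 min periods). Drift is a separate
  parameter so the noise-free round-trip oracle turns off both explicitly.
* **EEG** — per channel: 4–45 Hz band-limited background (RMS 3 µV) plus a
  narrowband 8–12 Hz component (resting amplitude 4 µV) whose envelope on
  the four frontal pairs scales by exp(±δ/4) during trials, signed by
  valence, so the planted right-minus-left alpha log-power difference is
  ±`effect_eeg` (default 0.3). Background is high-passed at 4 Hz so the
  <3 Hz artifact detector has a low false-positive rate on clean data.
* **Face** — frames are Dirichlet draws (concentration `noise_face` = 8)
  around a neutral-heavy resting profile; during trials `effect_face`
  (default 0.25) of probability mass moves to Happiness (positive) or one
  sampled negative emotion. With probability `misexpression_rate`
  (default 0.2) a trial's expressed emotion is drawn irrespective of
  valence — spontaneous displays are unreliable, and without this the
  clip-level recognition rate is degenerately 1.0.
* **Expressiveness** — every (participant, trial, modality) carries a
  unit-mean gamma gain (shape 2) multiplying the planted effect,
  emulating variable responsiveness across stimuli; shape 0 disables it.

What a green test establishes: the pipeline recovers exactly the
structure the generator plants — linear-in-log-power asymmetries,
HRF-shaped lateralized hemodynamics, simplex-biased emotion streams with
stationary Dirichlet noise. Real recordings differ in ways the generator
deliberately omits: 1/f spectra and non-stationarity, correlated
cross-modal artifacts (motion hits fNIRS and EEG together), systemic
physiology (cardiac, Mayer waves), head-movement video artifacts, and
participant-level (rather than trial-level) effect heterogeneity.
Published headline accuracies from the original recordings are therefore
not reproduction targets; the synthetic defaults are calibrated only to
make the pipeline's contrasts detectable.

## Numerical choices

* Zero-phase filtering: 4th-order Butterworth, forward–backward
  (`sosfiltfilt`); only cutoffs are fixed by the design.
* Sample (n−1) standard deviation throughout (both conventions round the
  published recognition-rate sd to the same 0.10).
* Tie-breaks: emotion argmax by documented order; affect ratio ties to
  positive; ROC ties ½.
* Degenerate inputs: non-positive intensities, empty streams and
  single-class folds raise or are skipped with logged warnings; zero
  calibrated frames become uniform; constant features are flagged
  undefined rather than propagating NaNs.
* Determinism: all randomness flows from integer seeds via spawned
  `SeedSequence` streams keyed by (seed, stage, participant); identical
  configs give byte-identical CSV trees.

## Known limitations

* EDF input is not supported (no EDF library in the dependency set); EEG
  interchange is CSV.
* The facial landmark tracker and region-based expression classifier that
  would produce the probability streams from video are upstream of this
  package; streams are consumed as given.
* The ICA component-selection t-test treats samples as independent;
  autocorrelation in real hemodynamics makes its p-values optimistic.
  Selection uses the max-|t| rule, so this affects only the "additional
  significant components" criterion.
* Leave-one-trial-out pools participants, so the model is population-level;
  no per-participant calibration or transfer is attempted.
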