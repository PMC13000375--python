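# Methods

This note documents the models, estimators and design choices in
`vocalrisk`, in the package's own words: what is computed, under what
assumptions, with which defaults, and where the known limits are.

## Audio standardization (`audio_io`)

Recordings are decoded from RIFF/WAVE PCM (8/16/24/32-bit integer or
32-bit float) to floats in [-1, 1], mixed to mono by channel averaging,
resampled to 16 kHz by polyphase filtering, high-pass filtered, clipped
to a centered segment, and amplitude-normalized.

- **High-pass, 70 Hz, 4th-order Butterworth.** A band-pass to 8 kHz
  would be degenerate at a 16 kHz rate (8 kHz *is* Nyquist), and the
  anti-hiss role of an upper edge is already served by the resampler's
  anti-alias filter, so only the low edge is implemented. The filter is
  applied forward-backward (`sosfiltfilt`), trading an effectively
  doubled magnitude response for exactly zero phase — cycle landmarks
  used by the perturbation measures must not be shifted.
- **Normalization** targets peak -1 dBFS by default (RMS -20 dBFS
  available). Order of operations is mono → resample → filter → clip →
  normalize; normalizing last means the clip's level is exact.
- **Framing** is 25 ms Hamming / 10 ms hop (400/160 samples); frame k
  covers [k·160, k·160+400). All indexing is 0-based half-open.

Zero-phase filtering overshoots at hard signal edges; on clips with
abrupt onsets the normalization peak can sit in the edge transient.
Clips with natural fades (all synthetic and clinical material) are
unaffected.

## Acoustic features (`features`)

**Pitch** is tracked per frame by normalized autocorrelation, divided by
the Hamming window's own autocorrelation to undo the taper bias
(Boersma's correction), searched over 60–500 Hz. Because the corrected
function is ≈1 at *every* multiple of the true period, the winning lag
is chosen among local maxima with a 0.03-per-octave cost favoring
shorter lags, followed by a second pass that re-searches every frame
within ±25% of the voiced median lag — octave errors on sustained
vowels are eliminated at the cost of limiting trackable within-clip
range to ±25% of the median (ample for sustained phonation; a
180→220 Hz glide stays inside it). Frames are voiced when the corrected
peak is ≥ 0.45. Lag and value are refined by 3-point parabolic
interpolation.

**Cycle marking** walks forward and backward from the strongest
waveform peak in the longest voiced run, measuring each successive
period as the lag (within ±30% of the locally predicted period) that
maximizes the cross-correlation between one cycle-length Hann-tapered
window and the signal one period away. The correlation runs on a
glottal-flow proxy — the LPC (order 18) residual passed through a leaky
integrator (pole 0.95) — not on the raw waveform: formant ringing
carries over between cycles, and any waveform-domain matcher therefore
drags its lag toward the *average* period, systematically shrinking
measured jitter by roughly half. The flow proxy is cycle-localized and
free of that bias. Marks get sub-sample precision from parabolic
interpolation of the correlation peak; per-cycle amplitudes are
parabolic-refined waveform peak magnitudes between marks.

**Perturbation measures** use the standard local definitions —
jitter = mean |T_i − T_{i−1}| / mean T, RAP with the 3-point smoother,
shimmer = mean |A_i − A_{i−1}| / mean A (plus a dB variant). At least
10 cycles are required.

**HNR** per voiced frame is 10·log10(r/(1−r)), clamped to [−10, 40] dB,
where r is the taper-corrected autocorrelation peak near the expected
lag. Two accuracy-critical details: the peak value is parabolic-
interpolated (the value at the nearest integer lag caps measurable HNR
near 19 dB), and HNR uses its own 50 ms analysis windows — at 100 Hz a
25 ms window holds 2.5 periods and cannot resolve high harmonicity.

**CPP** is the height of the cepstral peak (quefrency window 2–16.7 ms)
above a least-squares line fitted to the real cepstrum of the dB
spectrum over that window, per frame (FFT 1024).

**HRF** reads harmonic magnitudes A_k at k·F0 (k·F0 < 4 kHz) from a
4096-point spectrum with quadratic bin interpolation, subtracts a local
noise-floor estimate (median magnitude in an annulus of bins beside
each harmonic) so leakage never masquerades as harmonic energy, and
reports 20·log10(ΣA_{k≥2}/A_1), floored at −30 dB. **QOQ** is the
fraction of each cycle the inverse-filtered, leaky-integrated flow
proxy spends above 50% of its within-cycle range (LPC order 18,
pre-emphasis 0.97).

**Aggregation.** Clip vectors are arithmetic means over frames/cycles;
patient vectors are arithmetic means over the patient's clips. Clips
whose cycle marking fails are dropped; a patient with zero valid clips
is excluded with a warning. The default panel has 20 registered
features (the registry is extensible); the seven-feature
`ELBOW_PANEL` subset is also exported.

### Estimator accuracy and floors

Round-trip measurements against the generator (20 seeds per setting)
recover planted jitter within ±0.3 pp over 0.5–4%, shimmer within ±1 pp
over 2–10%, HNR within ±0.6 dB over 5–25 dB, and F0 within 0.3%. Known
limits, visible in the tests and deliberately not hidden:

- jitter has an additive noise floor that grows as HNR falls (~0.6 pp
  at 30 dB, ~1.7 pp at 15 dB) — noisy voices read as slightly more
  jittery, which compresses but never reverses group contrasts;
- shimmer resolution is bounded near 0.2–0.4% by sampling-phase
  quantization of cycle peaks when the period is not an integer number
  of samples;
- measured HNR saturates near 31–33 dB (window correction residuals),
  well above the clinically relevant range.

## The risk model (`nam`)

Each panel feature has a subnetwork taking (feature, age, sex); the
model output is σ(β + Σ_k g_k). Subnetworks are MLPs with two tanh
hidden layers (default 32×32), one scalar output, no output
nonlinearity; β is a global learnable offset. The implementation is
pure numpy with hand-written backpropagation and Adam, full batch,
float32; a leading "model axis" trains many models in one set of
BLAS-batched matrix multiplications, which is what makes the nested
selection procedure fast on a single CPU. Training is deterministic
given seed, data and configuration.

Defaults: binary cross-entropy loss; weight decay 1e-4 on weight
matrices (stability on n≈150 cohorts); inputs standardized (features
and age z-scored with training-set statistics; sex encoded
female = 0, male = 1); minority class oversampled with replacement to
exact balance, training portions only; learning rate and epoch count
chosen by AUC on a stratified 20% inner split over the grid
{3e-3, 1e-2} × {100, 300} (epoch candidates are evaluated as
checkpoints of a single run). The fitted artifact (.npz) carries
weights, panel, standardization constants, encodings, configuration and
seed, and scores without any training-time context.

Feature importance is the mean absolute subnetwork output over a
dataset — the additive-model reading of "contribution"; a mean
absolute parameter diagnostic is provided separately.

## Development pipeline (`pipeline`)

Five stratified patient-level folds (deterministic in the master seed;
all of a patient's clips share its fold by construction, since features
are aggregated per patient before folding). Within each training fold,
in order:

1. **Recursive feature addition.** Greedy forward selection; each step
   trains one screening NAM per (candidate, inner fold) — 3 stratified
   inner folds, hidden 16×16, 120 epochs, lr 3e-3 — all stacked on the
   model axis of a single fit. The step metric is mean inner-fold
   validation AUC; candidates within 0.01 AUC of the step best are
   treated as tied and resolve to the earliest panel position, so
   near-duplicate features (two shimmer variants, several F0
   statistics) cannot make folds disagree by noise. Addition stops
   after 2 consecutive gains < 0.005 AUC (those trailing additions are
   rolled back), at 8 features, or when the panel is exhausted. The
   inner-validation mean risk-score difference after each addition is
   recorded alongside for plotting.
2. **Final fold model** trained on the whole training fold with the
   grid-searched configuration on the selected subset.
3. **Recalibration.** Logistic intercept/slope fitted on *cross-fitted*
   training-fold predictions (4-fold inner cross-fitting with the
   winning hyperparameters, one batched fit). In-sample predictions of
   an overfit network are separable and push the slope to the bound,
   which is why the map is estimated out-of-sample within the training
   fold; slopes well below 1 are the expected overconfidence
   shrinkage. Perfect separation falls back to a slope clamped at ±20
   with a refitted intercept, logged.
4. Held-out patients (including moderate-risk patients, who are never
   trained on) are scored by the fold model and its calibration map.

The reported feature subset is the intersection of the five fold
selections. An empty intersection raises with full per-fold diagnostics
by default; `on_empty_intersection="warn"` records the empty set and
continues, which null-control runs (label permutations, where no stable
subset should exist) require. The development Youden threshold is the
out-of-fold score maximizing sensitivity + specificity − 1 (ties to the
lower threshold). External cohorts are scored by the ensemble mean of
the five calibrated fold models (a refit-on-all variant is a one-line
change) and classified at the development threshold.

Every stage writes the patient ids it consumed into an audit log;
`audit_leakage` verifies no validation patient influenced
standardization, oversampling, selection, grid search or calibration in
any fold, and that every patient has exactly one out-of-fold score.

## Synthetic cohorts (`synth`)

One phonation = Rosenberg-type glottal flow pulses (open quotient 0.6)
differentiated and shaped by a cascade of resonators at adult [i]
formant targets (270/2290/3010 Hz), plus white noise at the gain
realizing the target harmonics-to-noise power ratio, peak-safe at
16 kHz.

Planted perturbations are defined on the scale of the measured local
metrics: per-cycle Gaussian perturbations are scaled by √π/2 so the
*expected* local jitter (and shimmer) equals the dial value. Jitter
perturbs cycle onsets while the pulse shape follows the smooth F0
contour (a shape that stretched with each perturbed period would hide
~45% of the timing perturbation from any waveform-matching measure);
shimmer is applied as per-cycle amplitude modulation of the radiated
waveform with ~1 ms smoothed transitions (source-side gains are diluted
by formant ringing carry-over). A slow AR(1) F0 drift (SD 0.5%) makes
F0_std and Max Pitch non-degenerate, and an optional linear F0 glide
supports contour tests.

Cohort structure (defaults, all configurable): high-risk group jitter
mean higher by 0.0085, shimmer by 0.0266, HNR lower by 3.1 dB than
low-risk (within-group SDs 0.006 / 0.02 / 3 dB — moderate standardized
effects); high-risk older (Normal(72.3, 9.9) vs Normal(62.9, 12.6)
years) and more often male (83% vs 45.5%); moderate group at the
parameter midpoint; 1–3 clips per patient weighted (0.1, 0.2, 0.7)
toward three, 1.0 s each. Demographics couple weakly to the voice
(male F0 ≈ 125 Hz vs female ≈ 205 Hz; +5e-5 jitter per year over 60) so
the confound-adjustment machinery has something real to absorb. The
external-site design is smaller (19 high / 16 low), older, with more
female high-risk and fewer male low-risk patients. `null_effects()`
removes *all* group contrasts — acoustic and demographic — because age
and sex are model covariates and a demographics-only contrast would
still discriminate.

What the generator does **not** emulate: room/equipment channel
effects, non-stationary voice quality (diplophonia, voice breaks,
tremor), inter-session variability, label noise in PAS-derived risk
classes, or any correlation structure between acoustic deficits and
comorbidities. Passing tests therefore demonstrate that the pipeline
recovers known structure correctly and leaks nothing — not that
clinic-grade discrimination would match: synthetic cohorts separate
more cleanly (out-of-fold AUC ≈ 0.9 at the default effects) than real
recordings plausibly would.

## Evaluation statistics (`evaluation`)

AUC by the Mann–Whitney identity with half-credit ties; 95% CI and
paired comparisons by DeLong's structural components (an O(n²)
exhaustive pair-counting oracle is kept for testing). Proportions carry
Wilson score intervals (Clopper–Pearson behind a flag). Decision curves
use net benefit (TP − FP·pt/(1−pt))/n on a 0–0.75 grid (step 0.01).
Calibration reports logistic intercept/slope on the logit, Brier score,
and a 10-equal-count-bin reliability curve bias-corrected by
2·apparent − mean(bootstrap), 1000 seeded resamples by default. Group
comparisons are Welch t-tests with BH q-values (q never below p,
monotone in rank). Fisher exact tests: hypergeometric for 2×2, full
enumeration over fixed margins for r×c up to 10⁶ tables, seeded Monte
Carlo (10⁵ permutations) beyond; Kruskal–Wallis with tie correction.
Interrater agreement is pairwise Cohen kappa (undefined, flagged, when
chance agreement is 1); human-vs-model contrasts use the exact binomial
McNemar test on discordant pairs (the center term is not double-counted
when b = c) and the paired DeLong z-test.

## Problem sizes and determinism

The test suite exercises the full chain at the default cohort design
(146–163 patients, ~380 clips, 20-feature panel); the 20-seed
discriminability suite, the three-seed null and site-shift controls,
and the 20-seed parameter-recovery grids complete in about 10 minutes
on one CPU. All stochastic stages — cohort draws, folds, oversampling,
inner splits, weight initialization, bootstraps, Monte Carlo tests —
draw from explicitly passed seeds; repeated runs are bit-identical.

## Known limitations

- The pipeline's statistical behavior is validated on synthetic
  phonations only; clinical deployment would require the original or
  comparable recordings.
- The feature estimators trade bit-compatibility with established
  voice-analysis toolboxes for testability: they implement the standard
  definitions but are not drop-in replacements for PRAAT/COVAREP
  outputs.
- The cross-fold intersection can legitimately be empty when no feature
  is selected in all five folds (always under the null, occasionally
  under signal when collinear features split votes); this is surfaced,
  not papered over.
- QOQ rests on LP inverse filtering, a rough glottal-flow proxy; its
  absolute level is interpretable only relative to the same pipeline.
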