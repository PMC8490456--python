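# Methods

`alphanft` analyses multi-session alpha-upregulation neurofeedback (NFT)
experiments: 46 participants, one 2-min eyes-closed resting (ECRS) recording,
then 12 sessions of a 2-min baseline plus six 6-min training trials, three
bipolar channels (C3a-C3p, Cza-Czp, C4a-C4p) sampled at 500 Hz.  This note
records the models, conventions and design choices the package commits to,
and what the synthetic-data tests do and do not establish.

## Spectral conventions

Recordings are cut into non-overlapping 1-s epochs (trailing partial windows
dropped).  Each epoch is Hamming-windowed and Fourier transformed; the
one-sided magnitude spectrum is scaled by `2/sum(w)` (coherent-gain
correction), so a pure sinusoid of peak amplitude A at an integer frequency
reads ~A µV in its bin.  Per-channel spectra are averaged across the three
bipolar channels, and band amplitudes are arithmetic means of the 1-Hz bins
over inclusive integer ranges: delta 1–3, theta 4–8, alpha 8–12, beta
13–30 Hz.  The printed band edges are taken literally, so the 8-Hz bin
belongs to both theta and alpha.  Note that under the Hamming window a pure
tone leaks over ~3 bins, so the 5-bin alpha *band* amplitude of a clean
20-µV sinusoid is well below 20 µV; the synthetic generator calibrates its
components through this exact pipeline so that requested band amplitudes are
what the analysis recovers.

### Artifact rejection

An epoch is rejected when its broadband (1–30 Hz) mean spectral amplitude
deviates from the across-epoch mean by more than 2.5 across-epoch SDs
(`statistic="epoch_amplitude"`, the default).  The mean and SD are
re-estimated iteratively (≤5 passes, cumulative mask), because large bursts
otherwise inflate the SD and shadow smaller ones; on synthetic motion bursts
at 10× the background SD this raises per-epoch sensitivity from 0.74 to
≈0.98 at a ~1–2% false-positive rate on clean Gaussian-like epochs.

An alternative statistic (`"peak"`: per-epoch peak absolute sample against
the whole-segment sample SD) is available, but carries an extreme-value
caveat: the per-epoch maximum of ~1500 Gaussian-like samples already sits
near 3 SD, so at a 2.5 threshold it rejects essentially *every* clean epoch.
It is appropriate for clipping/spike screens at much larger factors.
Rejected epochs are excluded from all downstream means; a caller-supplied
manual mask (e.g. visually marked blinks) merges by logical OR; a fully
rejected trial is dropped from its session with a log entry.

## MRAA and learning indices

Relative alpha amplitude of a trial = (trial mean alpha amplitude) /
(that session's 2-min baseline alpha amplitude); the session's MRAA is the
mean over its valid trials.  Three between-session indices summarise the
12-session MRAA trajectory:

* `L1 = MRAA(12) − MRAA(1)`;
* `L2 = Σ_{i=2..12} [MRAA(i) − MRAA(1)] / 11` — the divisor is fixed by
  definition, so a missing session invalidates L2 (no imputation);
* `L3` = least-squares slope of `MRAA(i)` on `ln i` (natural log; the base
  only rescales the slope), fitted over whatever sessions are available
  (≥3 required).

A subject is a responder for an index iff the index is strictly positive;
an exactly-zero index (measure-zero in practice) counts as nonresponder.

## Group statistics

Trainability: classical one-way within-subject ANOVA of MRAA over the 12
sessions (df 11, 495 for n=46), no sphericity correction by default (a
Greenhouse–Geisser flag exists); Bonferroni-corrected paired t-tests of each
session against session 1 (factor k−1 = 11).

Independence: per-bin paired t-tests of last- vs first-session spectra,
Bonferroni over bins, plus a two-way fully-within-subject session×frequency
ANOVA.  Error terms are per-effect (each effect against its subject×effect
interaction) by default; a `pooled_error` option tests every effect against
the highest-order residual stratum, whose df is (n−1)(b−1) = 45·27 = 1215
for 46 subjects and 28 displayed bins.  The exact error-term construction
behind that alternative convention cannot be pinned down unambiguously, so
the package exposes both and reports which was used; it does not attempt to
reproduce any specific F value under the pooled convention.  Training counts
as "independent" when every significant bin lies inside the trained 8–12 Hz
band.

## Responder prediction

The 4×3 ECRS-band × learning-index Pearson correlations form a single
Benjamini–Hochberg FDR family of 12 (α=0.05 two-tailed); zero-variance
variables are flagged and excluded from the family.  Simple OLS regression
of an index on ECRS alpha reports R², which equals the squared Pearson r by
identity (asserted in tests to 1e−12).

Feature selection is forward-stepwise under the Wilks'-lambda partial-F
criterion for two groups: at each step the candidate with the smallest
partial-F p-value enters if p < 0.05; after each entry any retained feature
with removal p > 0.10 is dropped (worst first); iteration continues to a
fixed point, with ties broken by the canonical band order
(delta, theta, alpha, beta).  An empty selection is a reported status, not
an error.

The retained features enter a Fisher discriminant with pooled within-class
covariance, `D = a0 + Σ ai·Xi`, oriented so responders score D < 0.  Under
`priors="equal"` (default) the D = 0 boundary sits at the class midpoint;
under `"proportional"` it shifts by ln(π_N/π_R).  The choice matters under
the ~4:1 responder imbalance typical of this design: the midpoint boundary
is conservative (it sacrifices accuracy to treat both classes symmetrically,
and can fall below the no-information rate when separation is weak), while
proportional priors track the base rate.  Both are exposed and logged; the
permutation-null calibration tests use proportional priors because the
no-information (majority-class) benchmark is only attainable by a
prior-informed classifier — with equal priors the null accuracy is ~50% by
construction.

Leave-one-out cross-validation refits the LDA coefficients on each n−1
subset and classifies the held-out subject by the sign of D.  Under the
default `fixed_features` policy the stepwise selection is performed once on
the full data (as the study design prescribes); `nested_stepwise` reselects
within every fold for an honest validation of the entire procedure.  A fold
that loses one class entirely falls back to the training majority and is
flagged.  Metrics: sensitivity = 100·TP/(TP+FN), specificity =
100·TN/(TN+FP), accuracy = 100·(TP+TN)/n; an undefined denominator yields a
missing value, never zero; reports round to one decimal.

## Synthetic cohorts

The generator emulates the study design with known ground truth.  Per
subject, band levels are lognormal across subjects (defaults, arithmetic
mean ± SD in µV: delta 6±1.8, theta 5±1.5, alpha 10±4, beta 2.5±0.8 —
resting alpha amplitude genuinely spans a wide range between subjects).
The learning gain is

    g = gain_mean + gain_sd · (ρ·z + √(1−ρ²)·ε),

where z is the subject's true ECRS alpha amplitude standardised by the
generating distribution's mean and SD and ε is standard normal, so the
population corr(ECRS alpha, g) equals ρ (default 0.7).  Defaults
gain_mean=0.35, gain_sd=0.43 give a group MRAA endpoint of 1.35, an L1
spread of ±0.43 and a responder fraction Φ(0.35/0.43)≈0.79, in the range
the design targets (group MRAA 1.0–1.35 over 12 sessions, 76–87%
responders).  Trajectories are normalised so MRAA(1)=1 and MRAA(12)=1+g
exactly, with linear or sigmoid shape (default sigmoid, midpoint session 6,
width 1.5 — learning typically emerges mid-training).

Fast path: per-trial band amplitudes are sampled directly from the
generative means with lognormal noise — session-level day noise CV 10%
(shared between a session's baseline and its trials, so it cancels in the
MRAA ratio), trial noise CV 5%, ECRS measurement noise CV 5% — plus 1–30 Hz
mean bin spectra for sessions 1 and 12 (bin noise CV 8%) for the
independence comparison.  Within-trial alpha variability has no published
reference value; these CVs were chosen once to keep estimated MRAA
trajectories in the observed 1.0–1.35 range with session-to-session jitter
comparable to published group curves.

Slow path: full time series.  The alpha component is a sinusoid at the
subject's peak frequency (normal 10±0.8 Hz, clipped to 8–12) under a slowly
varying positive envelope (AR(1)/Ornstein–Uhlenbeck, τ=2 s, CV 0.25),
shared across channels; delta/theta/beta are independent band-passed
Gaussian noise per channel; a small 1/f floor is added.  Each component is
rescaled so the spectral stage recovers the requested band amplitude on
that realisation, making the generator's levels recoverable by construction
rather than nominal.  Artifacts are Poisson-timed bursts (default 0.5/min;
duration U(0.2, 1.0) s) of low-pass noise plus a monophasic offset under a
Tukey(0.5) envelope, peak amplitude `artifact_amplitude_factor` (default 8)
times the background SD, identical on all channels (motion is largely
common-mode on a bipolar montage).  The ground-truth mask marks epochs
containing ≥0.15 s (or the whole plateau, if shorter) of the envelope's
full-amplitude plateau: epochs touched only by the low-amplitude tapers
carry negligible artifact energy, are indistinguishable from clean epochs
by any amplitude statistic, and do not corrupt band amplitudes, so they are
not counted as contaminated.

Randomness is hierarchical (`SeedSequence([seed, subject, stream, …])`), so
identical (config, seed) pairs reproduce bit-identical cohorts and growing
the cohort never reshuffles existing subjects.

### What the synthetic cohorts do not show

The generator captures the study's sampling structure, the alpha-gain
coupling, band-limited background activity and transient artifacts.  It does
not model eye-blink or EMG morphology, volume conduction, non-stationary
drowsiness drift, or inter-channel correlation structure beyond the shared
alpha source.  Passing the closed-loop tests therefore demonstrates that the
analysis recovers the generative parameters under these idealised
conditions, not that it is robust to every contaminant of real EEG.

## Known limitations and measured gaps

* **Stepwise exclusivity under default conditions.**  Over 200 default
  cohorts (n=46, ρ=0.7), alpha is the top-correlated band in 100% of
  replicates, but the stepwise selection returns *exactly* {alpha} in only
  ≈66–69%.  Two effects cap this rate.  First, even when alpha always
  enters, each of the three null bands still enters with probability ≈ the
  0.05 entry level, bounding the exclusive rate by (1−0.05)³ ≈ 0.857.
  Second, with lognormal band levels (alpha CV 0.4) the two-group partial-F
  power for alpha against binarised responder labels at a ~4:1 imbalance is
  ≈0.81 (the skewed right tail inflates the pooled within-class variance;
  normally distributed traits of the same CV give ≈0.95).  A single real
  cohort finding alpha exclusively selected is entirely consistent with
  these rates; a ≥90% exclusivity rate across replicates is not attainable
  under this entry rule and trait distribution, and the corresponding
  acceptance test is left failing rather than tuned.
* The equal-priors LOOCV accuracy on default synthetic cohorts (~50%) is
  far below the proportional-priors accuracy (~80–83%); see the priors
  discussion above.  Which convention the original analysis used is
  unknowable from the printed tables alone.
* The two-way pooled-error F convention is implemented for its degrees of
  freedom; no claim is made to reproduce specific published F values under
  it.
* EDF export uses a minimal self-contained writer (1-s records, int16,
  physical unit µV); reading goes through `mne.io.read_raw_edf`, which also
  cross-checks the writer in tests.  16-bit quantisation bounds round-trip
  error at ~3·10⁻⁵ of full scale.

## Problem sizes used by the test and acceptance suites

Closed-loop signal tests use 30–120 s recordings and 2-subject slow-path
cohorts; distributional checks use 2 000–10 000 ground-truth draws;
replicate-based properties use 200 fast-path cohorts of the full 46×12×6
design; the ANOVA type-I calibration uses 1 000 simulated null matrices and
the permutation-null LOOCV 200 permutations.  These sizes keep every Monte
Carlo tolerance at least ~3 binomial SDs wide while the full suite runs in
about a minute.
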