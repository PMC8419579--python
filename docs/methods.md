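# Methods

This note documents the models, algorithms and numerical choices behind
`pupcall`, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate.

## Signal model and synthesis

Pup calls are modelled as additive harmonic tones: a fundamental contour
F₀(t) (constant by default) with `n_harmonics` partials whose amplitudes
fall off as 1/k², under a raised-cosine onset/offset envelope of ≥ 20 ms.
The 1/k² roll-off makes the fundamental the spectral peak, so the nominal
"peak frequency" of a synthesized template call equals its F₀; real pup
calls can place the peak on a harmonic, which the feature extractor handles
but the generator does not emulate. Default sampling rate 96 kHz (the
recording standard for this kind of field work); the synthesizer rejects
contours whose highest harmonic reaches Nyquist.

## Pitch shifting

The duration-preserving shift is a phase vocoder: the signal is
time-stretched by the shift ratio (Hann analysis/synthesis windows of 2048
samples, 75% overlap, per-bin instantaneous-frequency phase propagation)
and then resampled back to the exact original sample count, scaling the
fundamental, all harmonics and the spectral peak by the ratio while leaving
the length unchanged to the sample. Frequency-scaling accuracy is limited
by the synthesis hop (≈ 0.8% worst case, well under one spectral bin for
the 119 → 153 Hz shift); overlap-add edges where the window sum is < 0.01
are zeroed rather than amplified. Shifts that would push the 99%
spectral-energy rolloff past Nyquist are rejected.

## Segmentation and features

* **High-pass**: order-4 Butterworth at 100 Hz, applied forward–backward
  (zero phase): ≈ 48 dB attenuation one octave below cutoff, < 0.1 dB above
  2× cutoff, no onset shift. The 119 Hz fundamental loses ≈ 2 dB, which is
  irrelevant to peak/F₀ measurement on clean signals.
* **Segmentation**: 1 ms RMS frames; frames above −30 dB relative to the
  file's 95th-percentile frame RMS are active; active runs separated by
  ≤ 5 ms merge into one call, larger gaps split calls, and runs shorter
  than 50 ms are discarded. The −30 dB/50 ms defaults are design choices
  (only the 5 ms gap rule is externally fixed) and are configurable.
* **Features every 5 ms**: analysis windows of ~80 ms (nearest power of
  two; 8192 samples at 96 kHz) centred on each 5 ms step, with reflection
  padding at call edges so the contour length equals ⌊duration / 5 ms⌋.
  F₀ by autocorrelation (search band 60–800 Hz) with parabolic
  interpolation and 5-point median smoothing; frames whose normalized
  autocorrelation peak is < 0.5 are unvoiced and excluded from F₀
  statistics. Peak frequency is the parabolic-interpolated argmax of the
  Hamming power spectrum above 60 Hz. The ~80 ms feature window is
  deliberately longer than the 2048-sample display-spectrogram window: at
  96 kHz a 21 ms Hamming window has a ≈ 187 Hz mainlobe and cannot separate
  a 119 Hz fundamental from its second harmonic; the feature path and the
  display spectrogram are therefore decoupled.
* **Formants** (optional): Yule–Walker LPC via Levinson/Toeplitz solve,
  complex roots with bandwidth < 400 Hz, sorted ascending.

## Match rule

A window of k consecutive calls (k = template length ∈ {2, 3}) is a match
when every successive onset-to-onset gap is ≤ 1 s and every successive
mean-F₀ difference is ≥ 100 Hz in magnitude with the template's direction
sign. "Within 1 s" is read as onset-to-onset because stimulus calls are
0.75 s apart onset-to-onset while distinct sequences are > 1 s apart.
Overlapping candidate windows are resolved greedily left-to-right (earliest
window wins, no call reuse) — deterministic given sorted input, and
identical to all-windows enumeration whenever matched windows do not
overlap (property-tested). All k calls of a matched window are flagged,
because the regression's unit is the individual call. Control pups are
scored against all three templates, trying the three-call template first at
each position so a full up–down triple is credited as one *ab* match rather
than a pair plus an orphan.

Note the template's *peak-frequency* step (153 − 119 = 34 Hz) is smaller
than the 100 Hz *fundamental-frequency* criterion; the two scales are
simply used where stated (peaks for stimulus construction, F₀ for
matching), and the synthetic colony plants matches satisfying the F₀ rule.

## Gower / Mantel similarity

Feature vectors per matched call: duration, mean/min/max F₀, mean peak
frequency, inter-call interval (onset-to-onset gap to the previous call of
the window; missing for window-initial calls) and sequence position. The
exact parameter list used originally is unpublished, so the set is
configurable. Gower dissimilarity averages range-normalized absolute
differences over pairwise-available variables; ordinal variables are
ranked first; zero-range variables are dropped with a warning.

The Mantel construction needs both matrices on one object set: the
response-side matrix is Gower over the matched calls of a pup × age-bin
cell (≥ 3 calls, else the cell is skipped), and the template-side matrix is
Gower over the template calls each response is position-aligned to — for
playback pups their assigned stimulus, for control pups the template each
chance-matched window happened to realize (control cells at weaning have
few matches and correspondingly noisy r) — with
normalization spans pooled over responses and template calls so the two
matrices share one scale. This is a documented design choice, not a claim
about the original software. Mantel r is the Pearson correlation of
upper-triangle entries; p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm) with
rows/columns of the second matrix permuted jointly, one-sided (greater),
default 9 999 permutations, seeded.

## Mixed models

* **Match model**: logistic regression of the call-level match indicator on
  age, condition (reference = control) and their interaction, with a pup
  random intercept. Fit by maximum likelihood with the random effect
  integrated by 25-node Gauss–Hermite quadrature; BFGS optimization;
  Wald CIs from the numerically differentiated Hessian. The fit aborts with
  a diagnostic when a coefficient diverges (apparent complete separation)
  or the design is inestimable (single pup, one outcome class). Agreement
  with lme4's Laplace fits was verified during development (coefficients
  and random-intercept SD to ~3 decimals on a 3 600-call table).
* **Similarity model**: Gaussian mixed model of Mantel r on age bin
  (ordinal 0–3), condition, sex and age × condition, pup random intercept,
  REML (statsmodels MixedLM; gradient-free fallbacks for boundary
  variances). Estimates of both models are reported exponentiated for
  parity with the study's tables; on the Gaussian response this is a
  reporting convention, not an odds ratio.

## Synthetic colony

The generator stands in for unreleased field recordings; its defaults are
the study conditions.

* **Trajectories**: planted-match probability is linear in age on the
  log-odds scale per condition. Anchor values are interpreted as means over
  the first (0–4 d) and last (15–19 d) age bins — the form in which the
  quantities are reported — and the line is solved to hit those bin means
  exactly. Defaults: control 20% → 2%; varied rises to 35% at weaning;
  each playback condition doubles from the first to the last bin; the
  feeding trajectory is the varied one scaled down 1.5× in probability
  (a rate ratio, matching the "1.5 times more often" phrasing; at the
  odds-ratio reading the realized proportion ratio would be ≈ 1.33).
* **Sequences**: calls come in groups of template length (controls draw a
  template uniformly per group). Within groups, onset-to-onset gaps are
  ≈ 0.75–0.97 s; between groups > 1.2 s, so classifier windows never span
  groups. Planted matches walk the template direction with |steps| ≥
  115 Hz; non-matches use |steps| ≤ 80 Hz, so the 100 Hz rule separates
  them even with ±2 Hz estimation error (sensitivity and false-positive
  rates are calibration-tested).
* **Variance reduction**: the number of planted matches per session is the
  randomized rounding of (number of sequences × trajectory probability),
  with match flags placed uniformly at random. Marginally each sequence is
  planted with the trajectory probability, but realized session rates
  concentrate on it instead of fluctuating binomially — appropriate for a
  generator whose purpose is testing recovery of its own configured rates.
* **Similarity gain**: for varied pups the scatter of planted-call features
  (sequence base F₀ SD = 2 × `f0_sd`, step jitter ±40 Hz, duration SD
  0.08 s, gap jitter) shrinks linearly with age; the schedule constant was
  calibrated by simulation so the default configuration yields the
  configured 25% rise in mean Mantel r from the first to the last age bin
  (early r ≈ 0.74), with feeding/control trajectories flat. Gains far from
  the default are realized only approximately (the noise→r map is
  nonlinear and the schedule saturates).
* **Seeding**: every session draws from `default_rng([seed, pup, day])`, so
  runs are bit-reproducible and restricting the simulated day set leaves
  the remaining sessions unchanged.
* **Tabular generators**: `simulate_match_table_from_effects` draws
  call-level outcomes directly from the logistic mixed model at specified
  odds ratios (default: the study's fitted values, age coded as the four
  5-day bins — at a per-day coding those coefficients would saturate the
  probabilities), 4 pups × 400 calls per condition, random-intercept SD
  0.5. `simulate_mantel_rows` draws per pup × bin r values (baseline 0.55,
  varied slope = 25% of baseline over 3 bins, pup SD 0.04, residual SD
  0.045 — chosen so the varied trend is detectable with ~85–90% power in
  the 12-pup design, consistent with its clearly significant report).

## Problem sizes and runtimes

Colony round-trip checks synthesize audio at 16 kHz (a generator
parameter; default 96 kHz). Planted F₀s, durations and hence match
fractions are rate-independent, and 16 kHz comfortably covers the 60–800 Hz
F₀ band and its harmonics. Round-trip cells use ≥ 2 000 calls (4 pups ×
~110 calls/day over the evaluated bins; the condition/development ratio
colony uses 8 pups × 50 calls/day × 20 days), which puts three binomial
SDs at ≤ 3 percentage points on the anchored fractions. The GLMM recovery
experiment averages 20 replicate fits.

## Known limitations

* Clean-signal operation is the tested contract: no wind/surf noise,
  overlapping callers, or noise-robust pitch tracking.
* The generator does not model adult or seabird calls, source levels,
  propagation, amplitude variation across days, or within-call F₀
  contours beyond constant pitch.
* The greedy window assignment is one deterministic resolution of
  overlapping candidate matches; alternatives (e.g. latest-window or
  maximum-matching) would differ on pathological chains.
* Exponentiated Gaussian-LMM estimates are reported for table parity only.
* Formant estimation is included as an optional feature and is not part of
  any reported quantity.
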