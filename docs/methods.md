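# Methods

This note documents the models implemented in `ciderev`, the parameter
choices that matter, and what the synthetic evaluation can and cannot
show.

## Room simulation

**Geometry.** The virtual listening room is a 7 × 6 × 3.5 m shoebox with
uniform, frequency-independent pressure reflection coefficient `r` on all
six surfaces.  A spherical head (radius 0.16 m) sits 1.9 m from the
source on the room's long axis, symmetric about the room centre; each ear
is an ideal point receiver on the sphere surface, perpendicular to the
source direction.  Scattering, diffraction, head shadowing and source
directivity are deliberately absent.  The source is at 1.5 m height and
the head centre at 1.3 m.  The height offset is deliberate: with source
and receiver at exactly equal heights, every ceiling/floor image pair of
the lattice arrives at *exactly* the same instant, and their coherent
summation inflates the reverberant energy by up to 3 dB.  Room-acoustic
measurement practice avoids symmetric positions for the same reason.

**Image-source method.** Specular reflections only; each image
contributes an impulse of amplitude `r^n / d` at the sample nearest
`d / c` (`c` = 343 m/s), truncated at 1.5 × RT60 (leaving < 0.1 % of the
energy).  With all-positive amplitudes the image-source model accumulates
a non-physical low-frequency pedestal (the classic DC-buildup artifact),
so reverberant responses are high-passed at 100 Hz (2nd-order
Butterworth).  Anechoic responses (`r = 0`) are returned untouched.

**RT60 control.** `reflection_coefficient_for_rt60` inverts Eyring's
relation `RT60 = (24 ln10 / c) V / (−S ln(1−α))` with `α = 1 − r²`
(closed form, exact round-trip through the forward formula).  Eyring
describes the *diffuse-field* decay; an ideal specular shoebox with
uniform absorption decays 20–30 % more slowly, because grazing paths
along the longest dimension meet walls less often than the mean free
path assumes.  `study_room` therefore treats the Eyring inverse as an
initial guess and runs a deterministic secant search on `r` until the
*measured* Schroeder T30 of the simulated response equals the target
(0.5 % tolerance) — the same "adjust the surfaces until the achieved
RT60 is right" procedure one uses with any room simulator.  Sabine's
formula is kept as a cross-check; it agrees with Eyring within ~5 % only
for absorption below ≈ 0.1 (the gap is `−ln(1−α)/α − 1`).

**Metrics.** RT60 is estimated from the backward-integrated (Schroeder)
energy decay curve by a least-squares line on the −5…−35 dB span (T30
convention, RT60 = −60/slope); inputs whose energy does not decay are
rejected.  DRR integrates the direct energy over ±2.5 ms around the
direct-path arrival and divides by everything after the window.  The
2.5 ms half-width is a common convention separating the direct path from
the first reflections; in this geometry the earliest reflection trails
the direct sound by well over 2.5 ms, so the window contains the direct
path only.  With these choices the simulated room yields DRR = −3.9 dB
at RT60 = 0.4 s and −8.7 dB at 1.0 s at the 1.9 m distance.

## STFT

32 ms square-root Hann window, 8 ms hop (75 % overlap), FFT = window,
16 kHz.  The square-root window is applied at analysis and synthesis so
overlap-add reconstruction is exact (machine precision) and robust under
spectral modification.  With one frame of lookahead the algorithmic
latency of the chain is ≈ 40 ms.  The signal is padded by one window on
each side internally; `synthesize` returns exactly the original length.

## WPE dereverberation

Per frequency bin, the output is the delayed-linear-prediction error
`d_t = x_t − Σ_{τ=Δ}^{Δ+L−1} g_τ* x_{t−τ}`, with `g` the weighted
least-squares solution using weights `1 / max(λ_t, ε·mean λ)` where `λ`
is the desired-speech PSD.  Singularity is handled by a relative
diagonal load (1e−6 of the mean autocorrelation diagonal); bins with no
past energy get a zero filter outright.

* **Prediction delay Δ = 4 frames (32 ms).**  With a 32 ms window and
  75 % overlap, frames fewer than 4 hops apart share samples and are
  deterministically correlated even for anechoic input; a shorter delay
  lets the predictor cancel clean speech itself.  Δ is exposed for
  experimentation.
* **Order L = 12 frames (~100 ms of tail).**  Long enough to remove the
  energetically dominant early part of the tail, short enough to leave
  the late tail to the post-filter — the division of labour that
  distinguishes the two processing variants.
* **PSD floor ε = 0.03 of the per-bin mean power.**  The floor bounds
  the weight spread.  A near-zero floor makes silent gaps dominate the
  fit: gap suppression improves but the filter visibly distorts
  speech-carrying frames and the intelligibility score *drops below* the
  unprocessed condition.  Three percent balances suppression and
  fidelity on the synthetic corpus.
* **PSD source.**  `oracle_psd` uses `|clean|²` (floored) — the
  idealised stand-in for a trained PSD estimator, available in
  simulation where the clean signal is known.  The iterative variant
  re-estimates `λ ← |output|²` for a configurable number of rounds
  (default 3); its weighted log-likelihood objective is tracked per
  iteration and is non-increasing.
* Filter estimation is batch (whole utterance), matching the offline
  concatenation protocol; no recursive variant is provided.

## Late-reverberation post-filter

A Wiener-style gain `max(φ − φ_late, 0)/φ`, floored at −12 dB and
lightly smoothed across frequency (5-bin Hann) to suppress isolated
musical-noise dips.  The late-tail PSD `φ_late` follows an exponential
decay with constant `δ = 3 ln10 / RT60`.  Two estimators are available:

* **Observation-driven** (standalone default):
  `φ_late(t) = e^{−2δD} φ(t−D)` with `D` the late delay (default
  100 ms).  Simple, but blind to the difference between a decaying vowel
  and a reverberant tail.
* **Reverberation-informed** (used in the WPEPF chain): the tail beyond
  the WPE prediction span `(t₀, t₁)` is extrapolated from the power WPE
  itself removed,
  `φ_late = e^{−2δt₁} / (e^{−2δt₀} − e^{−2δt₁}) · smooth(φ_removed)`.
  On clean input WPE removes almost nothing, so the gains stay near one
  and clean speech passes through — a guarantee the observation-driven
  form cannot give.  This estimator is what lets the WPEPF variant add
  benefit on reverberant input while leaving anechoic input with STOI
  ≥ 0.98.

## STOI

The standard short-time objective intelligibility measure: resample to
10 kHz; remove frames more than 40 dB below the loudest clean frame;
25.6 ms Hann frames at 50 % overlap, 512-point FFT; 15 one-third-octave
bands from 150 Hz; per band, 384 ms (30-frame) envelope segments are
normalised, clipped at −15 dB signal-to-distortion, and correlated with
the clean envelopes; the score is the mean correlation.  The
implementation is validated against an independently written,
loop-structured reference implementation (machine-precision agreement on
seeded signal pairs).  Inputs must be time-aligned; the stimulus
protocol compensates the direct-path delay before scoring.

## Synthetic sentences and protocol

Each pseudo-sentence (~1.8 s) is five word-like bursts of a harmonic
carrier (f0 drifting within 100–140 Hz) with per-word formant resonators
(F1 300–800, F2 1000–2200, F3 2400–3200 Hz, diphthong-like glides),
1–2 syllables per word, occasional noise-burst onsets, and inter-word
gaps of 60–130 ms.  The Hilbert envelope carries ≥ 50 % of its
modulation power in the syllabic 2–8 Hz range, so reverberation
demonstrably smears it and STOI responds.  Two properties are essential
and deliberate:

* **Jitter and shimmer.**  The fundamental carries ~2.5 %
  Ornstein-Uhlenbeck jitter and the amplitude ~2 dB shimmer.  Without
  them the carrier is a sustained chord whose frames are perfectly
  predictable at any lag, and a delayed linear predictor cancels the
  *speech*; with them, clean speech is nearly unpredictable at the
  32 ms prediction delay, as natural voices are.  Voiced material still
  retains genuine pitch continuity, so the strict "WPE leaves clean
  input bit-identical" idealisation holds only for noise-like signals;
  on clean sentences the contract is STOI ≥ 0.98 and a small filter
  norm.
* **Determinism.**  A sentence is a pure function of its seed.

The presentation protocol concatenates a sentence five times, convolves
the whole concatenation with the room response (tails flow across copy
boundaries), processes it in one piece, and extracts the segment aligned
with the fourth copy (offset by the direct-path delay).  More than 5 s
of material precedes the extracted copy, so the prediction filter is
fully initialised and no edge transients reach the scored segment.
Initialising with three *different* sentences instead of copies changes
the scored benefit by < 0.02 STOI.

Digital level convention: sentences are RMS-normalised to −26 dBFS; no
absolute SPL calibration is modelled.

## Simulated listening study

**Listeners.**  Each listener is a three-parameter psychometric function
on the STOI axis: `p(word correct) = (1 − lapse)·logistic(slope·(STOI −
s50))`, words scored as independent Bernoulli draws (5 words per
sentence).  Population defaults: slope uniform 12–20 per STOI unit,
lapse uniform 0–0.05, and `s50` from a truncated normal with SD 0.04.
The location is the package's one fitted calibration: the anchor equals
the measured mean STOI of the synthetic corpus reverberated at
RT60 = 1.0 s (0.547; `scripts/calibrate_listeners.py` recomputes it), the
truncation (0.51–0.635) keeps every psychometric function crossing 50 %
inside the titration grid, and the truncated-normal location is solved
so the *truncated median* equals the anchor.  Consequently the cohort's
median RT60 threshold lands at ≈ 1.0 s by construction — a designed,
not emergent, agreement.

**Titration.**  Percent correct for 10 unprocessed reverberant sentences
at each grid RT60 (0.4–1.4 s, 0.1 s steps, same sentence pool at every
step since synthetic listeners have no memory); RT60_50% is the linear
interpolation at the first downward 50 % crossing (an exact 50 % grid
point short-circuits; no crossing is an error naming the achieved
range).

**Crossover protocol.**  Six conditions (clean / reverberated ×
unprocessed / WPE / WPEPF), test and retest each, 20 sentences × 5 words
per cell, randomised cell order per listener (logged, not modelled).
Reverberant cells use the listener's RT60_50% rounded to the 0.05 s grid
the stimuli exist on; rounding also lets the stimulus bank share
impulse responses and STOI scores across listeners, which is what keeps
the full study at ~3 minutes of compute.

**Statistics.**  Scores are transformed to rationalised arcsine units,
`RAU = (146/π)(arcsin√(x/(n+1)) + arcsin√((x+1)/(n+1))) − 23`, and
analysed with linear mixed models fit by REML (statsmodels `MixedLM`):
a subject random intercept with i.i.d. residuals — the scaled-identity
covariance.  The condition effect is a Wald F test on the condition
coefficients; all 15 pairwise contrasts use the fixed-effect covariance
with Šidák correction `1 − (1−p)^m`.  A second model on the reverberant
conditions only adds the (centred) RT60_50% covariate and its
interaction with condition.  Degrees of freedom follow the residual
approximation `N − k_fixed − n_subjects`; parameter-recovery and type-I
calibration tests, not df bookkeeping, are the correctness contract.

**Subjective ratings.**  Eight pairs (four measurement, four control) on
a 0–100 slider with 50 = indifference.  The simulated preference is
driven by the difference in *perceived* intelligibility — each
listener's psychometric function evaluated at the two stimuli — through
a saturating slider map `50 + 50·tanh(6·(p_A − p_B)) + N(0, 8)`,
clipped to [0, 100].  The psychometric stage is what makes the control
pairs behave: two transparent algorithms on clean speech differ
slightly in STOI but not in perceived intelligibility at ceiling, while
the same STOI difference mid-range is clearly audible.  Each
presentation uses a sentence drawn per listener/pair/replicate from an
8-sentence pool.  Per pair, listener means of test/retest feed a
one-sample two-tailed t test against 50 with Bonferroni correction
within outcome; a zero-variance degenerate case reports p = 1 with a
flag rather than raising.

**Reliability.**  ICC(3,1) — two-way mixed, consistency, single
measurement — from the explicit mean-square decomposition, with the
F-distribution 95 % CI; verified against both a brute-force ANOVA
decomposition and `pingouin.intraclass_corr`.

## Problem sizes and runtime

The package's own evaluation runs at: 20-sentence condition sets for the
STOI orderings; a 15-listener study with 11 titration points × 10
sentences and 6 × 2 × 20-sentence crossover cells; 100 simulated studies
for mixed-model parameter recovery and 500 for type-I calibration
(simulated directly at the RAU level, no audio).  The full test suite
takes ~6 minutes; the acceptance script a few seconds.

## What the synthetic evaluation does and does not show

The generator produces envelope statistics and spectral shapes close
enough to speech for reverberation, dereverberation and STOI to interact
realistically, and every pipeline property asserted here (benefit
ordering, clean-speech neutrality, threshold titration, statistical
calibration) is expected to transfer qualitatively.  It does not contain
lexical content, so absolute intelligibility percentages, absolute STOI
values and human effect sizes are not comparable to listener studies
with real corpora; the study-level checks are therefore sign- and
ordering-level, not numeric reproductions.  Known limitations: no
binaural/HRTF rendering or head shadow; frequency-independent wall
absorption; the oracle PSD upper-bounds what a trained estimator could
provide (the iterative variant lower-bounds it); batch processing only;
rating simulation is a two-parameter caricature of preference
judgements.
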