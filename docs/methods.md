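# Methods

`sniffsync` analyzes synchronized four-channel physiology sessions
(EEG1, EEG2, EMG, Resp at 400 Hz) from freely moving mice, linking the
respiration rhythm measured by an implanted thoracic-pressure sensor to
cortical state.  This note records the models, estimators, parameter
choices, and known limitations; everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Respiration frequency estimation

The dominant sniff frequency is estimated per rolling 1-s window (50-ms
shift).  Each window is linearly detrended and standardized, its
autocorrelation computed, and the reciprocal lag of the first qualifying
autocorrelation peak taken as the window's frequency.  Design details the
one-line recipe leaves open, fixed here:

* **Energy normalization.**  Each lag's product sum is divided by the
  energies of *both* overlapping segments.  The plain (biased or
  triangular-corrected) estimate carries phase-dependent boundary terms
  that shift the first peak by up to ~1.5 lags; the energy-normalized
  score is exactly 1 at a periodic window's period.
* **Peak qualification.**  First local maximum after the first zero
  crossing, at lag ≥ 1/15 s (capping detectable rate at 15 Hz), with
  plain autocorrelation value ≥ 0.2.  The plain value is used for
  qualification because the energy-normalized score is noisy at long lags
  and would let aperiodic windows through; with this gate, white noise
  yields essentially no estimates.
* **Sub-lag interpolation.**  Cosine interpolation through the three
  samples around the peak (exact for a sinusoidal autocorrelation), with
  a parabolic fallback.
* **Lag cap.**  Lags are searched up to 3/4 of the window, requiring at
  least a quarter-window overlap (slowest detectable rhythm ~1.3 Hz for a
  1-s window).

Accuracy: on pure sinusoids the error stays below one autocorrelation lag
quantum wherever the window holds at least 2.5 cycles (≥ 2.5 Hz).  Below
that, the prescribed detrending interacts with the partial cycle and
accuracy degrades to ~0.06 Hz — far below the quantum at those
frequencies (e.g. 0.006 Hz at 1.5 Hz).  A rolling window necessarily
smooths rapid transitions: an abrupt frequency step appears ramped over
±0.5 s, which slightly dilutes bout-onset contrasts (see the bout-trial
recovery below).

Inhalation peaks (troughs of the thoracic-pressure cycle) are detected on
a zero-phase 1–15 Hz band-passed copy: local minima with minimum spacing
of one maximal-rate cycle, prominence ≥ 25% of the median trough
prominence, sub-sample refinement by parabolic interpolation, and a
rhythmicity gate that keeps only troughs whose surrounding second of
signal has a qualifying autocorrelation peak.  On generator sessions with
additive noise at 10% of the sniff amplitude, ≥ 95% of true inhalation
times are matched within ±5 ms.

Trial construction around exploration bouts follows the fixed rules:
trials cover 3 s before to 3 s after bout start; bouts with under 3 s of
prior recording are discarded; baseline = mean frequency over the first
500 ms of the trial; exploration frequency = mean over the first 1 s of
the bout; trials with over half the baseline missing are dropped with a
logged count.  Per-state intersniff statistics assign each interval to
the vigilance state of its earlier peak and summarize rate as
1/mean(interval) — under cycle-to-cycle rate jitter this is the harmonic
mean of cycle rates, slightly below the arithmetic mean.

## Vigilance-state scoring

Wake/NREM/REM labels are assigned per 5-s epoch from three features: delta
(1–4 Hz) power and theta (4–10 Hz) power of the mean of the two EEG
channels (Welch), and EMG RMS.  The rule: EMG above tone threshold →
wake; otherwise delta above threshold → NREM; otherwise theta/delta ratio
above 1 → REM; otherwise wake.  Thresholds are relative to session
medians (EMG: 2× median epoch RMS; delta: 1.5× median epoch delta power),
which makes labels exactly invariant to common rescaling of the signals.
These scoring bands are deliberately distinct from the coherence-analysis
bands and kept as separate named constants.  REM→NREM transitions are
counted as a QC flag, never forbidden.  The scorer is a reproducible
rule-based stand-in for semi-automated scoring with manual verification;
it is validated only against synthetic truth (≥ 90% epoch accuracy on
planted schedules, typically ≥ 99%).

Sleep-odor trials use the standard layout: respiration sensor on 10 s
after NREM onset (for 1 min), odor 10 s later, state transitions counted
in the 20 s after odor, respiration/EEG compared over the 5-s windows
before vs. after odor (paired t test).  Trials where the animal is not in
NREM at odor time are excluded.

## Behavior

Velocity uses the body-center point (not the nose, which inflates speed
through head bobbing): displacement between consecutive frames times the
frame rate.  Exploration bouts start at the first frame with the nose
within 2 cm of the object (inclusive boundary) and end at the next frame
outside.  Movement classification computes EMG RMS over sliding 2-s bins
(0.5-s step) and calls a bin moving when RMS exceeds 10–20% (default 15%)
of the session-maximum bin RMS — a deliberately low bar, so "still"
requires very low muscle tone.  Degenerate case: when the session has no
burst structure at all (max bin RMS under twice the median) there is
nothing to be still *relative to*, and every bin is classed still.

## Locally-stationary spectral analysis

Bands: delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30 Hz.  Each band is
analyzed in non-overlapping epochs holding about five cycles of the band
midpoint — 2.22, 0.83, 0.5 s, and 0.25 s for beta (the five-cycle rule
rounds to 0.24 s; the conventional 0.25 s is pinned as an override).
Epochs are anchored at the start of each contiguous telemetry-valid
segment and never straddle a gap; partial epochs are dropped, not padded.

Within each epoch the 4×4 spectral matrix is estimated with K = ⌈1.5 p⌉ =
6 orthonormal sine tapers.  Two structural choices matter and differ from
the most literal pipeline reading:

* **No band-pass prefilter before estimation.**  With the five-cycle
  rule, the K-taper bandwidth at the band midpoint spans roughly the
  band, so the center-bin estimate is already band-local.  Prefiltering
  all channels to the band empties exactly the frequencies the outer
  tapers sample, collapsing the effective taper count and inflating
  *every* pairwise estimate (measured null mean 0.47 against the
  theoretical 0.25; without the prefilter, 0.252).  Zero-phase
  Butterworth band filters remain available (`bandpass`,
  `prefilter=True`) for display and signal construction.
* **Center-bin band evaluation.**  The per-epoch band value is the
  estimate at the FFT bin nearest the band midpoint.  Averaging across
  the (strongly correlated) in-band bins changes nothing in expectation
  but destroys the exact null law below; `band_mode="mean"` is available.

Partial coherence between channels j and k given all others is
|G_jk|²/(G_jj·G_kk) with G = S⁻¹, a scale-free measure of direct
association in [0, 1]; with p = 2 it reduces to ordinary magnitude-squared
coherence.  Reported pairs are the EEG1–EEG2–Resp triangle, each
conditioned on the remaining channels including EMG.

**Null law and p-values.**  Under H0 the center-bin estimate is
Beta(1, ν−1) with ν = K − (p−2) effective complex degrees of freedom
(taper count reduced by one per conditioned channel), giving
p = (1−c)^(ν−1).  Calibration is verified by simulation: rejection at
α = 0.05 on independent-noise epochs lands at 0.05 within Monte-Carlo
error.  FDR control uses Benjamini–Hochberg over the pooled pairs ×
epochs family.

**Regularization.**  With K ≥ p the per-epoch matrices are almost surely
invertible, so the pipeline default is no shrinkage (weight 0), keeping
the null law exact.  When shrinkage is requested (collinear channels,
K < p situations) the default mode shrinks the spectral *coherency*
matrix toward the identity while preserving each channel's power —
shrinking toward the scaled identity instead (`mode="identity"`) lets a
high-power narrowband channel's trace swamp weaker diagonals and crush
their coherences.  The weight used is recorded in outputs.

**Small-sample debiasing.**  The raw estimate is biased upward
(E = 1/ν = 0.25 under H0 at ν = 4).  The exact finite-sample mean
function of the estimator (Goodman's distribution, evaluated by
quadrature with ₂F₁) is tabulated and inverted; `estimate_debiased` maps
each raw value to the population value whose expected estimate matches.
Event-locked regression applies the inversion to fitted *cell means*,
where it is consistent; p-values always use the raw estimate.

**Band power** is the diagonal of unregularized multitaper matrices
averaged over delta-length epochs, normalized so mean power over
0.5–20 Hz is 1.

## Event-locked inference

`lagged_event_regression` regresses per-epoch estimates on indicator
variables for lags −3…+3 epochs around each event (the epoch containing
the event start is lag 0); baseline is every epoch more than three epochs
from any event; events without full ±3 context are dropped and counted.
Coefficients are reported on the population scale via the mean-function
inversion above (delta-method standard errors; raw-scale p-values, where
the equal-bias null is exact).  The same machinery serves exploration
bouts and sleep odor-introduction events.  At the recovery-test scale
(100 events, K = 6, one modulated epoch per event) the lag-0
coefficient's sampling SD is ≈ 0.026 — an intrinsic degrees-of-freedom
floor, reproduced by maximum-likelihood and pooled-spectra variants.

Connectivity graphs pool still-epoch estimates per pair (mean raw
estimate, inverted to the population scale); an edge is drawn when the
pooled estimate exceeds 0.15, solid when the pooled p-value (normal
approximation to the mean of null Beta variates) is below 0.05, dashed
otherwise.

The movement confound check fits Sniff_rate ~ EMG_RMS + (1 | animal).
The derived correlation rescales the fixed effect by *within-animal*
(group-demeaned) SDs — the model adjusts for between-animal variation, so
pooled SDs would re-import exactly the spread it removed.  With one
animal the model degrades to OLS with a warning and matches its slope
exactly.  The check is run on all bins, still bins, and moving bins.

## Synthetic sessions and ground truth

The generator produces sessions with the statistical structure the
analysis assumes, plus exact generative truth for recovery tests.  All
components draw from per-component substreams of one global seed; the
same config and seed reproduce byte-identical session files.

**Respiration** is a phase oscillator: the phase advances at the
instantaneous rate (state base rate + per-cycle Gaussian jitter truncated
at 3 SD + bout increment + any scheduled boosts), and the waveform is
`a·sin(φ − π/2 − 0.3·sin φ)` — an asymmetric cycle whose minimum sits
*exactly* at each φ = 2πk crossing, so truth inhalation times are exact.
Per-cycle amplitude jitter is interpolated within the cycle by a
smoothstep with zero slope at the boundaries, preserving that exactness.
State defaults (free parameters, not calibrated claims): wake 7.0 Hz
(jitter SD 1.2, amplitude 1.0), NREM 3.0 Hz (0.25, 0.4) — slow and
regular, low amplitude — and REM 3.3 Hz with doubled NREM jitter (0.5)
plus amplitude jitter, i.e. slightly irregular.  The default exploration
increment is +3 Hz.

**Coupled EEG.**  Each EEG channel sums, per band, a shared band-limited
component (the band-filtered respiration channel for Resp pairs; an
independent band-limited source for the EEG1–EEG2 pair), weighted as
w = √(c/(1−c) · N(f_c)/S(f_c)), plus independent band-limited noise and
weak broadband noise.  S and N are *multitaper-smoothed* PSDs at the band
midpoint (band epoch length, K = 6): calibrating against pointwise PSDs
overstates the coherence a finite-bandwidth estimator can see when a
narrowband component faces broadband noise.  With this calibration the
achieved magnitude-squared coherence at the band midpoint equals the
target by construction, and the implied *partial* coherences (closed form
from the weights) are exported in truth.  Inside bouts the weight
switches to the bout-modulated level.  State-dependent gains on the
independent band noise give NREM its delta dominance and REM its theta
dominance; EMG is white noise whose RMS follows the state (wake 1.0,
NREM 0.3, REM 0.05) times a burst gain (10×) inside movement intervals.

Limitation: respiration is a single narrowband rhythm, so a band's
coupling is only controllable when the sniff fundamental lies within that
band estimator's bandwidth.  Coupling injected into a band far from the
sniff rate stays at the null floor (the estimator's bandwidth is
dominated by nearer harmonics that the band's shared component does not
contain).  Recovery tests therefore probe each band in a session whose
sniff rate feeds it — delta at 2.25 Hz sniffing, theta at 6 Hz, alpha at
10 Hz.  Real EEG-respiration coupling is broadband in ways this generator
does not emulate; passing tests demonstrate estimator correctness, not
physiological realism.

**Tracking** builds the nose trajectory in polar coordinates around the
object: the nose–object distance follows a piecewise-linear profile whose
perimeter crossings are analytically known (exported as truth bouts, so
detector recovery within ±1 frame is a meaningful check), with slow
angular drift and smooth wandering between approaches; body center and
tail trail the nose toward the arena center.  A sleep-odor session lays
out sensor-on and odor events for every NREM segment of at least 60 s
(sensor on at onset + 10 s for 1 min, odor at onset + 20 s) and applies
the configured respiration response (+2 Hz for 10 s by default) after
each odor.

**VAR oracle.**  A stable VAR(1) simulator with the closed-form spectral
matrix S(f) = H Σ Hᴴ, H = (I − A e^{−iω})⁻¹, provides an independent
route to ground-truth partial coherence (e.g. the chain X→Z→Y, whose
X–Y partial coherence is exactly zero while ordinary coherence is not).
It is used only as a test oracle, never by the analysis pipeline.

## Problem sizes

Recovery simulations use sizes that make their tolerances meaningful
while staying desk-scale: 10-minute records for oracle and calibration
checks, 5000 epochs for null rejection, 1000 replicates for FDR control,
50 bout trials, 100 coupling-modulation events, 2000 bins × 4 animals for
the mixed model, and a 600-s five-segment schedule for scoring.

## Known limitations

* The sub-2.5 Hz frequency-estimator accuracy floor and the rolling-window
  smoothing of rapid rate transitions, described above.
* The vigilance scorer is validated against synthetic truth only; real
  scoring involves manual verification this package does not emulate.
* The p-value law assumes the center-bin Wishart model; a strong
  quasi-deterministic spectral line in a channel perturbs the estimator's
  finite-sample mean slightly away from the Gaussian-process form used in
  debiasing (a few hundredths at moderate coupling).
* More severely, when the spectrum *within* the taper bandwidth is
  dominated by off-center power (e.g. theta-band epochs during NREM,
  where 4× delta noise and a 3 Hz sniff line sit inside the theta bin's
  bandwidth), the tapered coefficients of independent channels become
  similarly structured and their pairwise estimates inflate well above
  the null floor.  Band estimates are trustworthy where the band of
  interest carries the local spectral mass — the awake-still and
  awake-exploring regimes the connectivity and exploration analyses are
  designed for — and should not be read in sleep epochs for bands far
  from the dominant sleep rhythms without prewhitening.
* Shrinkage-weight selection is fixed/manual; no data-driven weight.
* The generator's arena trajectories are kinematically plausible but not
  behaviorally realistic (no rearing, grooming, or pose structure).
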