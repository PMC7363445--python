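# Methods

`ripplelock` implements a complete ripple-locked analysis of
hippocampal–neocortical coupling in sleep EEG: artifact rejection, detection
of discrete sleep spindles and sharp-wave ripples (SW-R), construction of
matched ripple-free surrogate events, Morlet-wavelet time–frequency
analysis, trial-ensemble connectivity (coherence, phase-locking value,
orthogonalized power correlation, partial directed coherence), and the
associated permutation and z-statistics. Because clinical intracranial
recordings are not redistributable, the package ships a synthetic
two-channel generator with exact ground truth; every stage is validated
against it.

## Signal model and conventions

Two channels: a neocortical scalp channel ("NC", Cz-like) and a hippocampal
depth channel ("HIPP"), sampled at 1 kHz, amplitudes in µV. Sleep staging
is an input: a plain-text hypnogram with one of {W, S1, S2, SWS, REM} per
20 s epoch. "NREM" means S2+SWS; S1 is excluded by default because its
inclusion would contaminate the surrogate pool with wake-adjacent activity
(a flag restores it). Time is seconds from recording start, intervals are
half-open, samples 0-based.

## Artifact rejection

Three automated detectors run per channel with thresholds computed per
sleep stage:

* **amplitude** — |signal| > 750 µV after 0.3–150 Hz filtering. The
  high-pass is a *causal* first-order 0.3 Hz filter (the shape of an
  acquisition filter): a zero-phase filter splits a step's excursion
  symmetrically, so a sustained 800 µV deflection would peak near 430 µV
  and never trip the bound, defeating the rule's purpose.
* **gradient** — sample-to-sample difference of the zero-phase 0.3–150 Hz
  band-passed signal outside median ± 6·IQR (two-sided). For a normal
  difference distribution 6·IQR ≈ 8.1 SD, so clean signal is almost never
  flagged; a degenerate IQR of zero (constant derivative) yields no flags,
  since a constant-slope signal has no transient.
* **hf_burst** — RMS (100 ms centred window) of the >150 Hz high-passed
  signal above median + 4·IQR for at least 100 ms. The centred RMS window
  smears a burst of duration d into a run of about d + 100 ms, so the rule
  is applied to the window-compensated run length; otherwise any strong
  50 ms transient would pass the 100 ms criterion through smearing alone.

Flagged samples are padded by ±250 ms and clean gaps shorter than 3 s are
closed (class `short_gap`). All FIR filtering is zero-phase single-pass
with odd-length linear-phase kernels and odd-reflection edge padding
(keeps the derivative continuous at the boundary; plain reflection creates
a kink whose high-frequency transient the burst detector would flag).

## Event detection

Both detectors share one scheme: band-pass (12–16 Hz spindles, 80–120 Hz
ripples), moving-RMS envelope (200 ms window + 200 ms smoothing for
spindles; 20 ms + 20 ms for ripples), thresholds from the envelope's mean
and SD over artifact-free NREM samples only:

|            | detect        | upper guard  | duration      |
|------------|---------------|--------------|---------------|
| spindles   | mean + 1.25·SD| mean + 5·SD  | 0.4–3 s       |
| ripples    | mean + 2.5·SD | mean + 9·SD  | 38–500 ms     |

Events are maximal supra-threshold runs inside the duration bounds; an
event whose envelope exceeds the upper guard anywhere is discarded as a
probable artifact. Ripples must additionally show ≥3 cycles, counted as
alternating extrema with prominence ≥ 0.5× the segment maximum on a
40–300 Hz trace — an operationalisation of visual cycle counting that is
immune to the ~3 Hz sharp-wave offset underneath the ripple (zero-crossing
counting fails there, and counting on the raw trace is ill-posed under 1/f
drift). Spindle peaks are the deepest filtered trough, ripple peaks the
largest positive filtered peak.

A frequency-profile check rejects broadband false positives: the
event-locked wavelet profile (spindles 9–19 Hz in 0.5 Hz steps averaged
over ±0.5 s; ripples 65–135 Hz in 2 Hz steps over ±50 ms) must have its
*global maximum* as an interior peak inside the band of interest with peak
prominence ≥ 20% of the maximum. The global-maximum reading (rather than
"any in-band peak") is what actually rejects 1/f-tilted broadband
transients, whose profile maximum sits at the low-frequency grid edge.
Note the discriminative power is limited by physics: within the ±0.5 s
averaging span a 13 Hz wavelet (σ_t ≈ 0.17 s) provides only ~3 independent
temporal samples, so single-event profiles are noisy and a genuinely flat
transient is rejected stochastically (~60% of draws), not deterministically.

Because all thresholds are data-derived, detection is exactly invariant
under positive rescaling of the signal.

Two practical consequences of envelope thresholding are worth keeping in
mind downstream: detected onsets lag the physical onset of a
waxing–waning event (the crossing sits inside the envelope), and detected
durations carry the smoothing of the RMS windows. Event *midpoints* and
*differences between channels* are latency-free.

## Matched control events

For each detected ripple, 100 surrogate intervals of identical duration
are drawn from artifact-free NREM such that the surrogate ±1.5 s padding
contains no detected ripple, centres fall within ±10 min of the ripple
weighted by a truncated Gaussian (SD 200 s by default; configurable —
wide enough to span slow vigilance drifts while still preferring the
ripple's neighbourhood), and spans never overlap across all 100
sets. On window exhaustion the window widens in 5-min steps with a
warning; true exhaustion is an error, never a silent constraint violation.
An `audit_control_sets` routine re-verifies every constraint exhaustively.

Capacity arithmetic matters: 100 sets consume 100× the total ripple
duration of eligible clean NREM. The default generator night maximises
detector recall through a high ripple duty cycle and therefore cannot host
a full surrogate draw; control-based analyses use the
`coupling_night_config` (50 min, 1.5 ripples/min, 0.08–0.2 s), whose rates
sit in the clinical range.

## Time–frequency analysis

Morlet wavelets on a 1–20 Hz grid (0.5 Hz steps, coefficients every
20 ms). Cycles adapt to frequency: n(f) = max(5, ⌈f/2⌉) for f ≥ 5 Hz and
2–4 cycles below 5 Hz (2 for f ≤ 2, 3 for 2.5–3.5, 4 for 4–4.5), keeping
low-frequency wavelets short. The temporal width σ_t = n/(πf) averages
0.167 s over the 12–16 Hz grid. Coefficients are rescaled by 1/√σ_t so a
pure tone elicits the same response at every frequency regardless of the
cycle rule — without this the adaptive rule tilts frequency profiles.
Cells whose wavelet support crosses an epoch edge are NaN, never
zero-padded; epochs are cut at ±3 s so the ±1 s analysis window always has
full support. For whole-night work the recording is convolved once and
event stacks are sliced from the continuous coefficients (5 ms grid,
lock-point snap error ≤ 2.5 ms).

Power contrasts are computed against the per-ripple average of the 100
control TFRs (paired design) with a cluster-based permutation test:
per-cell paired t, 4-connected supra-threshold clustering at α = 0.05,
cluster-mass statistic against a sign-flip null (1000 permutations
default). Event-locked power can also be expressed as percentage change
from a −2 to −1.5 s pre-event baseline.

## Connectivity

All measures operate on the same wavelet coefficients:

* **coherence** — trial-ensemble magnitude coherence
  |⟨XY*⟩|/√(⟨|X|²⟩⟨|Y|²⟩) per (f, t); magnitude (not squared) by default.
* **PLV** — |⟨exp i(φ_X − φ_Y)⟩| across trials.
* **orthogonalized power correlation** — Y⊥X = imag(Y·conj(X)/|X|) per
  cell; power(X) is correlated with power(Y⊥X) across trials, the
  symmetric map likewise, and the two averaged. Removing the
  instantaneously in-phase component makes the measure immune to volume
  conduction and common-reference leakage; collinear cells (residual power
  < 1e-12 of the original) are invalid.
* **PDC** — non-parametric partial directed coherence. Per sliding 512 ms
  window (20 ms steps over ±1 s), the trial- and window-averaged wavelet
  cross-spectral matrix is extended to 0 Hz by nearest-value padding,
  Hermitian-corrected at the grid edges (the DC and edge matrices of a
  real process must be real; estimated wavelet CSDs violate this slightly
  and the factorization cannot converge otherwise), and factorized with
  Wilson's spectral matrix factorization (upper-triangular zero-lag
  convention, tolerance 1e-9, ≤200 iterations). The PDC is formed from
  Ā(f) = H(f)⁻¹ with column-wise (outflow) normalisation
  π_{i←j} = |Ā_ij|/√(Σ_k |Ā_kj|²). Smoothed wavelet spectra often settle
  into a small limit cycle instead of meeting the step-size tolerance; a
  window is accepted when the factorization reconstructs its CSD to <5%
  median relative Frobenius error, which is ample for PDC, and marked
  invalid otherwise.

Directionality is summarised as z(NC→HIPP) − z(HIPP→NC): each direction's
12–16 Hz band-mean PDC time course is z-scored per time point against its
distribution over the 100 control sets. The z-scoring is essential for
narrowband rhythms: a pure spindle carrier confines the raw phase-slope
information to a ~1 Hz sliver, so raw PDC differences are small and noisy
while the control-referenced z is stable. Display/interpretation can be
restricted to times of significant coherence via a mask argument.

## Event-level statistics

Peri-ripple histograms of spindle onsets (50 ms bins, ±0.5 s, normalised
by total onset count × 100) with per-bin z against control-locked
histograms; per-patient duration tertile splits (linear-interpolated 1/3
and 2/3 quantiles; boundary ties go to the discarded middle tertile);
one-sided independent-samples t for long- vs short-ripple power;
per-patient Spearman correlation of ripple duration with spindle-band
window power, Fisher-z transformed (|r| clipped just below 1) and tested
against zero across patients; and spindle/ripple contingency rates (±1 s
window).

## The synthetic generator

The generator is a statistical phantom, not a biophysical model. Defaults
(frozen before use as study conditions, chosen so the default night gives
near-ceiling detector recall):

* background: 1/f pink noise (exponent 1, 20 µV RMS, content below 0.3 Hz
  suppressed) + 0.8 Hz slow oscillation (25 µV);
* HIPP additionally carries dense bounded-amplitude sub-ripple HF bursts
  (80–120 Hz, 2–5 µV, 100/min, 50–300 ms) emulating hippocampal
  gamma/HFO background. These are load-bearing: the detectors' mean+k·SD
  thresholds presume background whose envelope variance is dominated by
  bounded bursty activity. A purely Gaussian background makes the upper
  guard clip true events (pooled SD too small) while its unbounded tails
  cross the detection threshold and create false positives; bounded bursts
  supply the variance without the tails.
* spindles: sine under a Hann envelope, 1.0–2.25 s, 18 µV, 7/min per
  channel, with per-event carrier frequency drawn uniformly from
  13.5 ± 1.25 Hz. The frequency variability is physiological
  (event-to-event spindle frequency varies by 1–2 Hz) and also
  load-bearing for directionality: with a single fixed tone the coupling
  delay's phase signature occupies a ~1 Hz sliver and directional
  estimates become realization-dependent; across variable-frequency
  events the trial-averaged cross-spectrum carries the delay's phase
  slope over the whole band;
* ripples: 90 Hz sine under a Tukey(0.5) envelope riding a single 3 Hz
  sharp-wave cycle (40 µV), 0.12–0.32 s, 28 µV, 7/min. The flat-topped
  Tukey envelope (rather than a Gaussian) keeps the supra-threshold run
  close to the nominal duration, which the tertile and duration–power
  analyses need; a Gaussian envelope halves detected durations and breaks
  the 38 ms minimum for short events.
* coupling: each ripple is preceded (p = 0.8) by an NC spindle whose onset
  leads the ripple peak by 225 ms and a HIPP spindle leading by 75 ms
  (truncated-Gaussian jitter, SD 10 ms). The HIPP spindle's carrier is 90%
  a copy of the NC carrier delayed by 20 ms (renormalised to unit
  amplitude — the same-frequency carrier sum otherwise shrinks coupled
  events by up to 20%), giving a ground-truth NC→HIPP direction.
  `duration_effect` scales coupled-spindle amplitude linearly with ripple
  duration around the configured midpoint.
* events are placed by a thinned Poisson process (≥1 s + one event length
  between events per channel and kind) inside S2/SWS blocks only; the
  default hypnogram is W 5% / S2 40% / SWS 30% / REM 15% / S2 10%.
* injected artifacts: Tukey-windowed 900 µV excursions, 400 µV
  single-sample step discontinuities with smooth decay, and 200 Hz bursts
  of 150 ms at 60 µV, placed clear of true events.

Event rates and ripple durations in the default night are deliberately
higher/longer than clinical values (≈5 spindles/min, ≈1.2 ripples/min,
≈50 ms ripples): high event duty is what gives the data-derived upper
thresholds room above the true events. The `coupling_night_config` uses
clinical-range ripple rates instead, at the price of detector precision
(~0.6); analyses that need 100 non-overlapping control sets run there.

What passing tests on the phantom do **not** show about real data: the
phantom has stationary background statistics within stages, perfectly
narrowband events of fixed amplitude, no epileptiform activity beyond the
injected artifact classes, and no genuine physiological coupling
variability. Detector F1 values near 0.95 are properties of this
separability regime, not promises about clinical recordings.

## Problem sizes and determinism

The bundled validation uses a 30-minute default night for detector
recovery, a 50-minute night for control/connectivity analyses, five
25-minute "patients" for the duration-effect analyses, 200 simulations for
permutation-test calibration and 2000 for the z-statistic null. All
randomness flows from explicit integer seeds (`numpy.random.default_rng`);
a fixed seed reproduces every number bit-for-bit.

## Known limitations

* EDF output is 16-bit with per-channel symmetric scaling; round trips are
  exact only to quantization, and recordings are padded to whole seconds.
* The spindle/ripple detectors inherit the envelope-thresholding biases
  described above (onset latency, duration smearing); analyses that need
  latency-free anchors should use peaks or midpoints.
* Wilson factorization on wavelet grids is accepted at <5% reconstruction
  error rather than strict convergence; PDC values carry that numerical
  floor.
* The 2×2 (two-channel) case is the only supported connectivity setting;
  no conditional/multivariate extensions.
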