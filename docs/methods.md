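# Methods

This note records the models and conventions behind `ppgkit`, the
choices made where the literature leaves them open, and what the
synthetic data can and cannot establish.

## Synthetic pulse model

A single pulse over one beat period is a sum of three components minus
a notch, all parameterized as fractions of the period:

* early systolic wave: Gaussian, centre 0.15, width 0.045, amplitude 1
  (the reference);
* late systolic wave (wave reflection): Gaussian, centre 0.26, width
  0.025, relative amplitude `late_systolic_amp_ratio`;
* diastolic wave: **two-sided** Gaussian — rise width 0.05, fall width
  0.18 — centre `diastolic_frac`, relative amplitude
  `diastolic_amp_ratio`. The asymmetric fall emulates the Windkessel-
  like diastolic runoff of real PPG: a symmetric component would leave
  the last ~40 % of the beat exactly flat, which real fingertip PPG
  never shows, and which would collapse the centre of the SPAR
  attractor into a point mass at the origin (any segment that is flat
  over 2τ maps x(t)=x(t−τ)=x(t−2τ) to (0,0)).
* dicrotic notch: a Gaussian of depth 0.05 and width 0.02 subtracted at
  the interior minimum of the base curve between the late-systolic and
  diastolic centres, capped at 2.5 notch-widths before the diastolic
  centre so the incisura does not erode the diastolic apex. If no
  interior minimum exists (no diastolic wave) the notch is omitted —
  there is no incisura to deepen.

Pulses start and end within 1 % of zero, so beats concatenate without
steps. Component widths narrower than two samples raise a resolution
error; at the default widths this requires roughly fs ≥ 250 Hz for
heart rates above ~100 bpm (the bundled cohorts use 500 Hz, matching
high-resolution pulse-wave databases).

**Aging map** (linear in age over 25–75 y): diastolic amplitude ratio
0.45 → 0.15, diastolic timing 0.46 → 0.36 of the period (the reflected
wave returns earlier as arteries stiffen), late-systolic amplitude 0.55
→ 0.95 (systolic augmentation). Endpoints are package choices that
reproduce the directions reported for vascular aging; they are plain
dataclass fields and can be overridden wholesale via `AgeMapping`.

**Signals.** Beat periods are i.i.d. lognormal with mean 60/HR and CV
`hrv_cv` (positivity; simplest stationary HRV surrogate). Baseline
wander is a single sinusoid (default 0.15–0.3 Hz, respiratory band),
sensor noise is white Gaussian, and motion artefacts are half-sine
transients of 1–3× pulse amplitude and 0.2–1.0 s duration placed by a
Poisson process. One integer seed determines every draw bit-exactly.

**Activity presets** (sleep / seated / exercise) move heart rate (55 /
70 / 110 bpm), beat-period CV (0.05 / 0.07 / 0.12) and artefact rate
(0 / 0.5 / 4 per minute); exercise additionally raises the diastolic
wave by +0.15 (peripheral vasodilation).

**Default study cohorts.** Young (25–35 y) and elderly (65–75 y),
n = 20 each, 70-s recordings at 500 Hz analysed over 60-s windows.
Heart rate (60–80 bpm), wander, noise (0.5–2 % of pulse amplitude) and
artefact rate are sampled from identical ranges in both groups; age and
beat-period CV differ (young 0.06–0.10, elderly 0.02–0.04 — heart-rate
variability declines across adulthood), so the cohorts differ in
morphology *and* variability, as real aging cohorts do.

What the generator does **not** emulate: pulse-shape change within a
recording (morphology is fixed per subject), respiratory amplitude
modulation, sensor saturation, coloured noise, and any mechanistic
haemodynamics — cardiac/vascular parameters act directly on morphology.
Passing tests therefore demonstrate correctness of the *analysis* under
controlled, known-truth conditions, not performance on clinical data.

## Beat processing

The detector computes a slope-sum transform (windowed sum of positive
slopes, window 0.128 s) of the 0.4–8 Hz band-passed signal, finds peaks
above a rolling 75th-percentile threshold (3-s window) separated by a
refractory period of 0.35 × the current cycle estimate, then refines
the systolic peak locally and takes the preceding minimum as the pulse
onset. The initial cycle estimate is the first *substantial*
autocorrelation peak in the 0.25–2 s lag band (at least half the
tallest in-band peak — spiky waveforms put small side-lobes before the
fundamental, harmonics only after it). A final guard rejects detections
whose median interval is unsupported by the autocorrelation (< 0.15),
which is what rejects white noise. Autocorrelations are finite-window
corrected (unbiased normalization).

`mean_cycle_length` is the median inter-onset interval, falling back to
the autocorrelation peak when detection fails; both failing is a
cyclicity error. Pulse quality is the Pearson correlation of each
time-normalized beat (100 samples) against the running median template
(11 beats, centred), accepted at ≥ 0.9 by default. Ensemble averages
are pointwise means and SDs of the time-normalized accepted beats.

## Fiducial point analysis

Derivatives use Savitzky–Golay filtering (window 0.05 s, order 3; both
configurable) — raw differentiation of PPG is noise-dominated.
Landmarks are *located* on the smoothed trace and smoothed derivatives,
but pulse-domain *amplitudes* are measured as the raw-signal extremum
within half a smoothing window of the landmark, so smoothing cannot
bias amplitude ratios.

Search conventions (pulse duration T):

* systolic maximum: global interior maximum (flat pulses are
  malformed);
* dicrotic notch: the most *prominent* local minimum after the last
  prominent systolic maximum in [0, 0.35 T] and before 0.8 T.
  Prominence (≥ 10⁻³ of the pulse range) rather than depth separates
  the incisura from noise dips in the low-amplitude diastolic tail;
  anchoring past the last systolic peak excludes the p1–p2 saddle.
  Fallback: the e-wave time, if it lies past the systolic complex;
* diastolic peak: largest prominent maximum after the notch; fallback:
  first deceleration inflection (local maximum of the first
  derivative), flagged `inflection`;
* p1: first prominent pulse maximum; p2: largest prominent maximum
  between the systolic apex and the notch, with a third-derivative
  shoulder fallback;
* SDPPG a: first prominent second-derivative maximum before the
  systolic apex (within [0, 0.25 T]); b: first prominent interior
  minimum after a within (a, 0.4 T], falling back to the global
  minimum in (a, 0.75 T] when the window holds no interior minimum (a
  symmetric single-hump pulse has its SDPPG minimum at mid-pulse, past
  the window); e: the prominent maximum nearest the notch (the e-wave
  accompanies the incisura), or the largest in (b, 0.6 T] when no
  notch exists; c/d: largest maximum and following minimum between b
  and e; f: first prominent minimum after e. SDPPG wave candidates
  must clear a prominence of 2 % of the SDPPG range — below that they
  are treated as noise wiggle.

Missing landmarks are flagged, never zero-filled; indices that depend
on them are NaN ("missingness is data"). The 48-index catalogue spans
six families — timings, normalized timings, amplitudes, areas (A1/A2
split at the notch, IPA = A2/A1, IPAD = IPA + d/a), first-derivative
and SDPPG ratios — each entry documented in `fpa_registry()`. Indices
for a window are per-beat medians over quality-accepted beats by
default (an index missing on more than half the beats stays NaN);
`ensemble` mode computes them once on the ensemble-averaged pulse.

## SPAR

Delay τ = round(fs · cycle/3), minimum 1 sample. Windows are min–max
normalized to [0, 1] before embedding by default (making density maps
comparable across windows); normalization is off in the exact-
invariance tests, where offset annihilation and drift translation hold
to machine precision. The density grid is 251×251 over the fixed extent
[−0.85, 0.85]² (data in [0, 1] satisfy |v| ≤ 2/√6, |w| ≤ 1/√2), so maps
from different windows are bit-comparable.

Key-index operationalizations (exact formulas for these attractor
quantifiers are not standardized, so these are package conventions,
versioned in the registry):

* `opening_5pct` = r(5 %)/r(95 %), where r(q) is the smallest radius
  enclosing q of the point mass (`opening_1pct` … `opening_50pct`
  likewise);
* `rotation_deg` = arg of the mean of exp(i·3θ), divided by 3, in
  [0, 120);
* `peak_width_deg` = circular SD of the 3θ-folded angles of the **arm
  points** (radius ≥ the median radius), expressed on the attractor
  scale. Near-origin points carry no angular information; including
  them reverses the index's response to beat-to-beat variability;
* `bandwidth` = median over occupied 10° angular bins of
  (r90 − r10)/r(95 %) within the bin;
* `symmetry` = 1 − (max − min) of the three rotation-aligned 120°
  sector masses;
* `arm_density` = 1 − exp(−(max bin mass / mean non-zero bin mass)/25).
  The 1/25 scale keeps the statistic resolvable in float64 (the raw
  ratio is O(10–100), and 1 − exp(−s) would saturate).

The remaining registry entries (radial percentiles and moments, sector
masses/spreads/bandwidths, angular and radial entropies, density
statistics, winding count, per-cycle loop-area CV, successive-point
distances, v/w moments) are documented in `spar_registry()`.
`attractor_quality` scores cyclicity as the first substantial
autocorrelation peak of the band-limited, 1st/99th-percentile-clipped
signal (clipping keeps rare motion transients from dominating the
energy), in [0, 1].

## Classification

AUC is rank-based with midranks for ties: AUC = P(b > a) + ½ P(b = a),
identical to the trapezoidal area under the empirical ROC curve and
verified exactly against all-pairs enumeration. Because index polarity
is arbitrary across the catalogue, both the raw and the folded value
max(AUC, 1 − AUC) are reported; significance is folded AUC > 0.85, with
no multiple-testing correction by default (a Benjamini–Hochberg option
exists but is off, matching the single-threshold screening convention).

## Numerical and degenerate-input conventions

Resampling uses zero-phase polyphase filtering for rational ratios
(demeaned, with a cubic-spline-corrected edge guard) and cubic-spline
interpolation otherwise. Beat-period rounding: each beat is rendered
with round(period·fs) samples. Degenerate inputs raise typed errors
(flat pulse → malformed; white noise → insufficient beats / cyclicity;
empty density → degenerate attractor; empty group → insufficient data)
rather than returning junk, and the batch pipeline logs and skips
failing signals instead of aborting the run.

## Known limitations

* `opening_5pct` = r(5 %)/r(95 %) does **not** increase strictly
  monotonically over the six-age sweep of this generator, although the
  young/elderly cohorts separate perfectly on it. Two confounds: r(95 %)
  itself grows with age (the spike-like normalized elderly pulse throws
  its arms farther), and isolated trajectory crossings near the origin
  — phases where x(t) ≈ x(t−τ) ≈ x(t−2τ) — drag the global 5 %
  quantile down at mid ages as the diastolic timing sweeps 0.46 T →
  0.36 T. The inner-envelope openings (`opening_1pct`,
  `opening_2_5pct`) do rise strictly with age; the headline 5 % index
  keeps its plain definition rather than being tuned around the
  confound.
* `arm_density`'s max-bin concentration statistic is high-variance (its
  extreme-value numerator), highly sensitive to sensor-noise level, and
  its within-cohort age trends run in opposite directions in the two
  cohorts; at the default noise ranges it does not reach the 0.85
  screening threshold between the cohorts (folded AUC ≈ 0.7–0.8) even
  though it responds strictly monotonically to beat-period variability
  under clean conditions. Denoised, high-passed, coarser-grid and
  top-mass-share estimator variants were evaluated and do not resolve
  this without breaking the clean-condition monotonicity.
* The per-beat SDPPG indices assume the smoothing window (0.05 s)
  suits the sampling rate; at 100 Hz the window is 5 samples and SDPPG
  ratios are coarse. Ensemble mode is preferable for low rates.
* The ROC screen treats subjects as exchangeable and windows as one
  observation per subject; no within-subject replication model is
  provided.
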