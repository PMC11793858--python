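# Methods

## Study design being modelled

The pipeline targets a within-subject protocol: each participant performs
four computerized tests (Stroop, visual / auditory / dual N-Back), each
consisting of an initial rest phase followed by three task sub-phases,
while PPG, EDA and skin temperature are recorded from the hand.  After
each test the participant rates the sub-phases on a four-level scale;
together with the rest baseline this yields five classes 0–4 per
(subject, test, phase).  Each test is analysed as a separate dataset.
The default design is 28 participants x 4 phases x 43 features = 4816
rows per test dataset.

Class labels for task phases are sampled from a configurable
distribution; the default `(0.15, 0.35, 0.35, 0.15)` over classes 1–4 is
deliberately non-uniform (self-ratings cluster at moderate levels) but is
a package default, not a claim about any particular population.

## Synthetic cohort generator

The generator's purpose is validation: every quantity a detector is
supposed to estimate is planted explicitly and returned as ground truth.

* **Inter-beat intervals.**  IBI(t) = µ(c) + a_LF·sin(2π·0.10·t) +
  a_HF·sin(2π·0.25·t) + ε, with ε white Gaussian.  The two tones sit in
  the middle of the conventional LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz)
  HRV bands, so band-power features have known targets.  Parameters that
  could produce non-positive intervals (amplitude sum + 4σ ≥ µ) are
  rejected; the rare >4σ noise excursion is clipped.
* **PPG.**  A unimodal template per beat — half-cosine rise (class-
  dependent rise time, default 0.13–0.15 s) and exponential decay
  renormalised to reach zero at the 0.4 s pulse end — placed at the
  cumulative IBI onsets, plus white noise (default SD 5 % of the unit
  pulse amplitude).
* **EDA.**  Tonic level + slope·t, plus SCR events from a homogeneous
  Poisson process (class-dependent rate, default 2–8 events/min) shaped
  by a Bateman kernel k(t) = e^(−t/τ₂) − e^(−t/τ₁) with τ₁ = 0.7 s,
  τ₂ = 3.0 s, normalised to unit peak so planted amplitudes are in µS of
  resulting peak height.  Explicit event times/amplitudes can be supplied
  for deterministic tests.
* **Temperature.**  Linear drift (class-dependent slope, default −0.0005
  to −0.0025 °C/s) plus AR(1) noise (ρ = 0.8, SD 0.01 °C).

Default per-class effect sizes are chosen so that a cohort of realistic
size separates baseline from altered states without being trivial; they
are validation instruments, not physiological claims.  The generator does
**not** model task content, motion artifacts, sensor drift/detachment,
respiration coupling, ectopic beats, or between-subject morphology
differences — so green tests demonstrate correctness of the pipeline's
arithmetic and recovery behaviour under the stated model, not robustness
to every artifact of real recordings.

Phase duration defaults to 300 s (at least one 60 s spectral window is
required, hence the 60 s lower bound).  The simulation sampling rate
defaults to 128 Hz — the documented acquisition chain (1200 Hz sampling,
50 Hz notch, 30 Hz low-pass, 0.1 Hz PPG high-pass) stays below Nyquist at
this rate while full-cohort runs stay cheap; 1200 Hz can be configured.

## Preprocessing

Zero-phase (forward–backward) filtering is used throughout: features are
computed offline and fiducial timing must not be shifted.  Defaults:
4th-order Butterworth low-/high-pass sections, notch quality factor 30.
Windows for per-beat statistics are 10 s, non-overlapping, with trailing
partial windows discarded (padding would bias window statistics).

## Feature extraction

* **Beat detection.**  Peaks are picked on a 0.5–8 Hz band-passed copy
  with an adaptive height threshold and a 0.3 s refractory period, then
  refined on a lightly smoothed copy.  The pulse foot is the last
  crossing of 8 % of pulse height above the local baseline before the
  peak; the baseline is the 10th percentile of the preceding valley (a
  plain minimum would let single noise dips drag the foot early).  The
  threshold crossing sits ~25 ms after the true onset systematically;
  this cancels in IBI differences and stays well inside the 50 ms
  matching tolerance used in validation.
* **Shape features.**  Mean / sample SD (ddof = 1) / median of per-beat
  amplitude, foot-to-foot duration and foot-to-peak rise time, computed
  per 10 s window over the beats whose foot falls inside, then averaged
  across windows.  Windows with fewer than two beats are skipped with a
  logged warning.
* **BPM trend.**  Instantaneous rate 60/IBI assigned at each interval's
  closing beat, linearly interpolated to a uniform 4 Hz grid spanning
  only the beats where a rate is defined (no extrapolation).
* **Spectral HRV.**  Short-time periodogram of the mean-removed trend:
  60 s Hann windows, 50 % overlap, density scaling.  At 4 Hz this gives a
  1/60 Hz resolution, enough to resolve the 0.04 Hz band edge.  Band
  powers integrate bins over half-open bands [0.04, 0.15) and
  [0.15, 0.4] — the 0.15 Hz boundary belongs to HF, so LF + HF tiles the
  total band with no double counting.  The LF/HF ratio divides by
  max(P_HF, 1e−12) to keep noiseless fixtures finite; features are the
  mean and SD of each quantity over window columns.
* **pNN50** uses the standard inter-beat-interval definition (successive
  IBI differences > 50 ms) rather than any trend-based reading; RMSSD and
  SDNN (ms) complete the catalogue's IBI-domain entries — they bring the
  registered set to its fixed size of 43.
* **EDA decomposition.**  The convex program
  min ½‖y − k∗q − Bc‖² + α·1ᵀq + γ/2‖D₂c‖², q ≥ 0, with B a cubic
  B-spline basis (knot every 10 s) and D₂ second differences of the
  spline coefficients.  On the non-negative orthant the ℓ₁ driver penalty
  is linear, so the objective is a smooth box-constrained QP; it is
  solved by FISTA with restart, FFT-based convolution operators and a
  power-iteration Lipschitz estimate.  The input is decimated to 8 Hz
  (line-padded polyphase resampling — zero padding would fabricate edge
  transients that the solver would explain as SCRs) before solving; the
  decomposition lives on that grid and reconstructs its input exactly by
  construction (residual := y − tonic − phasic).  Defaults α = 0.02,
  γ = 0.05 were fixed by a coarse grid on simulated phases (criterion:
  exact event-count recovery at zero noise, no spurious drivers on
  constant/ramp inputs) and are exposed as parameters.  SCR peaks are
  phasic local maxima at least 0.01 µS above the preceding trough;
  the count feature is the per-phase count (phases have equal duration
  by default, so count and rate are interchangeable up to a constant).
* **Temperature.**  The derivative estimator removes the least-squares
  line, low-pass filters the residual at 0.1 Hz (zero-phase), applies
  central differences and adds the line's slope back — exact for linear
  drifts, robust at the edges.  Initial/final values are intercepts of a
  local linear fit over the boundary second evaluated at the endpoint:
  as robust to sample noise as a 1 s mean, but exact on ramps, so
  delta = final − initial and variation = delta/duration keep their
  closed forms.

## Normalization and assembly

Max–min normalization is applied per subject and per feature **within
one test dataset** (datasets are analysed separately; pooling across
tests would let one test's range distort another's).  Constant features
map to 0 and are flagged degenerate; missing values are flagged but kept
as rows, so the row-count identity is checked on every assembly.

## Screening

Kruskal–Wallis (mid-ranks, tie-corrected, chi-square p) runs over the
populated class distributions of each feature.  Mann–Whitney U is exact
(full enumeration) when both samples have ≤ 8 tie-free observations and
otherwise uses the normal approximation with tie-corrected variance and
continuity correction; degenerate all-tied inputs return p = 1.
Benjamini–Hochberg is applied within each feature's family of pairwise
p-values (4 in BA, 10 in OA) — the correction addresses the multiplicity
of *that* comparison family; pooling across the full feature x pair
family is available via `bh_scope="pooled"`.  Bullet-matrix membership
requires the BH-adjusted decision, not raw p < 0.05.  Classes with fewer
than two observations for a feature cause that pair to be skipped and
logged.

## Validation strategy and problem sizes

The test suite validates each stage against independent oracles:
closed-form hand computations, full Mann–Whitney enumeration, Monte-Carlo
permutation of the Kruskal–Wallis H, a separate Welch periodogram for
planted spectral content, and the simulator's ground truth for detectors.
Error-rate behaviour of the screening is measured at the feature-table
level (i.i.d. null features / planted mean shifts), which isolates the
statistical stage from signal-processing variance: 50 null tables for
false-discovery control (empirical per-feature any-rejection rate ≈ 0.06
at q = 0.05, bound 0.10) and 20 replicates x 4 tests for recovery of a
five-feature planted subset (≥ 80 % required).  Signal-level checks use
300 s phases at 128 Hz for beat detection and spectral balance, 120 s
phases for EDA recovery, and a small 4-subject cohort for the end-to-end
pipeline run; these sizes keep the full validation suite within a few
minutes on one core while leaving every statistical margin wide.

## Known limitations

* The simulator's beat-to-beat spectrum is a two-tone caricature of real
  HRV; absolute band-power values are only meaningful relative to the
  planted amplitudes.
* The EDA solver's sparsity weight trades event splitting against event
  merging; closely spaced SCRs (≲ 2 s) merge into one detected peak, so
  recovered counts undercount at high event rates.
* Rank tests with the default skewed label distribution leave some
  altered classes with ~10–15 observations per test; OA comparisons
  between adjacent altered classes are accordingly low-powered, which is
  a property of the design, not of the implementation.
* The first/last beat of a phase and SCRs starting near the phase end are
  partially observed and may be dropped by the detectors.
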