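# Methods

This note documents the models, processing rules, and numerical choices
behind `gaitemg`, and what the synthetic-data generator does and does not
emulate.

## Signals and segmentation

A trial is one over-ground trot pass with marker trajectories at 200 Hz
and surface EMG at 2000 Hz on a shared clock (t = 0 common to both;
sample k of a signal sits at k/fs).  Trot is modelled as a two-beat
diagonal gait: left hind + right fore impact together, then right hind +
left fore half a stride later, with a stance fraction of 0.45.  Strides
are half-open impact-to-impact windows of a reference limb.  Kinematic
variables are segmented by the left hind; each EMG channel is segmented
by the hindlimb *contralateral* to its side, so the channel's own limb
cycle starts at 0% of its segmentation stride (forelimb muscles via the
diagonal pair, hindlimb muscles half a stride offset).

### Gait events

Candidate ground-contact dips are runs of (10 Hz low-passed) hoof height
below 5% of that hoof's vertical range.  The impact is timed by the
downward crossing of a 15%-of-range level just before the dip, linearly
extrapolated to the dip's median height; lift-off symmetrically after the
dip.  The naive alternative — the velocity zero-crossing inside the dip —
is biased by tens of milliseconds on flat-stance hooves because low-pass
filtering smears the touchdown corner and moves the velocity zero into
stance; the crossing-extrapolation rule times impacts to ≤ 2.5 ms on
synthetic data (one kinematic frame is 5 ms).  Limbs with fewer than
three impacts are an error, not a guess.

## Kinematic chain

* Occlusion gaps of ≤ 10 frames are filled by cubic splines (exact on
  polynomial trajectories up to degree 3); longer or boundary gaps stay
  masked and flag the strides they touch.
* All trajectories are low-passed at 10 Hz (Butterworth 4th order,
  forward–backward, i.e. zero phase; the magnitude response is applied
  twice).  Zero-phase filtering is used throughout the package because
  activation and kinematic timings are compared across signals filtered
  with different cutoffs.
* Vertical displacements of poll, withers and pelvis are additionally
  high-passed at 0.5 × the measured stride frequency (≈ 0.65 Hz) to
  remove drift while keeping the stride fundamental and its
  asymmetry-bearing second harmonic.  Because that cutoff's settling time
  spans whole strides, the filter is fed a phase-aligned cyclic extension
  of the record's edge strides instead of the default odd reflection;
  otherwise mm-scale edge transients leak into the first and last strides
  (enough to bias MinDiff recovery by ~0.3% of a large injection).
* MinDiff/MaxDiff: per stride, the filtered displacement must show
  exactly two interior minima and maxima (2%-of-range prominence);
  otherwise the stride is flagged and excluded.  Each extremum is
  assigned to the limb (fore pair for poll/withers, hind pair for pelvis)
  whose impact most recently preceded it — robust to global timing
  offsets, and mirror-consistent: relabelling left↔right in the input
  negates every index.  Sign convention: left-associated minus
  right-associated.
* Hip Hike: left minus right tubera coxae excursion (max − min of the
  10 Hz-filtered height) over the ipsilateral hindlimb's full swing
  (lift-off to next impact), assigned to the stride containing the
  lift-off.
* Stride speed: per-stride mean of the central-difference speed of the
  tubera sacrale marker's horizontal coordinates after the 10 Hz
  low-pass.
* Joint angles are sagittal-plane (x–z) interior angles between adjacent
  two-marker segments; limb pro-retraction is the signed angle of the
  limb line (spina scapulae→MCP, tuber coxae→MTP) against the normal of
  the trunk line (T6→tubera sacrale), protraction positive.  Working
  relative to the trunk line makes the angles invariant to global
  translation and in-plane rotation.  The static trial defines the
  reference pose; with two-marker sagittal segments that calibration is
  the identity, so evaluating the static trial returns its own reference
  angles exactly (the references are still carried for reporting; a full
  3D cardan decomposition on rigid marker clusters is out of scope).
* Time normalization: linear interpolation onto 101 equally spaced nodes
  spanning the stride window, node 0 and node 100 on the two events.

## sEMG chain

DC removal (channel mean), 40 Hz high-pass, full-wave rectification, and
two linear envelopes of the rectified signal: 25 Hz for
amplitude-normalized stride curves and 10 Hz for activation timing (all
Butterworth 4th order, zero phase; envelopes clipped at zero because
zero-phase low-passing a rectified signal can undershoot slightly).

* **ARV** is the mean rectified value over each segmentation stride.
  Outliers are flagged strictly outside mean ± 2 SD (n−1 estimator)
  within each (subject, muscle, side, condition) group, one pass, no
  re-iteration; groups smaller than 3 are left alone.
* **RVC normalization**: the ARV reference is the maximum non-outlier
  baseline-stride ARV per muscle-side; the envelope reference is the
  maximum baseline stride peak of the 25 Hz envelope after a second 2-SD
  pass on the peaks themselves.  Values are reported as % of the
  reference and may exceed 100% under induced conditions (the RVC is
  submaximal).
* **Double-threshold activation detection** on the 10 Hz envelope: a
  sample is candidate-active above 10% of the signal's per-trial peak
  envelope (relative, so detection is invariant to positive rescaling;
  the ±5% amplitude adjustment is a per-channel configuration override,
  never automatic).  Within each stride, sub-threshold dips shorter than
  5% of the baseline mean stride duration are merged, then bursts shorter
  than that same threshold are discarded.  Burst duration is counted in
  whole samples so a burst spanning exactly the threshold is retained
  regardless of float rounding.  Onsets/offsets are reported in % of the
  containing stride.

## Statistics

* **Discrete contrasts**: per variable, a linear mixed model (condition
  fixed, subject random intercept) via statsmodels; with speed
  correction, stride speed enters as a centred fixed covariate plus a
  per-subject random slope — a mean-zero random slope alone cannot
  absorb a condition-correlated speed shift.  Estimated marginal means
  and the contrast p-value are reported; non-convergence (or fewer than
  three subjects, where the fixed intercept is not identifiable against
  the random intercepts) falls back to a paired contrast of subject
  means, flagged in the output.  % difference uses the baseline EM mean
  as denominator and is "n/a" for signed asymmetry variables.  P-values
  are Benjamini–Hochberg adjusted within one induction contrast
  (configurable family).
* **Induction sufficiency**: forelimb sufficient iff |Δ mean poll
  MinDiff| or |Δ MaxDiff| strictly exceeds 13 mm; hindlimb iff the
  pelvis analogue exceeds 5 mm — in both cases with the induced-condition
  SD of the qualifying index below its induced mean magnitude.  The
  variability rule is applied to the induced condition (the choice among
  baseline/induced/difference was open).
* **1D SPM**: per subject, condition, and variable, the node-wise median
  across strides forms a 101-node field; conditions are compared by a
  node-wise paired t (df = n−1, residuals = centred differences).  Field
  smoothness (FWHM) comes from the variance of normalized residual
  gradients (Kiebel-style); the two-tailed, Bonferroni-corrected critical
  threshold t\* solves

      P(T_ν > t*) + R · √(4 ln 2)/(2π) · (1 + t*²/ν)^(−(ν−1)/2) = α/(2m),

  with R = 100/FWHM resels.  Constant residuals (infinite FWHM) degrade
  to the pointwise t quantile; for very small df combined with many
  resels/comparisons the expected-EC curve never drops below α_eff, in
  which case the threshold is reported as infinite and no cluster can be
  significant — an honest statement that the design cannot control the
  family-wise rate, not a cap.  Suprathreshold clusters are maximal runs
  of |t| > t\* with endpoints linearly interpolated to fractional %
  stride; cluster p-values use the expected-cluster-extent (Poisson
  clumping, exponential extents) approximation, capped at α.  An
  exhaustive sign-flip permutation of the paired differences (2⁸ = 256
  flips at the study's n = 8) provides the independent max-|t| threshold
  used to validate the analytic one; the two agree within a few percent
  on smooth nulls, and the full stage's empirical family-wise error on
  smooth Gaussian nulls (FWHM 20, 1000 replicates) sits inside the 95%
  binomial band around the nominal 0.05.
* The Bonferroni family in a pipeline run defaults to the number of
  variables in the tested panel, overridable.  Multi-subject runs pair
  subject-level median strides; a single-subject run pairs strides by
  index between the two conditions (the within-horse comparison).

## Synthetic data generator

The generator produces the study conditions with recoverable ground
truth:

* **Stride plan**: lognormal stride durations (CV 3% by default; means
  0.77 s baseline, 0.75 s forelimb induction, 0.71 s hindlimb induction),
  constant speed 3.5 m/s, 20 strides per trial, with a 0.75-stride
  lead-in/out.
* **Upper body**: each landmark's height is A·sin(4πφ) over stride phase
  φ (two oscillations per stride; A = 55/30/45 mm for poll/withers/
  pelvis).  Asymmetry is injected by adding a one-period raised-cosine
  (Hann) bump of half-width ¼ stride centred on the targeted extremum.
  On its support that bump equals DC minus the stride's second harmonic,
  so it shifts the targeted extremum by exactly the bump height, leaves
  the other three extrema of the stride untouched (they sit at the bump's
  zero-slope edges), and keeps the waveform C¹ — injected MinDiff/MaxDiff
  therefore equal the bump heights by construction.  Hip hike adds an
  analogous bump at the swing-phase height maximum of one tuber coxae.
  Preset injection magnitudes correspond to moderate inductions
  (e.g. poll MinDiff −53.73 mm for the forelimb case; pelvis MinDiff
  −22.25 mm, MaxDiff −27.87 mm, hip hike −61.73 mm for the hindlimb
  case).
* **Hooves**: flat during stance, sine arc during swing (cycloid-like
  forward progression), so ground contact starts exactly at the planned
  impact times.
* **Limb chains**: joint markers are placed by two-segment chains with
  prescribed sagittal angles (a common 15° pro-retraction term peaking at
  impact plus per-segment flexion sinusoids) — plausible smooth curves
  for exercising the angle and SPM stages, not a musculoskeletal model.
* **EMG**: each channel is white noise band-limited to 20–450 Hz (the
  sensor band, so the 40 Hz analysis high-pass has real work to do),
  unit variance, amplitude-modulated by per-stride burst envelopes with
  raised-cosine edges (taper 3% of stride) plus a noise floor of 5% of
  the channel's largest burst amplitude, and a small DC offset.  Default
  burst timings are stylized within-stride activity windows (fore muscles
  late swing approaching impact; hind muscles late swing through stance;
  semitendinosus with a second early-swing burst, latissimus with a short
  extra burst) — chosen so no preset burst wraps the stride boundary,
  which keeps per-stride truth/recovery comparisons unambiguous;
  `make_burst_envelope` itself supports wrapping bursts.  Induced presets
  rescale burst amplitudes per muscle and side (ratios of order 0.9–3.6)
  and shift some timings by ±4% stride.
* **Ground truth** stores true impact/lift-off times, the injected index
  values, and per-stride activation timings *as defined by the detector's
  measurand*: the double-threshold rule (10%-of-peak crossing, dip merge,
  minimum duration) applied to the noise-free modulation profile passed
  through the definitional 10 Hz envelope filter.  The envelope filter is
  part of the definition of "onset" here, not a copy of the estimator's
  noise path.

What the generator does **not** emulate: ground-reaction forces and true
dynamics, out-of-sagittal motion, soft-tissue artifact, electrode
crosstalk, heart-rate artifacts, marker-occlusion patterns of real
capture volumes, or inter-stride correlation structure beyond duration
jitter.  Passing the recovery tests therefore shows the *analysis chain*
is correct and calibrated on signals with the right structure and noise
character — it does not validate the biological realism of any preset.

## Recovery performance (computed by the test suite)

On noiseless presets the pipeline recovers injected MinDiff/MaxDiff/Hip
Hike within 0.5 mm (residual bias is a slight under-recovery from filter
attenuation, ~0.4%) and activation timings within 1% stride as a
per-channel average; at preset noise the aggregate bias over 20 seeds
stays within 5% (indices) and 2% stride (timings).  Single-stride timing
errors can reach ~1.5% because the detector's amplitude threshold uses
the ripple-inflated envelope peak — a property of the estimator, shared
by any implementation of the same rule.

## Problem sizes

Calibration and recovery checks run at desk scale: 1000 null replicates
for the family-wise error rate, 50 replicates for the permutation
comparison, 20 seeds for noisy recovery, 6–20 strides per simulated
trial, and sufficiency sweeps on 8-stride trials with 0.02 mm sensor
noise ("noise near zero", so the SD-below-mean rule binds only through
the mean).  These sizes keep every check well under a minute or two while
leaving the measured quantities' uncertainty far below the decision
thresholds being verified.
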