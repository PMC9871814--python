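# Methods

`rootwave` quantifies the kinematics of treatment-triggered calcium waves
in primary roots imaged on a dual-flow microfluidic chip, and ships a
synthetic time-lapse generator whose ground truth encodes the dynamics the
pipeline must recover. This note documents the models, the defaults and
why, and what the synthetic validation does and does not establish.

## The imaging and wave model

**Geometry.** The visible root is a constant-radius tube around a
centerline polyline (tip first), closed by a hemispherical cap at the tip
and cut flat at the shoot end (the real root continues out of the field of
view). Rasterisation gives every root pixel an axial arclength `s` (µm,
0 at the tip apex, increasing shoot-ward) and a signed transverse
coordinate `r` (µm across the midline). Concentric fractional radii
(default 0.5, 0.8, 1.0) annotate stele / cortex / epidermis annuli; they
are labels only and play no role in the kinetics. Defaults: 3 mm of
visible root, 60 µm half-width — typical of a 9-day-old *Arabidopsis*
primary root seen by a low-magnification objective.

**Wave kinetics.** A front starting at arclength `s₀` at onset `t₀`
activates position (s, r) at

    t_a(s, r) = t₀ + Δt_long + Δt_trans

with `Δt_long = (s − s₀)/u` on the propagation side of a one-directional
front (positions on the other side never activate), `|s − s₀|/|u|` for a
bidirectional front, and, for one-sided treatments,
`Δt_trans = |r − r_flank|/v_T` (clamped to "never" beyond the midline when
the wave does not cross). The local fluorescence multiplier rises along a
logistic from 1 to the plateau fold A with 10–90% rise time τ, half-rise
exactly at `t_a`, and is hard-gated to 1 before `t₀`. The gate truncates
the logistic within ~|u|·τ of `s₀`; everywhere else the front shape is an
exact time-shifted copy, which is what makes half-max crossing an unbiased
front-time estimator. τ defaults to 5 s; the plateau is sustained for the
whole recording (no decay or refractory term), matching the sustained
signals the recordings show within their 3-minute window.

**Camera.** 568 frames over 180 s (Δt = 180/568 ≈ 0.3169 s — the
frame-count/duration pair is internally consistent, whereas a nominal
"3.3 fps" would give 574 frames), 2 µm/px, 16-bit counts, in-root baseline
B = 2000 ADU over a 200 ADU chamber background, Gaussian PSF of σ = 2 µm,
Poisson shot noise at unit photon-equivalent gain plus 20 ADU Gaussian
read noise. Pixel size is not reported for the original recordings;
2 µm/px puts a 1.2 mm root span comfortably in frame for a 5×/0.15
objective and is configurable. Rendering is chunked and exactly
reproducible: one camera seed → byte-identical stacks; replicate i of a
run with base seed b uses seed b + i.

**Presets.** The machine-readable preset table
(`rootsim/data/presets.json`) fixes one scenario per treatment × site ×
sidedness combination, with the reported speeds (6.8, 11.6, 5.9, 10.5,
9.4 + 5.2, ±11, 4.2, 14.2 µm/s), plateau folds (1.5, 2.5, 4.0; the
one-sided PEG tip case reads "0.5-fold higher" than its NaCl counterpart
additively, giving 3.0) and replicate counts (10 or 5). Signs follow
positive = shoot-ward. Tip treatments initiate at the apex (s₀ = 0, the
columella); differentiation-zone treatments at s₀ = 2300 µm, far enough
from the shoot-end cut that the shoot-ward branch of the bidirectional
case stays in frame. Transverse speeds for one-sided *tip* treatments and
the one-sided PEG differentiation-zone case are not reported; the presets
carry documented placeholder values (9.4 / 14 µm/s) that are never used as
recovery targets.

## Estimation

**Kymographs** sum pixel intensities (ADU) inside an ROI into 1-pixel
(configurable) bins along the chosen image axis, per frame — summation,
not averaging, so the per-frame total over bins equals the ROI pixel sum
exactly in integer arithmetic (a conservation identity the tests enforce
on random stacks). Bin membership is by pixel centre; partial-pixel
weighting was rejected to keep the identity exact. Display normalisation
is min–max (optionally percentile-clipped), per sample or global across
samples.

**Section traces** are the mean (plot-profile semantics, deliberately
distinct from the kymograph's sum) of pixels within a half-width (default
2 px) of five transects perpendicular to the root axis at arclengths
anchor + (0, 290, 580, 870, 1450) µm — Tip, ME1, ME2, ED1, ED2 — spacings
measured along the axis, so curvature does not compress them.

**Front detection.** Per kymograph position: 3-frame moving-mean
smoothing; baseline mean from the leading 10 s; front time = first
crossing of baseline + 0.5·(top − baseline), linearly interpolated
between frames. Half-max is the primary criterion because it is invariant
to the amplitude attenuation at the root edge and to display scaling; a
k·σ criterion is available. The estimator aims for per-position error
statistics that are *identical along the root*, because any systematic
position dependence of the front-time error tilts the fitted slope. Four
rules serve that goal:

* the top level ("peak") is a trailing-window mean (default last 10 s),
  not the max over all frames: the max is an extreme-value statistic whose
  upward bias grows with how long a position has been at plateau, which
  under noise makes early-activating positions cross late relative to
  late-activating ones. The max remains available as `peak_mode="max"`.
* positions whose dynamic range is below 4 baseline SDs report no front.
  The SD is taken from the **raw** (unsmoothed) baseline so that the
  smoothed peak of a signal-free position — a maximum over ~570 correlated
  samples, typically ≈ 2σ_raw — stays well under the gate; estimating the
  SD from the smoothed trace would let pure noise through. Likewise the
  baseline mean comes from the raw rows: a centred moving mean leaks the
  first post-onset frames into the baseline window near the initiation
  locus.
* crossings inside the trailing `edge_guard_s` (default 25 s = plateau
  window + ~3 rise times) are dropped: a position still rising near the
  end has both a biased half-max and a rise-contaminated plateau window.
* after a provisional slope fit, positions within
  `onset_guard_s × |provisional speed|` (default 5 s of travel) of the
  earliest-front position are excluded and the slope refitted: around the
  initiation locus the rise is truncated by the treatment onset rather
  than being a time-shifted copy of the travelling waveform. The cut is
  made in position space so noise cannot select which positions survive.

Analysis ROIs are trimmed to the full-width root body (the rounded tip cap
and a blur margin at either end are excluded; transverse ROIs also drop
rows within 20 µm of the flanks): partial transects have a different
summed amplitude and rise shape than body transects.

**Speed** is the Theil–Sen slope of position versus front time (µm/s),
robust to stalled positions and stray detections; the median is taken
over pairs at least 20 µm apart (for nearly coincident positions the
noisy time difference in the denominator can change sign, throwing those
pairwise slopes into the opposite tail). Its uncertainty proxy is the 95%
confidence band half-width / 1.96, and fit quality reports the inlier
fraction and median absolute residual. **Direction** follows the
slope sign (positive = shoot-ward). A V-shaped front-time profile with an
interior minimum is split at the minimum and both branches refitted;
opposite signs with both magnitudes above 1 µm/s classify as
bidirectional. Each branch must hold ≥ 3 points *and* ≥ 5% of detected
positions, so the handful of optically-bled bins just past the initiation
locus cannot fake a branch. **Transverse speed** applies the same chain to
a transverse kymograph built across the root width next to the initiation
locus; a symmetric (full-treatment) activation has no net transverse slope
and is flagged unresolved.

**Fold change** is the background-corrected peak/baseline ratio of a
smoothed section trace: because the chamber background enters both
numerator and denominator additively before subtraction, the noiseless
ratio equals the simulated plateau fold exactly, blur notwithstanding.

**Statistics.** Replicate summaries report mean, SD (n−1; undefined at
n = 1) and n. Condition comparisons use a two-way fixed-effects ANOVA
(section × treatment, statsmodels OLS/`anova_lm` typ-II) with Tukey HSD
pairwise comparisons at α = 0.05; every cell needs ≥ 2 replicates.

**Flow transit.** The microfluidic decoupling argument is closed-form:
v = Q/A_free with Q = 20 µL/min and an effective free cross-section of
48 900 µm² (back-calculated — the chamber cross-section is only drawn, not
stated; the ~0.4% mismatch between a 1.76 s fill of 12 mm and 6.84×10³
µm/s is printed rounding). The occlusion fraction is interpreted as a
free-cross-section fraction; the "root fills 50% of the channel length"
figure is metadata, not part of the velocity formula. A decoupling ratio
v_flow/v_signal above 100 flags advection as excluded.

## Validation design and its limits

No raw recordings are publicly deposited, so the reported speeds and folds
are validated as *parameter recovery*: each preset injects the printed
value as ground truth, and the pipeline must get it back — within 1% on
noiseless renders, and within two standard errors of the replicate mean
under default noise at the experimental replicate counts (10 or 5). The
acceptance script re-runs that recovery from scratch at the full study
conditions (55 videos of 568 frames; a few minutes of CPU).

What passing shows: the kymograph summation, front criterion and robust
slope are a consistent, unbiased estimation chain at realistic SNR, frame
rate and optics, including the awkward cases (bidirectional splitting,
one-sided transverse waves, late-activating positions). Because replicates
differ only by noise realisation, the between-replicate standard error of
the recovered speed is extraordinarily small (~10⁻⁵–10⁻⁴ µm/s), so the
two-standard-error check probes the estimator at the 10⁻⁵ relative level —
far beyond anything meaningful for real data, where between-root
variability dominates. Residual systematics at that scale (notably a
~0.02% inflation of the short shoot-ward branch of the bidirectional fit,
traceable to ratio-of-noisy-differences effects in the pairwise slopes of
a 57 s branch) are documented rather than tuned away. What it does not
show: performance on real recordings with root growth or drift during the
recording, uneven illumination, autofluorescence gradients, saturating
sensors, or wave kinetics that deviate from a constant-speed logistic
front (deceleration, oscillations, decay). The generator also renders a
2-D projection with a single Gaussian blur scale — no cylindrical optics
or depth attenuation — and treats tissue bands as labels, not as different
conductivities.

## Numerical choices and degenerate inputs

* Bin width < pixel size, ROIs leaving the frame, baseline windows longer
  than the recording, < 3 positions with fronts, non-positive corrected
  baselines, and unknown presets all raise errors naming the offence.
* Constant kymographs normalise to all-zeros with a warning (documented
  convention); constant traces have fold change exactly 1; instantaneous
  (flat) front profiles return direction `none` with an unresolved speed.
* Saturation above 1% of pixels logs a warning at render time; stacks
  clip to their bit depth after rounding.
* Theil–Sen ties: `scipy.stats.theilslopes` handles tied times; the
  degenerate all-equal-times case is intercepted beforehand.

## Problem sizes used in the checked-in validation

Unit tests run on an 800 µm root with truncated recordings (≲ 200 frames)
so the suite stays fast; the acceptance suite and `scripts/acceptance.py`
use the full study conditions (3 mm root, 568 frames / 180 s, default
noise, n = 10 or 5 replicates per preset) — the sizes at which the
recovery claims are made.
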