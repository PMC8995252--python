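# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `oculodce`. Problem sizes quoted below are the defaults of
the shipped tests and of `scripts/acceptance.py`.

## Signal model and T1 mapping

All signal modelling uses the spoiled gradient-echo (SPGR) steady state

    S = M0 · sin(α) · (1 − E1) / (1 − E1 · cos(α)),   E1 = exp(−TR / T1).

T1 and M0 are estimated from a multi-flip-angle series (defaults 2°, 5°,
9°, 15°, TR 7 ms) by ordinary least squares on the linearised form: plotting
S/sin α against S/tan α gives slope E1 and intercept M0(1 − E1). The
linearised fit is exact on noiseless data (verified to < 1e−6 relative over
T1 ∈ [100, 5000] ms) and is the method of record for this application; a
nonlinear refinement would change noise propagation but not the noiseless
solution, and is not implemented.

Fits with slope outside (0, 1), with a degenerate design, or with signals
that do not vary across flip angles are *flagged*, carry NaN, and are
excluded from all lesion summaries — visible failure instead of silent
clamping.

**B1+ correction.** Transmit inhomogeneity scales the achieved flip angle.
The default correction multiplies all nominal angles by one scalar, the
median relative B1+ over the lesion (`lesion-median` mode); a per-voxel
mode exists. For the small, near-isocentre lesions this package targets the
field is nearly constant over the lesion, making the two modes equivalent
(asserted as a test property for constant fields); the scalar mode matches
how the quantity is reported (a lesion-median percentage) and is robust to
noise in individual B1 voxels. B1 maps are consumed as fractions (0.91);
percent-style maps (median > 2) are rescaled automatically.

**Outlier filtering.** After fitting, a 3D median filter over the
26-connected neighbourhood runs *inside the lesion mask only*: each lesion
voxel is replaced by the median of itself and its in-mask, fit-OK
neighbours. Out-of-mask voxels never contribute — the vitreous T1
(~4000 ms) would otherwise bleed into lesion-edge voxels — and are never
modified. The filter is applied to the T1 map, not to the source volumes.

## Concentration conversion

Per voxel, S0 is the mean over the baseline (pre-bolus) frames; with the
baseline T1 from the map, the implied M0 follows, and each dynamic sample
is inverted for E1(t), hence R1(t) = 1/T1(t), through the full SPGR
relation (no linearised approximation). Concentration is

    C(t) = (R1(t) − R1(0)) / r1,   r1 = 3.4 L mmol⁻¹ s⁻¹.

Signal values beyond the SPGR saturation branch are non-invertible; those
voxel-timepoints are flagged NaN. Negative concentrations produced by noise
are *retained* for fitting (the noise is zero-mean in R1; clipping would
bias low-enhancement voxels).

The DCE flip angle itself is corrected by the same lesion-median B1+ factor
as the VFA angles before inversion.

## Arterial input function

No artery lies within the small ocular field of view, so a population AIF
is used: the standard mixed-Gaussian plus exponential/sigmoid population
model (Parker), with its published parameters exposed in
`kinetics.PARKER_AIF_PARAMS` and overridable. A measured or site-specific
AIF can be supplied as a two-column (time s, Cp mmol/L) text file and is
resampled onto the dynamic grid by linear interpolation. The AIF is
consumed as plasma concentration; no haematocrit correction is applied by
default.

## Tofts model and fitting

Tissue concentration follows the standard (two-parameter) Tofts model; the
extended model's plasma-volume term is deliberately out of scope. The
convolution is evaluated with the exact recursion for a piecewise-linear
Cp: over one interval dt with kep = Ktrans/ve,

    acc_{i} = acc_{i−1}·e^(−kep·dt) + ∫ (linear Cp segment)·e^(−kep·(dt−u)) du

with the segment integral in closed form (trapezoid in the kep→0 limit).
On a uniform time grid with scalar parameters the recursion collapses to a
discrete convolution with the kernel e^(−kep·dt·k), which is the fast path
used inside the voxel-wise fitter. Agreement with a 100×-oversampled
trapezoidal convolution is ≤ 0.1 % of the peak.

**Bolus arrival time.** For each of 25 candidate arrival frames
(consecutive integer shifts from frame 0), (Ktrans, ve) is fitted to the
first 40 timepoints of the median lesion concentration curve; the candidate
with the lowest residual sum of squares wins, ties going to the earliest. A
manual integer override is supported and recorded as "manual" in the run
manifest. Because the BAT is needed to finalise the baseline, the pipeline
runs two passes: a provisional baseline (all frames within the injection
delay, minimum 2) feeds the BAT search; the final baseline is then all
frames before BAT − 1 (minimum 2) and the conversion is repeated.

**Voxel-wise NLLS.** Bounded least squares (`scipy.optimize.least_squares`)
over (Ktrans, ve) with Ktrans ∈ [0, 5] min⁻¹, ve ∈ (0, 1], tolerances 1e−10,
at most 500 evaluations. Start points come from a 4×4 log-spaced coarse
grid whose model curves are precomputed once per fit run; the two best
cells seed the optimiser and the better solution wins. There is no
randomness anywhere in the fit. Voxels that do not converge, pin at a
bound, have fewer than 10 valid timepoints, or show no measurable uptake
(Ktrans ≤ 1e−6, where ve is unidentifiable) are flagged. Lesion summaries
(median, 25th/75th percentile, IQR, voxel counts) use fit-OK voxels only;
percentiles use the linear-interpolation definition throughout.

## Motion correction

Each dynamic frame is rigidly registered to the reference frame twice:

1. **Head step** — full field of view, rotation centre at the volume
   centre, run at reduced resolution (shrink 4/2, linear metric
   interpolation, 10 Powell iterations). Accuracy here is secondary; it
   provides the capture range.
2. **Eye step** — metric restricted to a spherical eye mask (globe radius
   + 2 mm margin), rotation centre at the eye centre, initialised by the
   head solution (shrink 2/1, 15 Powell iterations).

The composed transform is applied in one resampling (linear for images,
nearest-neighbour for masks), so each output frame is interpolated exactly
once. The reference frame defaults to index 49 (the 50th timepoint) for
series of ≥ 50 frames, else the middle frame; registering to the
high-resolution post-contrast anatomy instead is possible by passing it as
the fixed image to `register_secondary`, but is not the default.

Numerical choices, each adopted after phantom experiments at 1.25–1.5 mm
voxels and SNR 20:

- **Similarity metric: global correlation (`ncc`) by default.** Mutual
  information on the small masked region (~2000 voxels) repeatedly fell
  into local optima for gaze rotations ≳ 10°, with rotation errors up to
  30°; correlation recovered all simulated transforms within 0.3 voxel /
  1°. Correlation tolerates the global intensity scaling across the bolus;
  `nmi` and `mse` remain selectable (`nmi` is also used for cross-contrast
  secondary volumes such as the B1 map).
- **Optimiser: Powell with dense metric sampling.** Gradient-free, no
  learning rate, deterministic — identical results on every run.
- **Metric interpolation: B-spline** for the eye step. Linear metric
  interpolation left a systematic ~1–2° rotation bias at this resolution
  under noise.
- **Temporal-neighbour rescue.** Frames are processed outward from the
  reference; the eye step also tries an initialisation from the already
  solved temporal neighbour's eye transform (gaze holds between saccades)
  and keeps the candidate with the better final metric. This rescues
  pre-bolus frames, where intra-ocular contrast is low and the globe is
  rotationally near-symmetric. Failed registrations fall back to the
  identity (or the head solution) and are flagged; the run continues.

## The eye phantom

`PhantomSpec` describes a complete synthetic study: a spherical globe
(default radius 11 mm) with a wall-attached spherical-cap lesion (default
prominence 7.8 mm, basal diameter 14.5 mm — a medium-large tumour), lens
and papilla-like intra-ocular features, a bright scleral rim, and smoothly
textured orbital tissue outside the globe. Defaults put the lesion at the
cohort-typical values: T1 1122 ms (pigmented and unpigmented lobes 494 /
1464 ms in the two-lobe variant; vitreous 4000 ms), Ktrans 0.46 min⁻¹,
ve 0.22, lesion-median B1+ 0.91 on a smooth in-plane gradient field
(≈ 0.85–0.98 across the FOV), 125 dynamics at 2 s, bolus arrival at frame
5 (injection 6 s after scan start plus transit). An optional lognormal
intra-lesion Ktrans field (`lesion_heterogeneity`, default off) emulates
the strong intra-tumour spread seen clinically (IQR comparable to the
median); the sensitivity analyses below use σ = 0.5, since several
perturbation effects (notably frame shifts) act through spatial gradients
and vanish on a perfectly uniform lesion.

Enhancement is generated by running the analysis chain in reverse per
voxel: Tofts C(t) → R1(t) = 1/T1₀ + r1·C(t) → SPGR signal at the local
achieved angle B1·α. Motion then resamples each frame: the head transform
acts globally, the eye transform only inside the globe plus a 4 mm margin
— a rigid eye inside a static orbit. The registration mask (globe + 2 mm)
lies strictly inside that rigid region. Motion traces combine smooth
sinusoidal drift, blink-like translation spikes (1–2 frames) and step
changes of gaze, re-expressed relative to the reference frame and clipped
to the stated maxima (3 mm, 20°, the clinically observed extremes). Rician
noise (`|S + n₁ + i·n₂|`) is added after resampling, with σ expressed as a
fraction of the mean baseline lesion signal (0.05 = SNR 20); the same σ is
applied to the flip-angle series.

**What the phantom does not model:** view-sharing (TWIST) temporal blur,
k-space artefacts, coil-sensitivity shading, partial-volume mixtures beyond
grid discretisation, deformation of orbital tissue around the moving
globe, physiological AIF variability, and retinal-detachment compartments
(a long-T1 non-enhancing blob is available but off by default). Passing
the phantom tests therefore demonstrates the correctness and stability of
the analysis chain under the modelled effects, not performance on raw
scanner data.

## Error-propagation harness

`sensitivity_suite` reruns the quantitative chain (T1 fit → conversion →
Tofts fit, with the BAT frozen at the baseline run's value for
comparability) after modifying one intermediate:

- `b1_scale`: multiply the measured B1+ fraction by 1 ± m (grid: ±2 %, ±5 %),
  which shifts both the VFA angles and the DCE flip angle;
- `t1_shift`: add ±30 / ±60 ms to every lesion voxel of the fitted T1 map;
- `frame_shift`: translate two consecutive registered frames by one voxel,
  either "late" (the dynamic nearest 175 s) or "post_bolus". The
  post-bolus window is placed on the contrast inflow (default BAT + 4
  frames): at a 2 s dynamic interval the tissue curve is still ≈ 0 one
  frame after arrival, and only the upslope samples — which carry most of
  the Ktrans information — make the shift costly.

Rows report 100·(perturbed − baseline)/baseline for the median lesion
Ktrans and ve; zero-magnitude rows report exactly 0 by definition. On the
default heterogeneous phantom the suite shows the expected structure:
B1 +5 % → Ktrans +10 %, B1 −5 % → −10 %, T1 +30 ms → −3.6 %, responses
ordered by magnitude, and the post-bolus shift (−2 to −3.5 %) exceeding
the late shift (≈ +0.5 %). Which frames are shifted — registered, as here,
modelling residual registration error — is a design choice; shifting raw
frames would entangle the perturbation with the corrector.

## Problem sizes and determinism

Tests and the acceptance script run on a 48×42×20 grid at 1.25×1.5×1.5 mm
(a cropped orbital FOV holding the whole globe) with 252 lesion voxels;
motion experiments use 24–30 dynamics, kinetic-only experiments the full
125. These sizes keep a complete end-to-end run in seconds-to-minutes on
one CPU while leaving every spatial effect (masked filtering, masked
registration, mask propagation) non-trivial. All randomness flows from
explicit seeds: phantom texture and noise from `PhantomSpec.seed`,
Monte-Carlo repeats from per-repeat seeds; registration and fitting are
deterministic by construction, so identical configs reproduce bit-identical
parameter maps.

## Known limitations

- The standard Tofts model ignores the intravascular contribution; highly
  vascular lesions would need the extended model.
- The scalar lesion-median B1+ correction under-corrects lesions that span
  a strong B1+ gradient (large or peripheral lesions).
- The eye-inside-static-orbit motion model leaves a thin blend zone at the
  globe boundary; edge-of-globe voxels are less reliable, mirroring the
  partial-volume caveat for edge voxels in real data.
- Registration accuracy was validated down to SNR 20; heavier noise or
  signal dropouts (blinks during acquisition of central k-space) are not
  modelled.
- The BAT search assumes one global arrival frame per lesion; strongly
  delayed sub-regions would bias per-voxel fits near the arrival.
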