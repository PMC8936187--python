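# Methods

This note documents the models, parameter choices and numerical
conventions behind `octavd`, and what the synthetic phantoms do and do not
establish about real AS-OCTA data.

## Imaging model and pipeline order

The pipeline consumes already-sliced en face angiograms (episcleral or
full conjunctival-to-scleral slabs), one per eye × sector × visit, as 8- or
16-bit grayscale TIFF/PNG normalized internally to [0, 1]. Stages run in a
fixed order — stripe removal, denoising, vesselness enhancement, local
thresholding, density computation — because the vesselness filter is
contrast-normalized and must see stripe-free input, and the threshold
operates on the vesselness map, not the raw image.

### Directional FFT bandpass (preprocess)

The 2-D spectrum is multiplied by a mask that is the product of

* a radial passband with smooth Gaussian-CDF edges at `1/filter_large_px`
  and `1/filter_small_px` cycles/px (defaults 40 px and 3 px: structures
  larger than 40 px — illumination gradients — and smaller than 3 px —
  pixel noise — are attenuated; edge softness 5% of the cutoff); and
* a hard angular wedge of zeros around the axis that carries the stripe
  orientation. A full-width horizontal stripe is constant along x, so its
  energy lies exactly on the vertical-frequency axis; the wedge need only
  cover small deviations from that axis. `direction_tolerance_pct` is
  read as the percentage of frequency directions *tolerated*: the default
  90% zeroes the remaining 10% of the maximal 45° wedge, a 4.5° half-angle.
  We evaluated wider interpretations (a 40.5° wedge, and a Fiji-style
  Gaussian notch across the perpendicular frequency) and found both
  destroy enough genuinely horizontal vasculature to cap segmentation
  Dice near 0.7 on phantoms; the narrow wedge removes a pure stripe
  completely (it lies exactly on the axis) while sparing vessels.

The DC bin is always kept, so the mean intensity survives; every mask
value lies in [0, 1], so non-DC spectral energy is never amplified. The
filter is linear up to an optional final rescaling. The default rescale
mode **clips** to the input range rather than min-max stretching: a
stretch renormalizes even a signal-free frame to full contrast, which
would both re-amplify suppressed stripe residue and defeat any absolute
signal-quality measure downstream. `stretch` (the familiar autoscale
behaviour) and `none` remain selectable. Constant images pass through
unchanged. Frequency grids are centered for even and odd sizes alike; no
padding is applied by default.

### Denoising and vesselness (segment)

Speckle is attenuated with a 3×3 median filter (radius 1) followed by a
Gaussian of σ = 0.5 px; both steps are disabled by setting their
parameter to zero, and both use reflect padding so border vessels are not
eroded (this holds for every spatial filter in the package).

Vesselness is the classic 2-D Hessian-eigenvalue measure for bright
curvilinear structures. At scale `s` the Hessian is computed with
scale-normalized Gaussian derivative kernels (multiplied by `s²`), its
eigenvalues ordered |λ₁| ≤ |λ₂|, and

    V_s = exp(−R_B²/(2β²)) · (1 − exp(−S²/(2c²))),   R_B = λ₁/λ₂,
    S = √(λ₁²+λ₂²),  V_s = 0 where λ₂ > 0,

with the final map the pointwise maximum over scales. The input is
mean-subtracted first; this makes invariance to additive intensity
offsets exact despite the truncated derivative kernels' small nonzero
sums. Defaults: β = 0.5 (the canonical blobness weight), scales
{1, 1.5, 2, 2.5} px ≈ the radii of 30–75 µm episcleral vessels at the
15 µm/px transverse resolution of the assumed scanner (larger scales
produce halos that systematically inflate VD), and `c = "auto"` — half
the maximal Hessian Frobenius norm at each scale. Kernels are truncated
at 4σ.

A frame-level flow-signal floor (`min_signal`, default 0.07 in Hessian
norm units on [0, 1] intensities) runs before thresholding: because
auto-`c` normalizes contrast away, the ridges of *any* smooth noise field
would otherwise be amplified to full vesselness, and a frame containing
no vasculature at all would segment at ~37% VD. Frames whose maximal
multiscale Hessian norm stays below the floor are declared flow-free and
return an empty mask; on phantoms the measured maxima are ≤ 0.062 for
vessel-free frames and ≥ 0.086 for vascular frames, and frames above the
floor are processed bit-identically to a pipeline without the check. This
mirrors the signal-strength gating OCTA devices apply before reporting
densities.

### Local adaptive threshold

A pixel is vessel iff its vesselness exceeds the local background
statistic over a `threshold_window` (61 px) neighborhood plus
`threshold_offset` (0.025). The statistic is the **median** by default:
with vessels covering ~25% of a window, a local mean is pulled up by the
vessels themselves and clips their interiors, while the median stays
anchored to the background level (the plain mean remains available as
`threshold_method="mean"`). The window is ~10 vessel calibers so each
neighborhood samples both classes. Connected components smaller than
`min_object_px` = 15 px (8-connectivity) are removed; since despeckling
only deletes pixels, it can only lower VD.

### Vessel density (quantify)

`VD = 100·P/A`, computed in exact integer arithmetic before the final
division. Each sector is its own scan, so `A` is the whole frame
(optionally minus a configurable margin crop, default 0 — a 10 px crop
moves VD by < 1 unit on a uniform phantom). Dye-restricted VD counts only
vessel pixels inside a pre-aligned trypan-blue reference mask while
keeping `A` the full frame, so restricted ≤ unrestricted by construction
and the two share a scale; the dye-mask-area denominator is available as
an option.

## Sector design and statistics

Each operated eye contributes one implant sector and two fixed opposing
control sectors (superior-nasal → inferior + temporal; inferior-nasal →
superior + temporal; inferior-temporal → superior + nasal); the mapping
is total on the three protocol implant locations and anything else is an
explicit error. When the analysis sector must be chosen from an implant
arc, the candidate with the highest baseline VD is selected (higher
signal is more reliable), ties broken by the canonical sector order, and
the selection frozen across visits.

* **Wilcoxon signed-rank** (follow-up vs baseline, two-sided,
  follow-up − baseline differences): zero differences are dropped
  (classic treatment; Pratt's method is switchable), |differences| are
  midranked. Up to `exact_cutoff` = 15 informative pairs the p-value is
  exact — the full 2ⁿ sign-flip distribution of the positive-rank sum,
  which is symmetric about Σranks/2, so ties pose no difficulty — and
  beyond that a normal approximation with tie and continuity corrections
  (scipy) is used. The mean difference and its paired-t 95% CI are
  reported over all pairs, the conventional companion to the
  nonparametric p.
* **Friedman** (serial measurements): within-eye midranks, tie-corrected
  chi-square statistic with df = k−1 on complete blocks (incomplete eyes
  are excluded and counted). For small problems the p-value is the exact
  within-block permutation probability — permuting values within a block
  only permutes its ranks, so ranks are computed once and the tie
  correction is permutation-invariant; `auto` enumerates when k!ⁿ is
  affordable and falls back to the chi-square otherwise. A sampled
  permutation mode exists for validation; measured at n = 20, k = 3 the
  chi-square p differs from the permutation p by up to ~0.04 mid-range
  and the gap closes by n = 60.
* **serial_analysis** runs, per group (implant, control 1, control 2,
  controls ordered canonically within eye), the Wilcoxon at every
  follow-up visit and the Friedman across the visit set, pairing strictly
  within eyes. Significance is α = 0.05 with **no multiplicity
  adjustment**, and the JSON report says so explicitly.

The choice of Friedman visit set is configurable because visit-dependent
dropout (25 eyes through month 1, 16 at month 3, 13 at month 6) makes
"complete case" ambiguous; the default uses all visits present, i.e. the
strictest complete-case set.

## The phantom generator

The generator exists to make every stage falsifiable against known
ground truth; it emulates the *appearance* of en face AS-OCTA, not OCT
physics (no A-scan or decorrelation modelling, no 3-D volume, no
pathology).

* **Vasculature**: biased random-walk strokes stamped as disks, starting
  from border entry points (roots) and later sprouting from existing
  vessels, with per-step heading noise (`tortuosity` = 0.1 rad/step,
  giving a persistence length of ~100 px, comparable to the field of view
  — episcleral vessels are elongated and gently curved), width jitter
  within `width_range` = 2–5 px (30–75 µm at 15 µm/px), and Bernoulli
  branching (p = 0.03/step). Growth halts the moment the vessel-pixel
  fraction reaches `target_fraction` (default 0.25, matching ~25 VD units
  of episcleral plexus), so overshoot is bounded by one disk stamp and
  the truth VD is controlled to < 0.1 unit. An unreachable target fails
  loudly with the achieved fraction.
* **Rendering**: two-level image (vessel 0.75, background 0.15) → 0.7 px
  Gaussian PSF → unit-mean gamma speckle (shape 3; multiplicative, the
  standard OCT speckle statistic, so the expected image equals the clean
  render; `inf` disables) → additive full-width horizontal stripes on a
  random 8% of rows (amplitude ±0.25) → clip to [0, 1].
* **Cohort simulation**: per eye, an implant sector drawn from the three
  protocol locations, a persistent eye offset (SD 2.5), then per visit
  VD = visit mean + offset + measurement noise (SD 2.3) for the implant
  sector and both controls, clipped to [0, 100]. The defaults encode the
  observed operated-cohort trajectory: implant means
  (25.6, 24.7, 22.5, 22.7, 23.5) across (pre, week 1, month 1, month 3,
  month 6), controls (23.2, 23.0, 23.3, 22.8, 24.0), and dropout
  (0, 0, 2, 7, 3) leaving 25/25/23/16/13 eyes. The two SDs were chosen so
  the cross-sectional SD is √(2.5²+2.3²) ≈ 3.4, the observed value; the
  split between stable and per-visit variance is itself an assumption.
* **Determinism**: every generator takes an explicit seed; the cohort
  seed spawns per-eye substreams (`numpy` `SeedSequence`), so tables and
  images are bit-reproducible.

**What phantom results do not show.** The phantoms have piecewise-constant
vessels, stationary speckle, and stripes that are exactly full-width and
horizontal. Real angiograms add projection artifacts, depth-segmentation
errors, focal signal dropout, non-stationary speckle and partial-width
motion artifacts. Recovery of truth VD within ±3 units and Dice ≥ 0.8 on
phantoms therefore validates the implementation and its parameter scaling,
not clinical accuracy; on real data the defaults are starting points and
every parameter is exposed in the YAML config.

## Numerical conventions and edge cases

* Intensities float64 in [0, 1]; masks boolean; VD stored at full
  precision (1-decimal formatting is presentation only).
* Reflect (symmetric) padding everywhere; centered FFT frequency grids
  for even and odd sizes.
* Empty ROI or empty dye mask → explicit `ValueError` (VD undefined).
* All-zero paired differences → p = 1 with the informative-pair count 0
  flagged, rather than an exception.
* Degenerate (constant) images: bandpass passes them through; vesselness
  is exactly zero (auto-`c` guards against amplifying numerical noise of
  a flat Hessian).
* Exact-test cutoffs: Wilcoxon 2ⁿ enumeration to n = 15 (32768 sign
  vectors, vectorized); Friedman enumeration when k!ⁿ ≤ 20000.
* Sector VD values enter the tests at full precision; tie-breaks in
  index-sector selection follow the documented canonical sector order.

## Problem sizes used in validation

The test suite and the acceptance script run segmentation on 304×304
frames (the conventional en face grid; the field of view is not
standardized, so this is a convention, not a measurement), cohort
simulations at the study's 25 eyes with its dropout schedule, power
estimates over 200 simulated cohorts and type-I error over 500. These
sizes give ±1% Monte-Carlo precision on a 5% rejection rate while keeping
a full validation run in tens of seconds.

## Known limitations

* The wedge interpretation of the stripe filter's "tolerance of
  direction" is one of several plausible readings of the tool setting it
  mirrors; the axis, width and geometry are configurable precisely
  because the setting is underdetermined.
* Dense vascular clusters (vessels merging into sheets) are the hardest
  case for a Hessian line detector; Dice against truth degrades as
  networks become blob-like.
* The Wilcoxon/Friedman implementations assume exchangeability within
  eye; no covariate adjustment (IOP, medication count) is provided.
* No registration: serial scans are assumed to image the same sector
  region; dye masks are assumed pre-aligned.
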