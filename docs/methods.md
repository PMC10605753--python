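# Methods

## The measurement problem

NemaFlex-type devices measure C. elegans neuromuscular strength by
imaging an adult crawling through a lattice of deformable PDMS
micropillars. Each pillar is a stubby cantilever clamped at the chamber
floor; when the worm pushes one sideways, the lateral displacement of the
pillar's imaged top circle reports the contact force. A recording is
summarised per animal as **f95**: in every frame the pillar with the
maximal deflection is found, deflections are converted to forces, and f95
is the 95th percentile of the per-frame maximal-force distribution.

This package implements that measurement chain — synthetic recording
generation with exact ground truth, pillar localization and deflection
quantification, worm morphometrics, force conversion and cohort
statistics — as a tested pipeline. No raw videos from the flight
experiment are publicly deposited, so the only directly reproducible
published numbers are the group summary statistics; everything upstream
is validated with render-then-measure experiments against known ground
truth.

## Pillar mechanics

The pillars have diameter comparable to their height (d/L ≈ 0.55 at the
defaults), so Euler–Bernoulli bending alone understates their
compliance. We use the Timoshenko clamped-cantilever model with a point
load at height *a* and the displacement read at the pillar top, where
imaging measures it:

    δ_top = F · [ a²(3L − a) / (6 E I) + a / (κ G A) ],

with I = πd⁴/64, A = πd²/4, G = E/(2(1+ν)) and the circular-section shear
coefficient κ = 6(1+ν)/(7+6ν). Units are µm, µN and MPa, so compliance is
in µm/µN directly. The closed form is verified in the tests against an
independent numerical integration of the Timoshenko beam equations
(agreement to 1e−6 relative) and force/deflection conversions round-trip
to 1e−9.

The load height is *a* = D/2 clamped to L: the worm lies on the chamber
floor, so its centerline — the nominal line of action — sits one body
radius above the base. This is where the "adjustment for body diameter"
enters: compliance changes by roughly 7% per µm of *a* at the default
geometry, which is why the pipeline measures each animal's mid-section
diameter and uses it in the conversion. Consequences: a diameter error of
0.3 µm moves every force by about 1%, so the morphometrics stage carries
a subpixel-accuracy requirement, not merely a classification one.

Parameters (all config-exposed; defaults in `DeviceGeometry`):

| parameter | default | basis |
|---|---|---|
| pillar height L | 80 µm | device as fabricated |
| chamber depth | 100 µm | device as fabricated |
| pillar diameter d | 44 µm | not printed for the flown device; chosen geometrically consistent with the stated heights and the 44–48 µm worm diameters |
| lattice pitch | 120 µm | same basis as d; leaves a 76 µm gap that a 45 µm worm can thread |
| Young's modulus E | 2.0 MPa | literature-typical for Sylgard 184 10:1 cured ~2 h at 70 °C |
| Poisson ratio ν | 0.499 | nearly incompressible elastomer |
| pixel size | 1.6 µm/px | 4× magnification |
| frame rate | 5 Hz | as recorded |

Out of model: nonlinear large-deflection mechanics, pillar–pillar
coupling, substrate tilting/warping corrections and elastomer
viscoelasticity. The force model is isolated in `geometry.py` so a
different calibration can be swapped in.

## Synthetic recordings

The generator's purpose is pipeline validation, so forces are
*prescribed*, not derived from worm-body mechanics: every quantity the
pipeline should recover is known exactly.

- **Trajectory.** The body is laid along a closed elliptical patrol path
  inside the field of view (minute-long recordings must stay in frame)
  with a sinusoidal undulation normal to the path; the head advances at
  the gait speed (default 120 µm/s, amplitude 25 µm, wavelength 450 µm —
  realistic crawling scales) and each frame's centerline is resampled to
  the exact body arc length.
- **Contacts and forces.** A pillar is contacted in a frame when its
  center lies within one worm radius of the centerline. Contacted pillars
  draw independent log-normal force magnitudes (median 10 µN, log-SD 0.3
  by default), directed along the local body normal. With a handful of
  contacts per frame this puts per-recording true f95 near 20 µN,
  matching the reported strength scale. Per-frame maxima and the true
  f95 are recorded as ground truth.
- **Rendering.** 8-bit grayscale frames: bright background (level 200),
  pillars as radially shaded dark disks (center depth 140, intensity
  rising toward the rim, as a slightly defocused pillar top appears)
  drawn at reference-plus-deflection positions with sub-pixel
  anti-aliasing; the worm as a dark soft-edged tube with an elliptical
  taper over the last 60 µm of head and tail (a full-width end cap would
  make the body read one diameter too long) and darker egg-like
  inclusions mid-body for gravid adults. The body is excluded from a
  ~2 px collar around every pillar footprint — the worm bends around
  pillars, it cannot overlap them. Gaussian camera noise (SD 5) and an
  optional linear illumination gradient complete the frame.
- **Cohorts.** The default design mirrors the flight study: groups
  wt/dys-1 × ground/flight with n = 30/30/25/29, per-group body sizes
  drawn from the published means ± SD, and per-group force scales
  proportional to the published f95 group means (flight/ground ratios
  0.833 for wt, 0.666 for dys-1). Each animal also receives a mean-one
  log-normal strength factor with CV 0.25, reproducing the published
  between-animal spread (SD/mean ≈ 0.25).

What the generator does **not** emulate: photorealistic optics, worm
self-occlusion and coiling, sustained isometric pushes (forces redraw
every frame), egg-laying, debris, illumination flicker, or focus drift.
Passing tests therefore demonstrate that the measurement chain is
correct and precise under controlled conditions — not that it is robust
to every artifact of real microscopy.

## Pillar tracking

- **Reference lattice.** Candidate dark disks are detected per frame
  (threshold + connected components with a size/roundness screen),
  clustered across frames, and localized to subpixel precision. The
  reference (undeflected) center of each pillar is the *mode* of its
  per-frame positions, found by mean-shift seeded at the densest
  observation. A plain temporal median is not robust here: when the worm
  repeatedly pushes a pillar in a consistent direction the median drifts
  toward the deflected cluster, while at-rest localizations form a tight
  cluster whose spread is just the localization jitter. Pillars detected
  in fewer than 20% of sampled frames are flagged invalid. A rigid
  square lattice (pitch, orientation, origin) is least-squares fit to the
  valid centers; off-lattice stragglers are dropped and a residual above
  a quarter pitch rejects the recording as not a regular arena.
- **Localization.** Two stages. First an iterated intensity-weighted
  centroid of the inverted image in a circular window of one pillar
  radius, baseline-subtracted at the window's 10th percentile; a window
  with less than 25 grey levels of 10–90 percentile contrast is declared
  featureless (occluded pillar) and returns a missing value. Second, a
  Gauss–Newton photometric alignment against the recording's own mean
  pillar appearance (template averaged from re-centred patches, with
  per-patch gain and offset estimated jointly so local illumination
  cannot bias the fit). The template pass roughly halves the centroid's
  noise — about 0.02–0.04 px RMS at 8-bit noise SD 5 — without assuming
  any analytic intensity profile. Each pillar's displacements are then
  re-referenced to its own at-rest mode so constant template
  misalignment cancels; a pillar whose apparent rest offset exceeds half
  a pixel is left untouched (it may be genuinely held deflected).
- **Noise floor.** Estimated per recording from never-contacted pillars
  (those whose 95th-percentile displacement stays within 3× their median
  displacement — the signature of pure jitter, for which that ratio is
  ~2). The floor is 4× the median of those pillars' median jitter;
  displacements below it are zeroed. The multiplier 4 is set by a
  false-positive budget: with ~50 pillars per frame, the per-frame
  probability that any noise excursion clears the floor must stay below
  1%, which needs ≈ 4.2 jitter SDs; 4× the median magnitude of a
  Rayleigh-distributed jitter is ≈ 4.7 SDs. A 3× floor (≈ 3.5 SDs) lets
  ~9% of worm-free frames through and was rejected for that reason.
- **Coordinates.** Pixel coordinates are 0-based, x = column, y = row,
  with pixel centers at integer coordinates; physical µm via the pixel
  size. Stated because off-by-half conventions dominate subpixel errors.

## Morphometrics

Per analysed frame: Otsu threshold, excise pillar disks, close with a
pillar-radius kernel (a bite can sever the outline entirely), keep the
largest component within [0.3, 3]× the expected worm area, and return it
with pillar interiors excluded. For measurement the bites are re-closed;
the centerline is the skeleton's longest geodesic path (double-sweep
Dijkstra over the skeleton graph), smoothed to remove the 8-connected
staircase that otherwise inflates arc length by ~8%. Body length adds a
tip correction found from the intensity itself: the half-contrast
crossing along the outward end direction (the skeleton stops short of —
or, after bite-healing, can overrun — the true tip). Mid-section
diameter is measured at stations spanning 40–60% of arc length
(mid-section = arc-length midpoint) from subpixel half-contrast crossings
of intensity profiles normal to the centerline, skipping stations too
close to a pillar; the mask distance transform is only a fallback. The
subpixel profiles matter: binarised-mask widths quantize at whole pixels
(1.6 µm), which through the contact-height adjustment would move forces
by several percent. Reported values are medians across analysed frames
(default 8 per recording), robust to occasional bad segmentations.
Adults are flagged when length ≥ 900 µm (configurable; no number is
published for the classification) *and* egg-like dark inclusions are
found inside the body.

## Strength statistics

f95 uses linear interpolation between order statistics (the "type 7"
convention, position h = 0.95(n−1)+1): the convention is fixed and
documented because at 300 frames the choice moves f95 at the 0.1 µN
level. A floor of 20 usable frames is required. Group comparison:
sample mean ± SD (n−1), Shapiro–Wilk normality per group (advisory only
— reported, never used to switch tests), two-way ANOVA on strain ×
environment with Type II sums of squares (the standard choice for the
unbalanced 30/30/25/29 design without interaction emphasis), and Tukey
HSD over the four groups. Significance stars follow the source figures'
own mapping — * p<0.05, ** p<0.01, **** p<0.001 — reproduced as printed
even though four stars conventionally mean p<0.0001.

Percent declines are reported at one decimal by truncation toward zero.
Truncation, not rounding, is the convention under which the published
group means reproduce *all four* printed decline figures exactly (16.6,
33.4, 5.5, 7.9; rounding would give 16.7 and 5.6 for two of them). The
untruncated value is available via `decimals=None`.

## Problem sizes used in tests and the acceptance script

Study-scale recordings (1920 × 1080 px, 300 frames, 114 animals) are the
generator defaults, but re-rendering that volume for every check would
be wasteful. The validation runs use a quarter-size field of view
(640 × 480 px) at the identical pixel scale, pillar geometry and noise
level, with 24 s (acceptance script, full 30/30/25/29 cohort) or 30 s
(tests, 5 animals per group, three seeds) recordings. Nothing in the
measurement chain depends on the crop; the worm simply patrols a smaller
ellipse. Accuracy at these sizes: reference centers recover to
~0.02 px RMS, per-animal f95 to a median ≈ 1–2% relative error with
~95% of animals within 5%, and estimated cohort declines land within
about one percentage point of the declines realized in the ground truth.

One reading of per-animal agreement deserves a note: with measurement
noise of SD ≈ 1.6% per animal, the *maximum* error across a hundred
animals will occasionally exceed 5% even though the typical animal is
well inside; the end-to-end checks therefore require the median animal
within 5% and at least 90% of animals within 5%, per run.

## Known limitations

- The force calibration of the physical device (the exact model relating
  deflection to force, including any substrate-warping correction) is
  not published; the Timoshenko model here is a defensible stand-in and
  is isolated behind one module.
- Whether f95 should be further normalized by a power of body diameter
  beyond the contact-height adjustment is ambiguous in the source; the
  pipeline reports raw f95 alongside the measured diameter so either
  convention can be applied downstream.
- The tracker assumes pillars are at rest in a reasonable fraction of
  frames; a pillar held deflected for essentially an entire recording
  would bias its reference toward the deflected position.
- Real-microscope artifacts (drift beyond a rigid lattice, vignetting,
  debris) are out of scope; `analyze` will process real TIFF stacks but
  has only been validated on synthetic ones.
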