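# Methods

This note documents the models, defaults and numerical choices behind
`figground`, what the synthetic scenes do and do not emulate, and the
known limitations.

## Scene model and data hygiene

All stages operate on *scene bundles*: co-registered rasters of motion
speed (deg/s), motion direction (deg; 0 = rightward, 90 = upward,
counter-clockwise), radial distance (m) and per-pixel labels (sky = 0,
figure ids 1..K, ground = 255), with a JSON metadata sidecar. Rasters are
`(row, col)` indexed; the angular position of a pixel relative to a
reference is `((col - ref_col)·dpp, (ref_row - row)·dpp)` so +x is right
and +y is up, consistent with the direction convention. Missing values
are NaN; sky pixels are missing for motion and distance everywhere.

Two validity rules apply throughout:

* **Noise floor.** Speeds at or below 0.5 deg/s are censored — motion
  estimators register spurious motion up to ~0.67 deg/s on static frames
  (99th percentile ~0.096 deg/s), so only strictly faster motion is
  treated as measured. The cut is strict (`> 0.5`).
* **Border buffer.** Pixels within 5 px (Chebyshev distance, i.e. a
  square structuring element — the standard morphological dilation) of
  any label border are excluded, to keep figure and ground statistics
  uncontaminated by boundary pixels. Implemented as a min/max filter
  disagreement, which is brute-force checkable.

Bundle I/O uses single-channel 32-bit float TIFFs, an 8-bit paletted PNG
for labels, and a JSON sidecar; the round trip is lossless to float32
precision and validated (missing channels and undeclared label values
raise).

## Synthetic scenes: what is emulated

The generator reproduces the *structure* of annotated outdoor
motion/distance recordings, not their appearance:

* **Layout.** A sky band (top 10% of rows), 1–3 figures as smooth
  closed-contour blobs (low-frequency radial perturbation, radius 3–8
  deg) that never overlap each other (each figure stays 4-connected),
  and ground everywhere else.
* **Ground motion.** 70% of ground pixels are static (speed drawn below
  the 0.5 deg/s floor — censored, not zero). Moving ground pixels draw
  log10 speed from a normal truncated at the floor (median ≈ 1 deg/s,
  σ = 0.45 log units) — wind-blown vegetation — except for a 15% share
  drawn from the *figure* speed distribution, standing in for animate
  objects not labelled as figures and moving shadows, which real ground
  regions contain. Ground directions are per-pixel draws from an
  equal-weight von Mises mixture at 0°/180° with κ = 1 (weak horizontal
  bias).
* **Figure motion.** Figures move rigidly: a per-figure static indicator
  (probability 0.5 — buildings, parked objects, resting animals), and
  for moving figures one base log-speed per figure (median ≈ 20 deg/s,
  between-figure σ = 0.35 log units, truncated at the floor) plus small
  per-pixel log jitter (σ = 0.05). One direction per figure from the
  0°/180° mixture with κ = 4 (strong horizontal bias), with tight
  per-pixel jitter (κ = 50). Rigid motion is what makes each sRF's
  figure cluster near its own speed maximum, and per-figure coherence is
  what the circular-variance comparison must detect.
* **Depth.** Ground distance follows a hyperbolic ground-plane ramp from
  3 m at the frame bottom to 50 m at the horizon (distance ∝ 1/elevation,
  as for a real ground plane). Each figure sits at half the local ground
  distance (`figure_depth_offset = 0.5`) with centimetre-scale jitter.
  This yields the bimodal global distance distribution with figures
  nearer.
* **Saliency.** A luminance channel (smooth ground noise; per-figure mean
  offsets; bright sky) feeds a stand-in saliency model: local intensity
  variance over a 7×7 window. Only the induced median split into
  fixation candidates matters downstream; the stand-in gives figures a
  mild salience advantage (via their boundaries and mean-luminance
  contrast), matching the mild figure bias of bottom-up saliency models
  on real scenes. Figure texture is deliberately *not* made more salient
  than ground texture.

**Recoverable ground truth.** When `fg_logspeed_offset` is configured,
the figure location parameter is solved (Brent root-finding on the
truncated-normal mean, including the fast-ground mixture term) so that
the population mean log10 speed of valid figure pixels exceeds that of
valid ground pixels by exactly the configured offset. This is the truth
that parameter-recovery tests check. Because sRFs within one scene share
per-figure base speeds, recovery is assessed on per-scene means with a
scene-clustered standard error — scenes, not sRFs, are the independent
unit.

**Not emulated:** photorealistic imagery, actual frame sequences and
motion estimation, self-motion/parallax fields, pursuit gain < 1,
vertical disparity, head motion/VOR. Passing tests therefore show that
the *pipeline* recovers configured structure and reproduces the
qualitative figure-ground regularities under these conditions — not that
any particular real-world dataset carries them.

## Gaze simulation

* **Fixation candidates** are the pixels at or above the median salience
  (ties enlarge the set). Each sRF draws its fixation uniformly from the
  candidates inside an annulus at distance `diameter × (1 ± 0.1)` from
  the sRF center — receptive-field size roughly matches eccentricity in
  MT, and the ±10% tolerance makes the rule testable; it is
  configurable.
* **Pursuit.** The observer is assumed to track the fixated point
  perfectly; the fixation's world motion vector is subtracted from every
  pixel's motion. If the fixated point's world speed is at or below the
  0.5 deg/s detection threshold (the same threshold as motion validity),
  the eye is stationary. A global toggle removes pursuit entirely
  (stationary-eye control). Only world speeds are thresholded; retinal
  (post-subtraction) speeds are not re-censored, but retinal speeds
  below 0.01 deg/s are floored before taking log10, since perfect
  pursuit can null a tracked region's motion exactly.
* **Vergence/disparity.** Distance maps are radial distances from the
  cyclopean origin (as from a laser range scanner); pixels are first
  reconstructed to Cartesian `[x y z]` via azimuth/elevation
  (`x = r cos(el) sin(az)`, `y = r sin(el)`, `z = r cos(el) cos(az)`),
  then horizontal disparity is computed from the two eyes' viewing
  geometry with interocular separation 6.2 cm; crossed (near) positive.
  Only horizontal disparity is computed. The implementation preserves
  the exact cancellation of fixation terms: relative disparity between
  two points is fixation-invariant to ~1e-12 deg in double precision.

## Receptive-field sampling

Apertures are circles (pixel-center-in-circle membership) of diameter
2.5, 5, 10 or 15 deg, placed uniformly such that the full circle is
in-bounds. Acceptance applies, in a fixed order so reject reasons are
reproducible: (1) invalid fraction ≤ 0.5 over aperture pixels (sky,
sub-threshold motion, missing distance); (2) figure fraction ≥ 0.25 and
(3) ground fraction ≥ 0.25, both computed over aperture pixels outside
the border buffer; (4) a fixation candidate must exist in the
eccentricity annulus. Ground means every non-figure, non-sky, non-buffer
aperture pixel. No cap is placed on the number of distinct figures per
aperture. Rejection sampling continues until 200 samples per diameter
(800 total); the run aborts with diagnostics if the acceptance rate
stays below 5×10⁻⁴ after 4000 proposals.

## Statistics

* **Region summaries.** Per sRF: `s` = mean log10 retinal speed over
  motion-valid pixels; `v` = circular variance (1 − mean resultant
  length, in [0, 1]); `d` = mean disparity over pixels with finite
  disparity. Regions with no valid pixels yield NaN and drop out of that
  feature's analysis.
* **Tests.** One-sample t (two-sided, against 0) with Cohen's D =
  mean/sd; one-way ANOVA with η² = SS_between/SS_total and Tukey HSD
  pairwise comparisons (studentized-range CIs; pairwise Cohen's D uses
  the two groups' pooled sd); Wilcoxon rank-sum with effect size
  r = |z|/√N; Rayleigh test with z = nR̄² and the standard
  small-sample-corrected p approximation; a two-sample Kuiper test
  (V = D⁺ + D⁻, rotation-invariant, asymptotic p with the Stephens
  finite-sample correction) implemented in-package and cross-checked
  against a brute-force CDF-difference scan; exact (Clopper-Pearson)
  binomial CIs for sign proportions, computed from beta quantiles.
  Significance threshold 0.05 throughout.
* **Ratio curves.** Features: relative speed (per-sRF min-max
  normalization to [0, 1] after trimming outside the 1st–99th
  quantiles; degenerate ranges map to 0.5 with a warning), relative
  direction (rotated so the sRF's dominant direction — the mode of a
  50-bin circular histogram, ties to the lower edge — sits at 0°), and
  raw disparity (shared bins spanning the pooled 1–99% range). Per-sRF
  relative frequencies on 50 linear bins are averaged across sRFs,
  converted to densities, and the per-bin figure/ground ratio is formed
  (missing where the ground density is zero). 95% CIs are percentile
  bootstrap (default 1000 replicates) resampling whole sRFs.

## Population model

50 neurons, Gaussian tuning over log10 speed with σ = 1 log unit and
peak rate 1, preferred speeds uniformly spaced over [−2.5, 4.0] log10
deg/s. The range is deliberately wide: a response-weighted-average
decoder on a truncated lattice is biased toward the lattice center by
the missing tail mass (a truncated-normal mean shift), and with σ = 1
that bias exceeds half a lattice spacing for stimuli closer than ~2.4σ
to an end. The default stimulus band (8 log-spaced figure speeds over
1–40 deg/s, the regime where the fast-speed bias is observed
empirically) sits ≥ 2.4σ inside both ends, keeping decoding error below
half a lattice spacing; stimuli near the ends are flagged rather than
silently decoded. Decoding averages preferred *log* speeds and
exponentiates (consistent with log-spaced tuning); linear-domain
decoding is available behind a flag. Ground speed is `s_f` scaled by a
uniform factor in [0.3, 0.8].

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; dataset generation spawns
per-scene child seeds from the master seed and logs them in a manifest.
The default study uses 30 scenes of 256×256 pixels at 42°×42° field of
view and 800 sRFs (200 per diameter) — sizes chosen so a full run
completes in about a minute on one CPU while keeping ≥ 20 independent
scenes behind every clustered standard error. The acceptance script
reruns the study (pursuit on), the stationary-eye motion control, and
the decoding experiment from a single seed.

## Known limitations

* Circular variance is reported unitless (it is a unitless quantity in
  [0, 1]).
* The rank-sum effect size r = |z|/√N is one standard reading of the
  rank-biserial family; published rank-sum statistics from large pixel
  samples are often U/W statistics and are not interpreted here.
* Percentile-bootstrap ratio CIs undercover slightly (a few percent) at
  small sRF counts; bins within one curve are correlated, so per-curve
  bin coverage fluctuates around the nominal level.
* The saliency stand-in ignores motion- and depth-driven salience; the
  generator contains no self-motion, so eccentricity-dependent effects
  here reflect aperture geometry and pursuit only.
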