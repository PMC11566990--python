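# Methods

This note records the measurement conventions, the generative model behind
the synthetic scenes, the numerical choices, and what the tests do and do
not establish.

## Coordinate and boundary conventions

Images are indexed 0-based, row-major (y, x), with pixel centers at integer
coordinates; polygons and bead centers live in the same frame.  Physical
calibration is carried as µm per pixel (default 0.1).

All radial statistics use a **star-convex per-ray boundary**: the cell
contour is represented as a boundary distance R(θ) from the centroid on a
720-point angular grid, and each ray is normalized so its own boundary
crossing sits at 100%.  This matches clock-scan semantics for non-circular
cells; a single equivalent radius would mis-assign boundary-hugging signal
on elongated cells.  Non-star-convex contours are resolved to the
outermost crossing with a warning.

### Segmentation

The boundary channel is smoothed (Gaussian, σ = 1 px), thresholded by Otsu,
hole-filled, and the largest component kept — a reproducible substitute for
the manual ROI tracing common in practice.  Two refinements:

* **Cortical-actin ridge refinement.**  Cortical actin is a ridge, not a
  filled region.  Thresholding a ridge places the binary boundary at the
  ridge's *outer foot*, ~2–3 px outside the true cortex, which inflates
  every inside/outside statistic (by up to ~15 percentage points for
  bead-antigen cells, whose outside antigen lies within a few pixels of
  the boundary).  When the boundary channel is actin, the per-ray radius
  is therefore refined to the intensity peak along each ray (parabolic
  sub-pixel fit within ±5 px of the mask boundary), recovering the ridge
  center line.
* **Bead-window exclusion.**  The actin cup around an attached bead would
  otherwise bulge the cell contour at the contact site.  The angular
  window facing each detected bead (half-width `asin(1.35 r_bead / d)` +
  3°) is excluded and bridged by periodic linear interpolation — the
  algorithmic equivalent of a human tracing the cortex smoothly through
  the contact.

The nucleus is segmented by Otsu within the cell mask on the mid plane;
for stacks, the plane maximizing the thresholded nucleus area is used and
recorded.  Beads are found by normalized matched-filter correlation with
a disk template (peak threshold 0.6, duplicate suppression within one
radius).

### Radial profile and region fractions

Intensity is sampled by bilinear interpolation at the midpoints of 120
1%-bins along each of 360 rays (out to 120% of the per-ray radius).  The
fraction-of-total distribution weights each sample by the polar area
element (ρ·R(θ)²), so a spatially uniform signal reproduces annulus areas
exactly: outer-quarter annulus = 43.75%, thirds = 1/9 : 3/9 : 5/9.  Bins
that fall outside the image are flagged absent (NaN mean), not zero.  When
a cut (1/3, 2/3, or the peripheral cut) falls inside a bin, the bin's mass
is apportioned by the quadratic sub-bin weight; ties at bin edges go to
the lower bin.

The inside/outside split is computed on the pixel grid (not by ray
sampling): each pixel is classified by ρ = r / R(θ); ρ ≤ 1 counts inside
(contour-coincident pixels inside by convention), 1 < ρ ≤ 1.2 outside.
"Peripheral quarter" is interpreted as the outer 25% of normalized
*radius*, not of area — the area interpretation is available by changing
the `cut` argument.

**Background.**  The operator subtracts a constant background (default 0,
per-call configurable).  The batch pipeline and the acceptance script use
`background="auto"`: the median intensity outside 125% of the cell radius.
Additive camera background otherwise biases the inside share toward the
area ratio of the two regions (≈ +6 percentage points for the knockout
bead condition, whose inside signal is scarce).  Subtraction is *not*
clipped at zero, so zero-mean noise cancels in the sums instead of
rectifying into a positive bias.

### Quadrant score and interface ROI

The quadrant region is the disk of 1.2 × bead radius around the bead
center (margin included because cup fluorescence hugs the bead rim; the
margin is a parameter).  Sectors are 90° each, the proximal sector
centered on the bead→cell-centroid axis; ties on sector boundaries go
counter-clockwise, and the four sectors partition the region exactly.
Note the cell's own cortical actin enters the proximal sector when the
bead rests on the surface; this offsets all conditions equally and cancels
in the clearance index (proximal share at first minus last timepoint).

The interface rectangle has width R_eq/2 (a quarter of the cell diameter,
the only dimension stated by the figure scheme it follows); its length is
taken as the bead diameter so the ROI spans the contact, and it is
centered midway between the bead center and the nearest contour point,
long axis along the bead→cell axis.  Length and placement are parameters.

### Colocalization, ratios, kinetics

Pearson uses no thresholding; multi-plane input pools ROI pixels across
planes (per-plane averaging is available behind a flag).  Constant input
is flagged undefined, never reported as 0.  Manders defaults to
per-channel Otsu within the ROI, since reference thresholds are rarely
reported; fixed thresholds can be passed.

The nuclear translocation ratio is nuclear MFI / whole-cell MFI on the
nucleus-area-maximal plane.  Surface kinetics use the per-timepoint
*median* across cells (robust to the log-normal tail of flow-style
intensities), background-subtracted and normalized to t = 0; values
outside [0, 100] are reported raw with a warning.

## The synthetic scene model

Each scene is one cell: a disk of radius 3.5 µm (0.1 µm/px) perturbed by
three low-order sinusoidal boundary modes (orders 2, 3, 5; total relative
amplitude 0.06) — star-convex by construction.  Channels:

* bright field: filled soft-edged disk (plus the bead, when present);
* actin: Gaussian ridge (σ = 1.5 px) on the boundary plus faint cytoplasm,
  plus the bead cup: a radial Gaussian on the bead rim whose angular mass
  is a von Mises mixture (κ = 8) moving from the cell-proximal pole to the
  distal pole as `cup_clearance` goes 0 → 1;
* nucleus: soft disk of radius R/2 (25% of cell area), slightly off-center;
* antigen: Gaussian puncta (σ = 2 px, truncated at 4σ so placement can be
  made exactly interior).  Inside puncta sit at normalized radii drawn
  from Beta(2,2)·0.95 ("central", the control phenotype), Beta(6,2)·0.95
  ("peripheral", the knockout phenotype), area-uniform, or a narrow ring;
  outside puncta are uniform on [1.0, 1.2].  The relative gain of the two
  populations is solved so the intensity split across the true contour
  equals `antigen_inside_fraction` exactly (pre-noise); radial ranges are
  shrunk/shifted automatically when boundary spill makes an extreme
  fraction unreachable.  Total antigen intensity is fixed
  (`antigen_total_intensity`), so intensity is conserved to rounding;
* signal (NF-κB): uniform over the cell with nuclear enrichment
  (1 + ν · nucleus), ν = `nuclear_fraction_param`;
* endosome/lysosome: independent puncta fields; the designated coloc
  partner is re-blended against its partner channel by empirical
  orthogonalization so the pre-noise pixelwise Pearson within the cell
  equals `coloc_rho` exactly;
* bead: soft disk resting on the surface (center at boundary + bead radius
  + 1 px along a random angle).

Noise is Poisson at a photon scale (default 50 expected counts per grey
level) plus Gaussian background (mean 5, sd 2), then rounding to integer
grey levels so 16-bit TIFF round-trips are lossless.  All realized
quantities (inside fraction, quadrant percentages, nuclear ratio, coloc ρ,
true masks, bead location) are recorded pre-noise in the scene's ground
truth.

Kinetics tables draw per-cell intensities log-normally (geometric sd 1.3)
around a decay curve interpolated log-linearly through (0, 1) and the
condition anchors; the anchors carry the condition medians (control:
40%/20% remaining at 5/30 min; knockout: 70%/50%).

### Presets

The named conditions fix the phenotype parameters: antigen inside
fractions 0.80 / 0.70 (control/KO soluble) and 0.50 / 0.20 (control/KO
bead); central vs peripheral antigen placement; cup clearance 0.85 vs 0.10
at the scored timepoint (time courses ramp 0.05→0.85 vs 0.05→0.12);
nuclear enrichment ν = 1.5 vs 0.4; coloc ρ = 0.6 vs 0.25.  Values not
fixed by the emulated experiments (ν, ρ, noise levels, cell size, puncta
count) were chosen once as typical of confocal B-cell imaging and are
documented here rather than tuned.

### What the generator does *not* emulate

No optical PSF beyond Gaussian spots, no photobleaching, no multi-cell
crowding, no z-dependent aberrations, no spectral bleed-through; cells are
near-circular and single.  A green recovery test therefore establishes
that the measurement chain is unbiased on idealized single-cell scenes at
realistic noise — not that segmentation would survive crowded fields or
heavy debris, which is out of scope.

## Determinism and seeds

A scene is a pure function of its config (including the seed).  Batch runs
split one root seed per cell with `SeedSequence([root, condition, index])`
(kept below 2³¹), so per-cell results are independent of batch ordering,
and reruns are byte-identical.

## Known limitations

* The actin-boundary ridge refinement assumes a dominant cortical ridge;
  images whose cytoplasmic actin rivals the cortex would need the
  bright-field boundary instead.
* The per-ray 120% region follows each ray; for strongly concave cells
  (excluded by the star-convex assumption) the region is undefined.
* Manders thresholds default to Otsu; published values obtained with other
  thresholding conventions are not directly comparable.
* The interface rectangle's length and exact placement are conventions
  (only its width is externally specified); both are exposed as
  parameters.
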