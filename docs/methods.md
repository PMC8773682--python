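# Methods

## Pipeline overview

For every field the analysis runs: background correction → smoothing →
primary object identification on the all-nuclei channel → per-object target
masks → Ch2 (impermeable-dye) feature measurement → reference-level
estimation (once per plate) → event classification → per-well aggregation
and statistics.  Time-lapse data add frame linking and trajectory
classification on top of the static per-frame analysis.

## Preprocessing

Background is estimated by grayscale morphological opening with a disk of
radius `background_radius_um` (default 30 µm) and subtracted, clipping at
zero.  The radius must exceed the nuclear radius by a comfortable margin,
otherwise nuclei are absorbed into the background estimate; 30 µm is ~4×
the largest rendered NET-cloud radius at the defaults.  The opening uses a
decomposed-disk footprint (a sequence of small structuring elements); this
is a close approximation of the exact Euclidean disk that runs in time
linear in the radius, and the unit tests bound its deviation from the exact
operator on fixtures.  Smoothing is a Gaussian blur (`smooth_sigma_um`,
default 1 µm) applied **only** to the nucleus channel for segmentation.
All intensity features are measured on background-corrected, unsmoothed
images so that the gates see undiluted signal.  Both operators use
reflective border padding.

## Segmentation

The nucleus-channel threshold is Otsu's between-class-variance split
multiplied by `threshold_scale` (default 0.6).  The sub-unity scale is
deliberate: dim spent nuclei of NET-forming cells and apoptotic nuclei must
not be lost, so the automatic threshold is relaxed toward the background
rather than tightened.  A constant image has no foreground/background
separation and raises a degenerate-image error.

Touching nuclei are split by a watershed on the negated Euclidean distance
transform.  Seeds are distance-transform maxima after h-maxima suppression
(h = 0.5 px, removing ridge noise) with a minimum separation of
`segmentation_radius_um` (default 4 µm, the expected nuclear radius); every
8-connected component is guaranteed at least one seed (its
distance-transform argmax), so no object can vanish.  Seed markers are
numbered in scan order and the final labels are densely renumbered, which
makes the output deterministic — identical input and parameters give a
bit-identical mask.  Objects below `min_object_area_um2` (default 12 µm²)
are removed; objects touching the image edge stay in the mask and the
object table but are flagged `border=true` and excluded from
quantification, because clipped nuclei bias the area gate.

The Ch2 foreground mask applies a plain threshold with **no** size filter:
NET clouds are diffuse and their full footprint must count.  Because most
Ch2 pixels are background in any treatment (so a bimodal split is not
guaranteed, e.g. on an all-control plate), the pipeline derives the Ch2
pixel threshold from the noise floor: median + 8 × robust SD
(1.4826 × MAD) of the background-corrected field.  The factor 8 places the
cut far above read/shot noise yet an order of magnitude below the rendered
dye signals.

## Target masks and features

Each cell's measurement region is its nuclear mask dilated by
`dilation_um` (default 8 µm), chosen so the several-fold decondensed
chromatin cloud of a NET remains inside its own region.  Where dilations of
neighbouring cells overlap, contested pixels go to the nearer object
centroid (ties to the lower label), so target regions always partition
their union and measurements stay single-cell.  `avg_intensity_ch2` is the
mean over the whole target region — not only over Ch2-positive pixels —
making the intensity gate sensitive to both brightness and spatial extent.
`target_area_ch2_um2` is the pixel count of Ch2 foreground inside the
region times the pixel area.

Annexin V descriptors use a *separate, smaller* dilation
(`annexin_dilation_um`, default 2 µm): surface Annexin V sits at the plasma
membrane, a micron or two outside the condensed apoptotic nucleus, so the
boundary shell of the 8 µm Ch2 target region would miss it entirely.  The
ring ratio is the mean Annexin intensity in the outer `shell_width_um`
band (default 1.5 µm) of that region divided by the mean over the eroded
interior, with an additive stabilizer of 1 intensity unit on the
denominator to keep dark interiors finite.  The coefficient of variation is
std/mean over the region.  Surface-localized staining gives ring ratios
well above 1; punctate staining gives CV above ~1.

## Reference levels and classification

*I\** is estimated by an exact 1-D between-class-variance split of the
per-object Ch2 intensities pooled over **all** wells — stimulated wells
supply the positive mode — accepted only when Sarle's bimodality
coefficient of the pooled sample exceeds 5/9 (the uniform-distribution
baseline).  Otherwise the plate is effectively unimodal (e.g. nothing
responded) and the gate falls back to median + 5 × MAD of the control-well
intensities.  *A\** is `area_multiplier` (default 2.0) × the median nuclear
area of Ch2-negative control cells.  Estimation requires at least 50
control objects; below that the pipeline demands manual gates.  All
effective gates are written to the run manifest.

Gates use ≥: a cell exactly at a reference level is a responder.  In
four-channel mode the branches are evaluated in fixed precedence
NET → apoptotic → necrotic → live: decondensation dominates Annexin
positivity (Annexin V also decorates NET remnants), and surface Annexin
dominates bare PI positivity (late apoptosis is PI-positive).  The Annexin
CV is reported and logged but not required for the NET branch; the area
gate suffices, and stricter gating remains available through configuration.
Reference levels are estimated once per plate, not per well, so that
treatment comparisons share identical gates.

## Quantification and statistics

Percent NETosis = 100 × Type 1 / total non-border Hoechst-positive cells,
fields pooled within the well.  Wells are the replicate unit.  Two groups
are compared by an unpaired two-sample t test (equal-variance by default;
Welch by flag), more by a one-way ANOVA F test, with stars at
p < 0.05/0.01/0.001.  No multiple-testing correction is applied and the
report labels p-values as unadjusted.  An empty well yields undefined
(None) percentages rather than an error.

## Time-lapse

Frames are linked greedily: candidate (track, detection) pairs within
`max_displacement_um` (default 10 µm) are sorted by distance (ties by lower
object id) and matched one-to-one; unmatched detections start new tracks
and tracks survive up to `max_gap` missed frames (default 1).  Greedy
linking equals optimal assignment in the sparse, near-immobile regime these
assays operate in, and it is deterministic.

A track is LIVE if the intensity gate never passes; NETOSIS if it passes
and the Ch2 area reaches *A\** at or after permeabilization; NECROSIS if
the area stays below *A\** **and** the track persists at least
`min_follow_min` (default 45 min, three 15-min frames) beyond
permeabilization — the necrosis call asserts that decondensation never
happened, which requires prolonged observation; a permeable cell followed
more briefly is AMBIGUOUS rather than necrotic.  When a plate has no
control wells (a stimulated time series), the pre-stimulation t = 0 frame
serves as the control population for gate estimation.

## Synthetic plates

The generator renders what the gates must discriminate, not photorealistic
neutrophils: live cells as multilobed Hoechst-bright nuclei (union of 2–4
offset disks, base radius 3.5 µm ± 5 %), NETs as enlarged
impermeable-dye-bright clouds with a soft radial profile and dimmed
Hoechst, necrotic cells as condensed (0.8×) doubly-bright nuclei, and
apoptotic cells as condensed nuclei with a membrane-radius Annexin ring
(late sub-state additionally PI-positive).  The NET decondensation factor
is sampled uniformly from 2.5–6× the live nuclear area — entirely above the
2× area multiplier, so ground-truth NETs are separable in expectation.
Rendering applies a 0.8 µm Gaussian PSF, a constant-plus-gradient
background (100 + 30 counts across the field), and signal-dependent shot
noise plus Gaussian read noise (SD 10 counts) at 16-bit depth,
0.65 µm/px.  Cells are placed by hard-core rejection sampling (20 µm
minimum spacing, footprints kept clear of the border) so ground-truth
masks partition trivially.  Time-lapse scripts permeabilize necrotic cells
at 30–60 min with constant area, NETotic cells at 60–120 min with area
growing monotonically to the sampled factor over 3–5 frames, and jitter
positions by < 2 µm/frame.

What this does **not** emulate — and hence what passing tests do not
demonstrate about real data: overlapping or clumped cells, NET clouds
merging across neighbours, photobleaching, focus drift, illumination
falloff beyond a linear gradient, debris, vital NETosis (anuclear
cytoplasts), and the full morphological variety of primary neutrophils.
The recovery numbers are upper bounds tied to these rendering assumptions.

## Validation problem sizes

The screening-plate recovery check uses 500 cells/field at 1024×1024 px
(6 fields/well in the test suite, 4 in the acceptance script) with truth
30 % NET / 10 % other death / 60 % live against a 95 % live control; the
concentration ladder uses 5/15/30/50 % NET in triplicate 150-cell wells;
the inhibitor contrast 40 % vs 8 % in triplicate; the time-lapse check 60
cells over 13 frames (0–180 min every 15 min).  Segmentation is checked
against brute-force 8-connected labeling on randomized well-separated
fixtures, and the statistics against textbook closed forms at 1e-10.

## Numerical and degenerate-input conventions

Coordinates are 0-based (row, col); labels are positive with 0 =
background; all length parameters are micrometres, converted internally
via `pixel_size_um` (default 0.65 µm/px for a 20× objective).  Watershed
ties and contested-dilation ties break toward the lower label; dense
relabeling follows seed scan order.  Constant images raise a
degenerate-image error at thresholding; empty masks yield empty record
lists; empty wells yield flagged-undefined percentages; identical constant
replicate groups give t = 0, p = 1.  Multi-page OME-TIFF input is accepted
by passing per-channel paths into the reader; the flat
one-TIFF-per-channel naming convention
(`{well}_f{field:02d}_t{minutes:04d}_{channel}.tif`) is the native layout.

## Known limitations

Ch1 under-segmentation of very faint merged NET remnants is tolerated by
design (classification is driven by Ch2 measurements anchored on Ch1
seeds).  The exact thresholding and segmentation operators of commercial
HCS software are proprietary; this package fixes open, documented choices
(scaled Otsu, distance-transform watershed) that reproduce the described
behaviour, not the vendor's binaries.  "Punctate" versus "surface"
Annexin V staining has no standard quantitative definition; the
ring-ratio/CV operationalization here is this package's construction, with
defaults calibrated on the synthetic generator and manual override always
available.
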