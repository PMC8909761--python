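# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Radial distribution and the MDR

The unit of analysis is a single cell: an intensity image with nucleus and
cell masks.  The centre is the centroid of the nucleus mask (an explicit
override is accepted); using the centroid removes the one manual step of
the original workflow while matching its intent.  Boundary radii are found
per angle as the first background crossing of each (hole-filled) mask along
the ray, sampled at 0.25 px steps.

Resampling to polar coordinates is done by splitting every pixel's
intensity over a `supersample × supersample` grid of sub-pixel points
(default 4×4) before binning in (θ, r).  Each polar bin therefore receives
the signal of exactly the image area it covers, which is the practical
content of the square-pixel correction: the alternative — sampling the
image at polar grid points — over-weights small radii.  Total signal is
conserved to floating-point precision (the suite checks a 2 % bound; the
measured error is ~1e-12).

Per angle, [0, nucleus_edge] maps affinely to [0 %, 25 %] and
[nucleus_edge, cell_edge] to [25 %, 100 %]; sub-pixel spill beyond the cell
edge is clipped to 100 %.  The marginal over angle is signal-weighted (a
ray contributes in proportion to the signal it carries); the alternative —
equal weight per angle — would up-weight rays with almost no signal, which
is not what a signal density should do.  The density lives on 100 bins of
1 % by default (360 angles × 256 radii upstream; all configurable).  The
convention checks use 1024 radii and 200 bins, where half-bin quantization
of a boundary spike is ~0.2 normalized units.

The MDR is the median of the radial density, found by linear interpolation
of the cumulative distribution; a CDF plateau at ½ returns the plateau
midpoint (unique and symmetric).  An empty cell (zero signal) is an error,
not a zero.

Accuracy: on synthetic scenes the MDR tracks the generating law's analytic
median.  Two real error sources are worth knowing.  First, the sampling
error of an empirical median scales as ~1.25·σ/√n, so wide laws need many
objects: uniform(25, 100) has σ ≈ 21.7, giving ±1.9 units at n = 200 and
±0.4 at n = 5000 — the validation scenes use 1000–5000 objects for this
reason.  Second, additive background noise, once clipped at zero, deposits
mass proportional to annulus area, which grows with radius; this tilts the
*profile* outward slightly but barely moves the median.  Objects are
rendered additively (overlapping fluorophores add), otherwise crowded
perinuclear regions would saturate and bias the MDR outward.

## Morphometry

Circularity is 4πA/P² with the perimeter measured on the 0.5-level
sub-pixel contour smoothed by a 7-point periodic moving average.  Chain-code
perimeters overestimate curved outlines by the staircase factor (a disk
scores ≈ 0.92) and Crofton perimeters underestimate axis-aligned rectangles
by ~6 %; the smoothed-contour estimator puts a rasterized disk at ≈ 1.00
and a 4:1 rectangle within ~2 % of its exact value, and is strictly
decreasing across an ellipse elongation sweep.

Morphology calls are an automated surrogate for blinded manual scoring: an
object is tubular when its elongation (major/minor axis ratio) ≥ 3; a cell
is reticular when the tubular fraction ≥ 0.6, rounded when ≤ 0.2, mixed
between.  The cutoffs are configuration, reported in output metadata, and
were fixed before validation; on generator scenes they recover the
generated mix direction essentially always.

Stereology: the fine lattice (default spacing 8 px) scores mitochondria,
the coarse lattice (default 32 px, a subset of the fine lattice) scores
cytoplasm, and the volume density is 100·P_mito/(r·P_cyto) with r the
number of fine points per coarse point (16 at the defaults).  The ratio
correction is what makes the double-lattice count a volume fraction;
without it the quantity is bounded by 100·r, not 100.  The lattice offset
is uniform over a fine cell (plus a uniform coarse-cell shift), which makes
the estimator unbiased; when the reference mask tiles the lattice evenly
(e.g. the full image with spacings dividing its size) the identical-mask
estimate is exactly 100 %.  Measured bias at true fractions of 5/15/30 % is
below 0.05 percentage points over 100 offsets.

## 3D segmentation

The chain is fixed: threshold → erosion → labeling → speckle removal →
measurement.  "Upper Otsu" is the higher threshold of a three-class Otsu
split of the intensity histogram, keeping the brightest class; a volume
with only two distinct values falls back to single Otsu with a warning.
Erosion uses a full 3×3×3 cube by default (cross and ball offered);
components under 10 voxels are removed and survivors renumbered by
decreasing size; labeling is 26-connected by default.  All parameters land
in the output provenance.

Volumes are measured by default on the *pre-erosion* thresholded mask
restricted to components that survive erosion and speckle filtering
(`measure_on="threshold"`); `measure_on="eroded"` measures the eroded mask
itself.  The reason is quantitative: erosion by a 3-cube removes roughly a
one-voxel shell, and at realistic mitochondrial sizes (≈ 3.8 µm³ at 0.15 µm
voxels, short semi-axis ≈ 5 voxels) that halves the measured volume and
distorts ratios between size populations; the pre-erosion measurement keeps
erosion in its intended role — separating weakly connected components —
without paying its volumetric bias.

Even pre-erosion volumes underestimate truth by ~20–25 %, because the upper
Otsu threshold cuts inside the smoothed object surface (more so for convex
surfaces).  The residual bias is well modelled as the loss of a thin shell:
`calibrate_shell_correction` renders reference objects of known volume,
runs the chain, and returns the mean volume deficit per unit surface area
(δ ≈ 0.05 µm ≈ 0.35 voxel at the defaults; stable to ~±10 % across the
1.9–7.6 µm³ range).  Passing δ to `run_segmentation` adds δ·A per object as
`volume_corrected_um3` (the raw `volume_um3 = voxel_count × voxel volume`
is always kept).  With the correction, per-object volumes land within
~5–10 % of truth and a true 2:1 two-population ratio is recovered as
2.0 ± 0.1; without it the measured ratio runs ~7 % high.

Detection limit: an object must survive thresholding plus erosion with
≥ 10 voxels, which at 0.2 µm voxels excludes objects below roughly 1.8 µm³
(worst-case aspect).  Validation scenes therefore use 0.15 µm voxels, where
the same limit is ≈ 0.8 µm³ and the full log-normal volume distribution
(mean 3.8, SD 1.5 µm³) is detectable.  This is a real property of the
erosion-based chain, not of the implementation.

## Dynamics

Linking is globally greedy: all (active track, new object) pairs within the
displacement gate are sorted by centroid distance and accepted in order,
one match per track and per object; unmatched objects open tracks; a track
may skip up to `max_gap` frames with the gate scaled by the number of
skipped steps.  On scenes with unambiguous displacements (steps small
against inter-object distances) greedy matching coincides with the
exhaustive minimum-total-distance assignment, which the tests verify by
brute-force permutation on ≤ 6-object instances.  Speeds are
|Δcentroid|/Δt per consecutive step; the per-cell summary reports the mean
over tracks of per-track maxima (and of means), excluding tracks shorter
than `min_track_len` (counted in a QC field).  Δt comes from metadata or
config, never inferred from the data.

Fusion readout: the converted (photoconverted) channel is segmented per
frame — with a *single* Otsu threshold, because a 50/50 fusion product is
half as bright in the converted channel as an unfused converted object, and
an upper-Otsu threshold would discard exactly the dim mixed class the
readout needs.  Per object, summed intensities in both channels are
measured on the converted-channel mask; an object is double-coloured when
each channel holds ≥ `frac_threshold` (default 0.1) of its two-channel
total.  The fractional criterion is intensity-scale invariant; an absolute
threshold would not survive illumination changes.  The growth rate of the
double-coloured count is a least-squares slope over frames, reported raw
(count/s) and normalized by the mean object count — the normalized rate is
the quantity that stays fixed when a condition simply has more mitochondria
at equal per-object fusion propensity, which is the logic of the doubling
comparison.

## Statistics

Two groups: Mann–Whitney U, exact null when min(n) ≤ 8 and tie-free,
normal approximation with tie correction otherwise; Student's t on request.
Identical constant groups return p = 1 with a warning rather than NaN.
Three or more groups: Kruskal–Wallis with tie correction, then Dunn's
pairwise z tests on the pooled mean ranks.  The family-wise default for
Dunn's follow-up is Bonferroni (the classical "Dunn's multiple comparison"
convention); Holm and Benjamini–Hochberg FDR are selectable because the
procedure name that circulates in methods sections ("Bonferroni–Hochberg")
does not pin down a unique method — the choice is logged in the report.
The cell, not the object, is the statistical unit for per-cell endpoints;
a replicate id accompanies every row so per-replicate summaries can be
formed.

Calibration: exact MW p-values match full rank enumeration for all
tie-free samples up to n = 6; under the null, both MW (n = 30 + 30) and KW
(3 × 30) reject at 0.05 within [0.03, 0.07] over 1000 simulations.  KW
group sizes of ~15 make the chi-square reference visibly conservative
(≈ 0.029), which is why the calibration scenes use 30 per group.

## The synthetic generator

2D scenes are circular cells with a concentric circular nucleus; objects
(thick segments for tubular, disks for round) are placed at normalized
radii drawn from a delta, uniform, or truncated-gaussian law supported on
[25, 100] — the generator works on the same normalized axis the analysis
reports on, so the law's analytic median is the scene's true MDR.  3D
scenes are axis-aligned ellipsoids with log-normal volumes (defaults: mean
3.8 µm³, SD 1.5 µm³, the scale of real mitochondria), constant drift plus
isotropic diffusion stepped at the frame interval (Euler, no sub-stepping;
default displacements are small against object size), reflecting at
margins so no object leaves the field.  Photoconversion relabels object
content inside the conversion region at t = 0 (fractionally for straddling
objects); fusion merges two live objects into one whose continuous volume
is exactly the parents' sum and whose channel content mixes in proportion
to parent volumes.  Because a merged ellipsoid is placed at the parents'
volume-weighted centroid, it could land on a bystander; objects are treated
as impenetrable and the product is nudged away until the scene stays
resolved.  EM scenes place dark ellipses until a target area fraction is
reached (stopping within 0.25 pp; unreachable packings error out after a
bounded number of attempts).

Rendering is anti-aliased intensity: binary masks smoothed with a Gaussian
(σ = 1 px/voxel by default) plus additive Gaussian noise, clipped at zero —
enough structure for Otsu thresholds to be meaningful.  Ground truth is
recorded at two levels: per-frame tables (rasterized voxel counts and mask
centroids, which measurement of the truth masks reproduces exactly, plus
the continuous model volume, on which fusion conservation is exact) and
full label volumes.  Identical spec + seed gives bit-identical output.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: realistic PSFs and anisotropic axial blur,
camera noise beyond additive Gaussian, curved/branched mitochondrial
tubules and genuine network connectivity, fission, photobleaching, uneven
illumination, and segmentation errors from touching organelles in dense
networks.  Real frame intervals and voxel sizes for fast volumetric
imaging are not published for the motivating experiments; the defaults
(Δt = 1 s, 0.15–0.2 µm voxels) are configurable, not asserted.

## Problem sizes used in validation

Chosen so each check keeps its estimator noise well inside the band it
asserts: MDR-law scenes use 5000 objects (median sampling error ±0.4
units); count recovery uses 50 seeds of 50-object scenes at 0.15 µm voxels;
the volume-ratio contrast uses 3 scene pairs of 50 objects after run-time
shell calibration; stereology averages 100 lattice offsets; the doubling
comparison uses 20 seeds per arm with a delta-method SE on the ratio of
mean rates; statistical calibration uses 1000 null replicates.
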