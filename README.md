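# mitomorph

Quantitative analysis of mitochondrial network organisation in single cells:
where mitochondria sit in the cytoplasm, what shape the network takes, how
big and how many the mitochondria are in 3D, how fast they move, and how
often they fuse.  The package reimplements the full measurement chain as
tested Python, driven by a ground-truthed synthetic scene generator, so every
stage can be validated without access to microscopy data.

It is written for cell biologists and image analysts quantifying
mitochondrial phenotypes (e.g. control vs knockdown contrasts) from
fluorescence, volumetric live-cell, or EM data.

## What it computes

**Mean distribution radius (MDR).**  For each cell, the marker signal is
mapped to polar coordinates around the nucleus centre; per angle, the radial
axis is rescaled so the nuclear envelope sits at 25 % and the cell periphery
at 100 %.  The signal is marginalised over angle into a radial probability
density p(r), and the MDR is the radius r where

    ∫₀ʳ p = ∫ᵣ¹⁰⁰ p = ½,

i.e. the median of the radial signal density.  A larger MDR means a more
peripheral mitochondrial distribution.  The polar resampling is done by
dense sub-pixel supersampling, so each polar bin receives exactly the signal
of the image area it covers (the square-pixel correction) and total signal
is conserved.

**Morphometry.**  Per-object circularity 4πA/P² (perimeter from the smoothed
sub-pixel contour), elongation, and a reticular/rounded/mixed call per cell
from the fraction of tubular objects.  Mitochondrial volume density in EM
images is estimated by double-lattice point counting: fine-lattice hits on
mitochondria over ratio-corrected coarse-lattice hits on cytoplasm, with a
random lattice offset per image.

**3D segmentation.**  Upper-Otsu threshold (the higher threshold of a
3-class Otsu split) → 3D erosion with a 3×3×3 kernel → 26-connected
labeling → removal of components under 10 voxels → per-object volume,
centroid and channel intensities.  An optional run-time-calibrated
shell-loss correction compensates the partial-volume/erosion bias.

**Dynamics.**  Greedy gated nearest-neighbour linking of per-frame objects
(validated against exhaustive minimum-cost assignment), per-track speeds,
and photoconversion-based fusion counting: objects segmented on the
converted channel are "double-coloured" when each channel carries ≥ 10 % of
their total intensity, and the growth rate of that count — absolute and
normalized by object count — reads out fusion activity.

**Statistics.**  Mann–Whitney U (exact for small samples) or Student's t for
two groups; Kruskal–Wallis with Dunn's pairwise z tests for three or more,
with Bonferroni / Holm / Benjamini–Hochberg adjustment.

## Worked example

`analysis/02_radial_mdr.py` generates two synthetic conditions of 30 cells —
a control with a gaussian radial law centred at 65 % and a knockdown-like
condition shifted inward to 55 % — and runs the full radial pipeline plus
statistics:

```
per-cell mean distribution radius (MDR, % of normalized axis):
  control    64.93 ± 0.09 (n=30)
  knockdown  55.36 ± 0.08 (n=30)
Mann–Whitney U = 900, p = 3.02e-11
```

The recovered per-condition means sit on the generating laws' medians (65
and 55), and the perinuclear shift is detected with the cell as the
statistical unit.  The other drivers follow the same pattern:

- `01_simulate_scenes.py` — one example scene of each family, written as
  TIFF / OME-TIFF with ground-truth CSVs;
- `03_morphometry_stereology.py` — morphology calls across a tubular-mix
  sweep and stereology vs pixel-count truth (e.g. 30.03 % estimated vs
  30.06 % true);
- `04_segment_volumes.py` — exact 50-object count recovery and the
  two-population volume contrast (measured ratio 2.01 for a true 2:1);
- `05_track_fusion.py` — drift speed recovery, scripted fusion counts
  (k fusions → exactly k double-coloured objects), and the doubling
  comparison (absolute growth ≈ 2×, normalized ≈ 1× with twice the
  mitochondria).

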