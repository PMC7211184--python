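# Methods

## Device model

The array is described entirely in physical µm (`ArrayLayout`), with one
conversion factor to scanner pixels (`pixel_size_um`, default 5 µm/pixel).
Defaults mirror the fabricated device: 300 µm square wells, 39 µm deep,
spaced 50 µm, in a 28 × 28 grid; each well holds a 3 × 3 grid of 40 µm posts
at 100 µm pitch, centered in the well.  Derived identities used throughout:
well pitch = side + spacing (350 µm = 70 px), post side = 8 px, post
footprint = 64 px.

Two design conventions are deliberate.  The well-count formula credits the
missing trailing spacer — ⌊(extent + spacing)/pitch⌋ per axis — because an
array of n wells spans n·pitch − spacing; this yields 28 wells across 1 cm at
the 300/50 geometry.  Post packing assumes a square grid at the given pitch
anchored to fit inside the well (⌊(well − post)/pitch⌋ + 1 per axis); at
20 µm posts the pitch is not dictated by the device, and we adopt 50 µm —
the natural half of the existing 100 µm pitch — giving a 6 × 6 grid.

## Signal model and the synthetic generator

The assay runs long enough that essentially all miRNA liberated in a well is
captured by its posts, so post fluorescence tracks the *amount* per well, not
the concentration.  The generator therefore uses a linear model on amounts:

    post mean = min(background + gain × amount, saturation),
    amount    = areal density (amol/mm²) × well footprint (0.09 mm²),

with the tissue patch above each well digested into that well only (no
cross-well leakage).  Negative-control and blank posts always carry amount 0.

Two baseline levels are distinguished.  `background_afu` (default 1500) is
the hydrogel post's fluorescence at zero analyte; `slide_afu` (default 100)
is the darker well floor exposed where a post was lost in fabrication.  This
contrast is what makes a missing post detectable downstream: its site reads
~slide level while the same well's negative-control post reads ~background,
so the control-subtracted net is strongly negative (≈ −1400 AFU at the
defaults), tripping the −1000 AFU rule.  With a single shared baseline the
rule could never fire.

Remaining defaults, chosen once as plausible for a PE-labeled hydrogel assay
on a 16-bit scanner and kept fixed: gain 1000 AFU/amol (so the expected
0.45 amol under ~5 amol/mm² tissue sits mid-range), pixel noise sd 50 AFU
(i.i.d. Gaussian per pixel; a post mean over 64 px then has sd 6.25 AFU),
saturation 65535 AFU, dust as 60–120 µm squares at 40–60 kAFU (always larger
than a post and far above tissue signal), missing-post probability 0.005
(near the observed 0.6 % fabrication loss rate).  Demo tissue densities are a
few amol/mm² with tumors at 3–5× NAT.

What the generator does **not** emulate: optics (PSF, vignetting, flat-field
error), slide rotation, hybridization kinetics and depletion, probe
cross-hybridization, sequence bias, and histology texture.  Passing tests
therefore demonstrate the correctness of the *analysis* — registration,
extraction, calibration arithmetic, filters, statistics — not robustness to
these physical effects on real slides.

Determinism: every generator consumes a `numpy` Generator seeded from the
scenario; derived streams (calibration replicates, serial sections) come from
`SeedSequence.spawn`, so identical seeds give bit-identical images and
tables.

## Image pipeline

**Dust removal.** Connected components (8-connectivity — conservative
merging for axis-aligned bright squares) of pixels strictly above a
user-supplied threshold whose area exceeds the 64 px post footprint are set
to the background level, defined as the median of all pixels at or below the
threshold.  The threshold is configuration (default 30 000 AFU in the CLI),
not a claimed universal constant.  The operation is idempotent and touches no
pixel outside removed components; a post overlapped by dust is cleaned to
background and subsequently excluded by the net-signal filters rather than
silently mismeasured.  Arrays handled cleanly can skip the step
(`--no-dust-removal`).

**Registration.** Two anchors — the pixel of the upper-left corner of the
upper-left post of two distinct wells — determine an axis-aligned grid: per
axis, pixel pitch = anchor displacement / well-index offset, falling back to
the nominal pitch when the anchors share a row or column.  Within-well post
offsets come from the layout.  A pitch deviating more than 10 % from nominal
warns; no rotation is modeled, so rotated slides are a stated limitation.
Pixel coordinates are 0-based, x = column, y = row, origin top-left; boxes
are half-open.  Box corners are rounded to integer pixels; at the device's
integer-pixel geometry (70 px well pitch, 20 px post pitch) this is exact.

**Extraction and window.** Post means are plain box means (boxes outside the
frame are flagged, not dropped silently).  The optional analysis window keeps
a centered rows × cols block of wells (margin floored), the convention used
to avoid array edges and cracks; 9 × 11 retains 99 wells.

## Quantification

Net signal subtracts the same well's negative-control post (the off-target
spike-in probe, e.g. cel-miR-54), not the blank post — the missing-post rule
is defined against that control — while the blank is carried as a QC column.
Calibration is an ordinary least-squares line on linear axes over the assayed
range; each calibration point is the mean net over an array's analysis wells.
LOD = 3·σ_blank/slope, the standard analytical-chemistry convention (the
estimator is a design choice; LOD values depend on it and on the synthetic
noise level, so they are package-internal quantities, not reproductions).
Amount conversion inverts the line and *preserves* negative estimates
(flagged `below_zero`) so region statistics remain unbiased.

## Filters and statistics

Filter order is fixed: the missing-post rule first (net < −1000 AFU, strict
inequality — a structural failure mode), then the distributional debris
filter — a one-sided high-tail Grubbs test, single pass (at most one removal)
at α = 0.001, with G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper
α/n t-quantile on n−2 df.  An iterative variant exists behind
`QcConfig(grubbs_iterative=True)` but is off by default.  Region comparisons
use Tukey's HSD via `scipy.stats.tukey_hsd`, which applies the Tukey–Kramer
adjustment for the unequal well counts that regions necessarily have; each
well under a region is one sample.  Star labels use strict thresholds
(***p < 0.001, **p < 0.01, *p < 0.05, else NS).  No correction is applied
across probes — the HSD family is the set of region pairs within one probe.

Monte-Carlo checks in the test suite verify the Grubbs false-removal rate at
its nominal α (1000 null samples of n = 99) and the Tukey family-wise error
at 5 % (1000 null datasets of four groups of 25), both within binomial 95 %
bounds of the nominal rates.

## Spatial mapping

Heatmaps are a lossless re-indexing of the well table onto the lattice
(NaN where filtered).  Region polygons are supplied in array µm coordinates
(the transfer from an H&E overlay is the user's responsibility); a well
belongs to the region containing its center, ties going to the first-listed
region with a warning.  Cross-section CV is the sample CV of section-level
region means per (region, probe), with the grand average reported as the
single reproducibility figure; serial sections are emulated by one
multiplicative gamma factor per section (unit mean, CV as configured), so all
(region, probe) pairs share a section's realized factor.

## Problem sizes and numerics

The demo scenario uses a 12 × 14-well array (1512 posts, ~0.8 Mpx image) and
calibration series of 6 amounts × 3 replicates; Monte-Carlo suites use 1000
replicates.  These sizes give stable statistics while keeping the full test
suite and drivers fast on a laptop.  Degenerate inputs are handled
explicitly: zero-variance samples have no Grubbs outlier, zero blank sd gives
a (warned) zero LOD, all-above-threshold images make dust removal fail rather
than invent a background, empty regions are omitted from summaries with a
warning, and boundary cases use the documented strict/closed conventions
(−1000 retained, p = 0.05 → NS, window margin floored).

## Known limitations

No rotation or flat-field correction; no automatic anchor detection; no
modeling of control-post loss (a missing *control* post inflates all targets
in its well — visible in synthetic data, unfiltered, as in the original
procedure); LOD and CV magnitudes are properties of the synthetic noise
model, not of any real scanner; RT-PCR comparison utilities implement the
normalization arithmetic only and take Ct tables as given.
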