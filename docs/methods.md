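# Methods

`dropseg` quantifies lipid-droplet (LD) phenotypes of yeast strains
from paired microscope fields: a brightfield channel for cell outlines
and a BODIPY-like fluorescence channel for droplets.  The pipeline has
four parts — instance segmentation of cells by spatial embeddings,
per-cell droplet counting by a descending threshold sweep, supersized-LD
scoring, and blocked-ANOVA strain statistics — plus a synthetic-scene
generator that provides full ground truth for every stage.

## Cell segmentation by spatial embeddings

A convolutional network makes three pixel-wise predictions: a seed
score `s_i ∈ [0,1]`, a positive scalar bandwidth `σ_i`, and a 2-D
offset `o_i`.  The spatial embedding of pixel `i` is `e_i = x_i + o_i`,
where `x_i` is the pixel's (row, col) coordinate divided by a
coordinate scale.  Training drives the embeddings to be constant over
each cell and distinct between cells, indirectly: for every
ground-truth cell `k`, the mean embedding `ē_k` and mean bandwidth
`σ̄_k` over the cell's pixels define a Gaussian soft mask

    φ_k(i) = exp( −‖e_i − ē_k‖² / (2 σ̄_k²) ),

which is matched to the cell's binary mask with the Dice loss
`1 − 2·Σφt / (Σφ + Σt + ε)` (ε = 1e−7), a choice robust to the strong
foreground/background imbalance.  The per-cell Dice terms are averaged
over cells.

**Seed-map objective.**  The seed head has no canonical loss in this
formulation; we regress it (squared error) to the gradient-detached
soft-mask value on each cell's pixels and to 0 on background, with a
configurable weight (default 1).  At inference the seed score of a
pixel then estimates how well its embedding represents an instance.

**Bandwidth parameterization.**  The raw bandwidth channel passes
through a softplus (+1e−4 floor) so `σ_i > 0` always; the "average
predicted bandwidth" of a cell is the arithmetic mean of `σ_i` over its
pixels.  An optional variance penalty encouraging per-cell bandwidth
consistency exists behind a config flag and is off by default.

**Coordinate scale.**  By default coordinates are normalized by the
larger image dimension.  Because a bandwidth learned in such units on a
128-px crop would be wrong on a larger field, the maps and checkpoints
carry an explicit `coord_scale` (pixels per embedding unit); training
fixes it to the crop size, and inference reuses the stored value, so
crops and full fields share one coordinate unit.

**Architecture.**  A residual U-Net: encoder/decoder with a residual
block at every scale, batch normalization after every convolution, 2×2
average pooling and nearest-neighbour upsampling, additive skip
connections through 1×1 projections, and a 1×1 four-channel head
(seed logit, raw bandwidth, two offsets).  Desk-scale defaults are
depth 3 and 16 base channels with 128-px crops; crop size and widths
are configurable upward (the formulation itself is the same at
1,024-px crops).  The head is initialized so that offsets start at
zero and the bandwidth at 0.08 normalized units — the embedding of
each pixel starts at its own coordinate, which makes the initial soft
masks compact blobs around cell centroids and speeds convergence.

**Training.**  Adam at learning rate 1e−4 on randomly flipped/rotated
random crops; batch size 2 by default, implemented as per-crop gradient
accumulation (identical to a joint mean, and memory-friendly).  All
randomness (initialization, crop sampling, augmentation) derives from
one seed; with augmentation off, two runs on the same CPU produce
identical traces.  A NaN loss aborts with the offending step and batch
named.  The returned parameters are the best-on-validation state
(validation loss on centre crops, evaluated every `eval_every` steps).
The network and its optimizer run on a small in-package reverse-mode
autodiff engine over numpy (float32), with convolutions via a
patch-matrix factorization; gradients are finite-difference tested.

**Inference.**  The iterative seed-clustering rule: among unassigned
foreground pixels (seed > 0.5) pick the pixel with the highest seed
score as a seed `s`; every unassigned foreground pixel `i` with
`exp(−‖e_i − e_s‖²/(2σ_s²)) > 0.5` joins the instance, where `σ_s` is
the bandwidth predicted at the seed pixel (the seed pixel's own
bandwidth, not a running average — the ambiguity is noted and the
choice fixed here).  Each round assigns at least the seed itself
(kernel value 1), so the loop terminates in at most one iteration per
foreground pixel.  Ties in the seed score break to the smallest
(row, col) for determinism.  Both thresholds are parameters.

**Postprocessing.**  Instances smaller than 300 px are removed
("falls below" read as strict `< 300`, so a 300-px instance is
retained — the boundary is tested), as are instances touching any
image border.  Survivors are replaced by their convex hulls for all
downstream analysis (mirroring an ImageJ ROI workflow); the raw pixel
clusters are kept in provenance.  Hull polygons are exported as
ImageJ `.roi` polygon records (zipped) plus a `polygons.json` mirror
and a hull-rendered label TIFF; where hulls of adjacent cells overlap,
the label image is render-order resolved but quantification uses the
per-cell hull masks, so each cell sees its full region.

**Validation metric.**  Predictions are matched to ground-truth cells
greedily by descending IoU (threshold 0.5).  Ground-truth cells that
the pipeline's own filters would remove (border-touching or under the
area threshold) are excluded by default so the score reflects
segmentation quality, not filter bookkeeping.  Mean IoU averages over
evaluated ground-truth cells, counting unmatched cells as 0; merged
(one prediction covering ≥ half of two or more cells) and split
configurations are counted separately.

## Droplet counting and supersized scoring

Counting follows an ImageJ-style routine.  For each cell region and a
lower threshold `T`, particle foreground is `T ≤ value ≤ 65,535`
(ImageJ lower-threshold semantics — the upper threshold is maximal);
particles are 8-connected components (ImageJ "Analyze Particles"
default; 4-connectivity available) of the foreground restricted to the
region.  A particle spanning two adjacent hulls contributes its
in-region component to each cell, matching per-ROI measurement.  The
sweep runs `T = 20,000, 18,000, …, 2,000`, and the cell's droplet
number is the **maximum** count over the sweep: high thresholds see
only the brightest droplets, low thresholds pick up dim ones but merge
clustered droplets, so no single threshold is right.  Counts need not
be monotone in `T`; what is guaranteed (and tested) is that the
foreground mask at a higher threshold is nested inside the mask at a
lower one.

A cell is scored as containing a supersized droplet when a separate
pass at lower threshold 10,000 finds a particle of area strictly
greater than 0.5 µm².  The area is the plain thresholded component
area (pixels × pixel area); nothing is deconvolved.  The default
calibration is 0.065 µm/px (typical 100× sCMOS sampling) and is
configurable; note that at this calibration a 0.4-µm-radius droplet has
area π·0.4² ≈ 0.503 µm², so the area rule and the r > 400 nm
description of supersized droplets coincide.  Intensities are 16-bit
counts (0–65,535), consistent with the threshold values.

## Strain statistics

Per field: the mean droplet count per cell and the percentage of cells
with a supersized droplet.  The three fields of a strain in an
experiment are averaged into one data point, giving a complete
strain × experiment table.  Strains are compared with a one-way ANOVA
with experiments linked as blocks (randomized complete block): the
additive decomposition `SS_total = SS_strain + SS_block + SS_res` with
`F = MS_strain / MS_res` on `(s−1, (s−1)(b−1))` degrees of freedom.
Preselected strain pairs (they must be supplied explicitly; there is no
all-pairs default, since the number of comparisons `m` enters the
adjustment) are tested with
`t = (ȳ_i − ȳ_j) / sqrt(2·MS_res/b)` on the residual degrees of
freedom — the pooled-error convention of the GraphPad Prism workflow —
two-sided throughout.  The Holm–Šidák step-down adjustment sorts the
raw p ascending and sets `p̃_(k) = 1 − (1 − p_(k))^(m−k+1)`, enforcing
monotone non-decreasing adjusted values by a running maximum and
capping at 1.  (Whether the original Prism analysis used Šidák or
Holm–Bonferroni stepping cannot be determined; Šidák is the default
and Holm–Bonferroni is available via `method="holm"`.)  Stars follow
* p < 0.05, ** p < 0.01, *** p < 0.001, NS otherwise.

## Synthetic scenes

The generator emulates the study's data: fields of non-overlapping
elliptical cells (a configurable fraction touching the border, to
exercise the border filter), a brightfield-like appearance (mid-grey
background, darker cell interior, bright rim, Gaussian blur and
noise — only learnability matters, not optics), and a fluorescence
channel in which droplets are hard disks at a peak intensity,
max-blended, blurred with a small Gaussian PSF (σ = 0.8 px) and given
read noise.  Strain archetypes set the droplet-count Poisson mean, a
log-normal radius distribution (µm), a peak-intensity range, and a
clustering probability (droplets deposited adjacent to existing ones —
the seipin-null hallmark).  Built-ins: `wt_like` (mean 8 droplets,
radii ≈ 0.13 µm, mild clustering), `null_like` (mean 2, radii
straddling 0.4 µm, strong clustering), `bright_sparse` (few bright
disjoint droplets with radii ≥ 2 px, for exact count-recovery checks;
a strict-disjoint placement mode discards draws that cannot be placed
with clearance so the droplet table stays exact), and `empty`.

Geometry is deliberately scaled down: cells have 10–16-px semi-axes so
that dozens of cells fit in a 128–400-px field while clearing the
300-px filter.  Coordinates are 0-based (row, col); label 0 is
background; images are 2-D projections only (no z-stacks).

What the generator does **not** model: real point-spread physics,
3-D structure, spectral properties of the stain, autofluorescence,
uneven illumination, or real brightfield texture.  Passing tests
therefore demonstrate that the algorithms are implemented correctly
and behave as designed under controlled conditions — not that the
trained network or the counting rule meets any particular accuracy on
real micrographs.

The fluorescence background (level 300, noise σ = 40) stays far below
the lowest sweep threshold; the tested invariant measures the maximum
intensity outside every droplet's rendered support (disk plus 3σ of
PSF), since immediately adjacent to a disk the blur tail necessarily
exceeds background.

## Problem sizes and numerical choices

- Desk-scale training: 8 training + 2 validation scenes of 128² px
  with ~10 cells, 500 steps, batch 2 — a few minutes on one CPU; the
  held-out mean IoU criterion is 0.7.
- Type-I calibration: 200 simulated experiment sets (2 pseudo-strains
  from one archetype, 3 experiments × 3 fields × 12 cells at 160² px),
  quantified on ground-truth regions.  With very few cells per field
  the discreteness of counts slightly inflates the rejection rate;
  12 cells per field restores nominal behaviour.
- Power/direction: 10 independent seeds of the full design (2 strains,
  3 × 3 fields, 30 cells at 224² px), segmented through the real
  inference path on oracle maps.
- Dice ε = 1e−7; bandwidth floor 1e−4; thresholds strict as stated
  (`seed > 0.5`, membership `> 0.5`, area `> 0.5 µm²`, counts
  `≥ lower threshold`); degenerate (collinear) hulls fall back to
  extreme points; training in float32, statistics in float64.

## Known limitations

Training is the only stage that is not bit-reproducible across
platforms (BLAS summation order); its acceptance is threshold-based
(IoU), while all other stages reproduce bit-identically from a seed.
The synthetic scenes are easier than real brightfield images; the
desk-scale network and training schedule are sized for them.  The
droplet count is a relative measure by construction (dim droplets
inflate it, clusters deflate it) and is not interpreted as an absolute
LD number.
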