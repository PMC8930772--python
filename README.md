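# dropseg

Automated quantification of lipid-droplet (LD) phenotypes in budding
yeast from paired microscope fields: brightfield for cell outlines,
BODIPY-style fluorescence for droplets.  Strains carrying seipin
mutations shift from many small droplets to a few "supersized" ones
(or tight clusters), and comparing strains requires counting droplets
per cell and scoring supersized cells over hundreds of cells per
field — a job for a pipeline, not a cursor.

The package implements the full chain, exercised end to end on a
synthetic-scene generator with complete ground truth:

1. **Cell instance segmentation by spatial embeddings.**  A residual
   U-Net (batch norm after every convolution) predicts, per pixel, a
   seed score, a bandwidth σ, and a 2-D offset; the embedding of pixel
   i is `e_i = x_i + o_i`.  Training grows a Gaussian soft mask per
   cell, `φ_k(i) = exp(−‖e_i − ē_k‖²/(2σ̄_k²))`, and matches it to the
   cell's binary mask with a Dice loss.  Inference iteratively picks
   the highest-scoring unassigned seed pixel and clusters all
   foreground pixels whose kernel affinity to it exceeds 0.5.
   Instances under 300 px or touching the border are removed; convex
   hulls of the survivors become the ROIs (exported as ImageJ `.roi`
   records).  The network and Adam optimizer run on a small in-package
   autodiff engine over numpy — CPU only, no deep-learning framework
   required.
2. **Droplet counting.**  Per cell ROI, particles (8-connected
   thresholded components) are counted at descending lower thresholds
   20,000 → 2,000 in 2,000 steps (upper threshold maximal); the cell's
   droplet number is the **maximum** count over the sweep.  A cell is
   supersized-positive when a pass at lower threshold 10,000 finds a
   particle of area > 0.5 µm² (0.065 µm/px default calibration).
3. **Strain statistics.**  Three fields per strain per experiment are
   averaged into one data point; strains are compared by a one-way
   ANOVA with experiments linked as blocks
   (`F = MS_strain/MS_res` on `(s−1, (s−1)(b−1))` df) followed by
   Holm–Šidák step-down tests on preselected strain pairs
   (`p̃_(k) = 1 − (1 − p_(k))^(m−k+1)`, monotonized).

See `docs/methods.md` for the model details, parameter defaults and
design choices.

## Worked example

The numbered scripts under `analysis/` run a desk-scale version of the
study design — two strains ("wt_like": mean 8 small droplets/cell;
"null_like": mean 2 droplets with radii straddling the 0.4-µm
supersized boundary and strong clustering), 3 experiments × 3 fields ×
40 cells — through simulation, training, segmentation, quantification
and statistics:

```bash
python analysis/01_simulate_fields.py    # 18 fields + ground truth
python analysis/02_train_segmenter.py    # 500 Adam steps on 128-px crops
python analysis/03_segment_cells.py      # instances, filters, ROIs, IoU
python analysis/04_quantify_droplets.py  # threshold sweep, max rule
python analysis/05_compare_strains.py    # blocked ANOVA + Holm-Sidak
```

Output from one run (seed 20260920, as configured in
`analysis/common.py`):

```
loss 0.529 -> 0.048 over 500 steps; best validation loss 0.048 at step 500
mean IoU over 18 fields: 0.952 (648 matched, 0 missed, 0 merged)

per-strain means over fields:
           mean_ld_per_cell  pct_cells_supersized
null_like              0.89                 77.16
wt_like                5.56                  8.02

blocked ANOVA: F(1,2) = 460.330, p = 0.002165
 wt_like null_like  -69.135802  -21.455309  0.002165  0.002165  **
```

Reading: the trained segmenter recovers every generated cell at a mean
intersection-over-union of 0.95.  The wild-type-like strain averages
5.6 counted droplets per cell versus 0.9 for the null-like strain
(counts are relative, not absolute — dim droplets inflate them and
clusters merge), while 77% of null-like cells versus 8% of
wild-type-like cells contain a supersized droplet.  The blocked ANOVA
on the per-experiment supersized percentages rejects equality
(F(1,2) = 460, p = 0.0022), and the Holm–Šidák-adjusted comparison of
the preselected pair is significant at the ** level — the direction
and strength expected from the generating archetypes.

The same pipeline is scriptable via the `dropseg` CLI
(`simulate | train | segment | quantify | stats | pipeline |
fixtures`), configured by YAML, with per-stage resume and a hashed
run manifest.

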