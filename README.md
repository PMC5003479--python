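# phenoarray

Quantification pipeline for phenotypic RNAi/miRNA cell microarrays, with a
fully synthetic test bench. The package covers the whole workflow of a
reverse-transfection spot-array screen read out by three-channel fluorescence
microscopy:

- **`phenoarray.layout`** — plan printable spot grids (pitch = spot diameter +
  edge gap), compute slide capacity, scatter negative-control positions, and
  partition a reagent library across a multi-array set.
- **`phenoarray.bench`** — deterministic bench calculators: transfection-recipe
  payload concentration (well and pooled array formats) and Ct-based relative
  mRNA expression (fold = efficiency^(−ΔΔCt), reference-gene + calibrator
  normalized).
- **`phenoarray.synth`** — render ground-truthed synthetic fields: a tracer
  channel with printed spots, a nuclei channel with one blob per cell, and a
  phenotype channel whose per-cell intensity is drawn from an expressing or a
  silenced distribution according to a per-spot silenced fraction.
  Deterministic given the seed.
- **`phenoarray.spots`** — tracer-spot detection (threshold, label, hole-fill,
  diameter gate) and translation-only registration of detections to the
  expected grid.
- **`phenoarray.cells`** — nucleus segmentation (smooth → Otsu → fill →
  distance-transform watershed → area gate), per-cell phenotype measurement
  over a dilated nucleus region, and expressing/non-expressing classification
  (fixed, Otsu, or control-percentile threshold).
- **`phenoarray.stats`** — cell-to-spot association (nominal disc, nearest
  centre), per-spot percent-expressing, normalization of conditions to the
  negative control (control ≡ 100%), knockdown percent, and Student's t-tests;
  plus `quantify_array`, the end-to-end composition.
- **`phenoarray.fileio`** — 16-bit TIFF channel files with a JSON field
  manifest, GAL-dialect layout files, and CSV tables for cells, spots,
  detections and conditions.

## CLI

```sh
# plan a 9-spot demo grid and write it as a GAL file
phenoarray layout --slide-width 2300 --slide-height 2300 --margin 300 \
    --control-fraction 0.5 --seed 1 --out layout.gal

# render a synthetic field over it (per-channel TIFFs + ground truth CSV)
phenoarray simulate --layout layout.gal --seed 2 --outdir sim/

# run the full pipeline: detect, register, segment, measure, classify,
# assign, score, normalize, test
phenoarray quantify --manifest sim/sim_f000_manifest.json \
    --layout layout.gal --outdir quant/
```

Other subcommands: `detect-spots`, `report` (normalize an existing per-spot
table), `sweep` (batch over generator-parameter grids), `validate` (check a
field manifest). `-v` logs per-stage timings to stderr.

## Conventions

- Physical units are micrometres; slide origin at the top-left printable
  corner, x along the long axis.
- Pixels are 0-based (row, col), y downward; pixel index ↔ µm via
  `field_origin + index * um_per_pixel`.
- Channel TIFF names: `<run>_<field>_<560|488|635>.tif` (tracer, phenotype,
  nuclei respectively).
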