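# mabveg

Altitudinal-belt stratified automatic sample selection and object-based
vegetation classification for mountain scenes.

The package implements a full mapping pipeline driven by a mountain
altitudinal belt (MAB) table — the prior knowledge that each vegetation
formation occupies a known altitude interval on each slope of a mountain:

1. **Scene** — either user rasters (4-band image + DSM) or a seeded
   synthetic mountain scene with a ridgeline, north/south slopes,
   belt-structured classes, fuzzy belt boundaries and band noise
   (`mabveg.scene_synthesis`), so everything is testable without satellite
   data.
2. **Segmentation** — bottom-up multiresolution region merging over the
   band stack (+DSM, +texture), with mean-variance scale selection and
   per-object spectral / texture / geometric / terrain features
   (`mabveg.segmentation`).
3. **Stratification** — ridgeline extraction splits the scene into north
   and south slopes; the MAB table is rasterized into terrain constraint
   factors; objects are assigned to belts by majority cover
   (`mabveg.stratification`).
4. **Automatic sampling** — per belt: fragment filtering (area,
   length/width), clustering with k = 3 × nearby formations, selection of
   the most suitable large cluster against a per-formation prototype,
   3-sigma (Pauta) brightness purification, and iterative 2-means
   correction down to the target sample count (`mabveg.auto_sampling`).
5. **Classification** — fuzzy-membership non-vegetation masking on the
   coarse layer (NDVI×100 / brightness / DSM, fuzzy AND), class inheritance
   to the fine layer, random-forest feature ranking, F1-tuned RF/KNN
   training, scene-wide object labelling (`mabveg.classification`).
6. **Evaluation** — confusion matrices, overall/user/producer accuracy,
   Cohen's kappa, per-formation sample accuracy with slope and
   west/middle/east breakdowns, random validation points
   (`mabveg.evaluation`).

## CLI

```bash
mabveg synth --rows 256 --cols 256 --seed 7 --out scene/     # synthetic scene
mabveg segment --scene scene/ --scale 8 --out seg/           # objects + features
mabveg stratify --scene scene/ --out strat/                  # slope mask + belts
mabveg sample --scene scene/ --objects seg/ --out samples/   # sample database
mabveg classify --objects seg/ --samples samples/samples.csv --out cls/
mabveg evaluate --matrix src/mabveg/data/table4.csv          # metrics from a CSV matrix

# or everything in one seeded, reproducible run:
mabveg run --synthetic --rows 256 --cols 256 --seed 7 --out run7/
```

`run` writes all artifacts (rasters as TIFF, tables as CSV) plus a
deterministic `report.json` carrying sample accuracies per formation and
stage, overall accuracy, kappa, per-class UA/PA, the config hash and every
seed.

## Data files

`src/mabveg/data/` ships the default Taibai Mountain belt table
(`taibai_mab.yaml`: 9 belts north, 8 south) and three CSV fixtures: the
clustering-algorithm comparison table and the RF/KNN confusion matrices
used as worked examples by the evaluation tests.

## Conventions worth knowing

- Belt altitude intervals are half-open `[lo, hi)`; the summit belt is
  closed at the top so the peak is covered.
- Confusion matrices are **rows = predicted, columns = reference**; user
  accuracy is row-wise, producer accuracy column-wise.
- Region merging stops when the cheapest merge cost reaches `scale**2`;
  one merge run can snapshot several scales (`segment_multi`), which makes
  object counts exactly monotone in scale.
- All randomness flows from explicit integer seeds; identical
  configuration + seed reproduces every artifact bit-for-bit.
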