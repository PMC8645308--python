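# texturality

Predict whether the human visual system treats an image as a **texture**,
from the image's own statistics.

The pipeline:

1. **Complex steerable pyramid** (`texturality.pyramid`) — polar-separable
   frequency-domain decomposition (default 4 dyadic scales × 4 orientations),
   tight frame: the real-part pyramid reconstructs the input to machine
   precision.
2. **Full statistic set** (`texturality.ps_statistics`) — marginal moments,
   per-scale skew/kurtosis and 7×7 central autocorrelations of the partial
   lowpass reconstructions, band-magnitude means and autocorrelations, and
   within-scale / cross-scale correlation matrices of the linear (real-part)
   and energy (magnitude) subbands, with phase-doubled upsampling for the
   cross-scale terms.
3. **Summary features** (`texturality.summary_features`) — 34 labeled
   class-by-frequency variables (`power`, `skew`, `kurt`, `cpL`, `cpE`,
   `coL`, `coE` at 64/32/16/8 cycles per image, plus `cfE`/`cfL` at
   32/16/8), a 12-variable moment-only subset, logistic-correlation
   screening against behavioral response proportions, and top-k selection.
4. **Classifier** (`texturality.classifier`) — judgment binarization at
   proportion 0.5, z-scored RBF-SVM (scikit-learn backed) with published
   hyperparameter presets, stratified k-fold cross-validation, grid tuning,
   and bit-exact JSON model persistence.
5. **Synthetic stimuli + observer** (`texturality.stimuli`) — stationary
   texture generators (filtered noise, gabor fields, binarized noise, dot
   fields) vs globally structured non-textures (blob, horizon scene, big
   polygon, mirror-symmetric layout), deterministic per-seed; a logistic
   simulated observer produces per-image response proportions so every stage
   is testable without behavioral data.
6. **IO + CLI** (`texturality.io`, `texturality.cli`) — PNG/TIFF/JPEG
   luminance reading (Rec.709), ratings-CSV aggregation, feature tables,
   and the `texturality` command.

## CLI

```sh
# generate a labeled synthetic dataset (16-bit PNGs + manifest.csv)
texturality synth --n 100 --seed 1 --out data/

# 34-variable summary feature table
texturality summarize --images data/manifest.csv --out features.csv

# screen features against ratings (columns: image_id, observer_id, task,
# response — or an aggregated dialect with a proportion column)
texturality screen --features features.csv --ratings ratings.csv \
    --task texturality --out screen.csv

# cross-validated accuracy with a published hyperparameter preset
texturality cv --features features.csv --ratings ratings.csv \
    --preset texturality_top6 --out cv.json

# train, then predict labels + decision values for new images
texturality train --features features.csv --ratings ratings.csv \
    --box-constraint 10 --kernel-scale 1 --out model.json
texturality predict --model model.json --features features.csv --out pred.csv

# bundle a run into one JSON
texturality report --cv-report cv.json --screen-table screen.csv \
    --manifest data/manifest.csv --out report.json
```

All commands honor `--seed`, `--config` (YAML/JSON overriding the defaults:
pyramid geometry, selection k, folds, preset, ...) and `--verbose`; each
writes its resolved configuration next to its outputs.

## Conventions

- Scales are 1-indexed finest-first; scale *s* of a 256-pixel image maps to
  the band at 256/2^(s+1) cycles per image.
- Moments are population moments, kurtosis non-excess (Gaussian → 3);
  zero-variance maps report skew 0 / kurtosis 3 / zero correlations.
- Kernel scale is the Gaussian width σ in `exp(-‖u-v‖²/σ²)`
  (scikit-learn `gamma = 1/σ²`).
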