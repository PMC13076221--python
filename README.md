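# lipidspec

Analysis toolkit for mid-infrared hyperspectral lipid imaging, with a
synthetic-data generator standing in for the instrument. It covers:

- **Band catalog** (`lipidspec.bands`): 22 assigned vibrational bands
  (C–H stretching and fingerprint blocks) with named wavenumber-subset
  presets (`all22`, `ch7`, `fp15`, `lda6`, scan windows).
- **Synthetic data** (`lipidspec.simulate`): Lorentzian-band endmember
  spectra (Chol, DOPC, SM, water, carbon tape, sucrose, a cyclodextrin–
  cholesterol complex, DOPE, S1P), a four-well phantom hypercube with
  per-band gain drift and additive noise, vesicle mixture spectra at
  configurable molar ratios, and cell time-series spectra with injected
  band enrichment — all seeded and carrying ground truth.
- **Preprocessing** (`lipidspec.preprocess`): per-band normalization to a
  flat carbon-tape reference, per-pixel L1 normalization, and the
  five-step single-spectrum chain (offset subtraction, endpoint
  normalization, cubic-spline resampling, medium subtraction, max
  normalization) with an append-only processing log.
- **Unmixing** (`lipidspec.unmix`): per-pixel non-negative least squares
  against an L1-normalized endmember library, crosstalk quantification
  along well profiles, and ternary (simplex) composition estimation.
- **Classification** (`lipidspec.classify`): LDA projection of labeled
  spectral pixels and stratified k-fold cross-validated classification
  with confusion matrices over wavenumber subsets.
- **Statistics** (`lipidspec.stats`): contrast-to-noise ratio, band AUC,
  enrichment percent change, two-sided paired t-test, KDE violin/box
  summaries, spectral correlation, and micrograph cell-intensity
  extraction (Otsu segmentation).
- **IO + CLI** (`lipidspec.io`, `lipidspec.cli`): plain-text CSV spectrum
  and cube-directory formats with provenance, and a `lipidspec` command
  tying the stages together.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(catalog bookkeeping, noiseless unmixing exactness, classification
accuracy, enrichment recovery, oracle and property suites).

## CLI

```sh
lipidspec simulate phantom --seed 7 --out phantom/          # cube directory
lipidspec preprocess --cube phantom/ --out pre/             # reference + L1
lipidspec unmix --cube pre/ --out abundances/               # NNLS + crosstalk
lipidspec classify --cube pre/ --subset fp15 --folds 5 --out confusion.csv
lipidspec simulate cells --scenario cells_chol --seed 1 --out cells/
lipidspec stats auc --spectrum s.csv --band 1484:1424
lipidspec report --seed 0 --out report.json                 # full chain bundle
```

## Layout

```
src/lipidspec/
  bands.py          band catalog + subset presets
  core.py           WavenumberGrid / Spectrum / HyperCube types
  simulate/         endmembers, phantom, vesicles, cells, micrographs
  preprocess.py     cube + single-spectrum preprocessing chains
  unmix.py          NNLS unmixing, crosstalk, ternary composition
  classify.py       LDA projection and cross-validation
  stats.py          scalar spectral statistics
  io.py, cli.py     text formats and command line
  data/             band catalog CSV + endmember spec files
```
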