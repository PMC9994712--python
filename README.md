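# phascreen

Analysis toolkit for high-throughput screening of bacterial
polyhydroxyalkanoate (PHA) production. It covers the five stages of a
plate-scale screening workflow, plus a synthetic-data generator so every
stage is testable without instrument files:

- **ftir_spectra** — whole-cell FTIR analysis: spectral CSV/JCAMP-DX input,
  amide-I anchored normalization (0.5 AU at 1650 cm⁻¹), linear baseline
  correction, band integration with per-region endpoint-chord baselines,
  carbonyl-ester peak localization, the carbonyl-to-amide-I (CA1) area
  ratio, and scl/mcl-PHA classification from the peak position (boundary
  1733 cm⁻¹, configurable). Built-in band-region profiles for an ATR
  instrument (`cary`: carbonyl 1705–1763, amide I 1580–1705 cm⁻¹) and a
  high-throughput transmission unit (`hts_xt`: 1710–1772, 1600–1710 cm⁻¹).
- **growth_kinetics** — per-well growth metrics from OD600 kinetics:
  maximum specific growth rate (max d ln OD/dt via a GCV smoothing spline,
  optional Gaussian-process smoother), its time point, trapezoidal AUC on
  raw OD (log-AUC behind a flag), and smoothing MSE; box-plot-fence outlier
  flags; group-vs-control comparisons (±2 SD band rule and Welch t-test).
- **biolog_phenotype** — phenotype-microarray (PM1) kinetics: no-carbon
  control subtraction, replicate-plate averaging, substrate utilization
  calls at net-absorbance cutoffs 0.15/0.30/1.00 (strict inequality on the
  maximum over time), heatmap export. The standard PM1 well→substrate map
  ships with the package.
- **media_design** — "C:N" ratios as mol acetyl-CoA equivalents per mol
  nitrogen, with a packaged 15-substrate reference table, and the inverse
  calculation (concentration needed for a target ratio).
- **pha_quant** — GC-FID external-standard calibration (through-origin by
  default) and monomer weight-percent-of-CDW quantification with
  hierarchical replicate summaries (technical → biological → experiment).
- **synthetic_data** — seeded generators: Gaussian-band spectra on affine
  baselines, logistic growth curves with lag, and 96-well formazan kinetic
  plates with a shared background trace.
- **pipeline_cli** — stage orchestration from a YAML config, a complete
  synthetic demo study with ground-truth manifest, and a combined JSON
  report.

## CLI

```bash
phascreen demo --seed 1 --out demo/          # write a synthetic study
phascreen run --config demo/config.yaml      # run every configured stage
phascreen ftir --profile hts_xt --spectra demo/spectra \
    --layout demo/spectra_layout.csv --out out/ftir
phascreen growth --plate demo/plates/growth_plate.csv \
    --layout demo/growth_layout.csv --out out/growth
phascreen biolog --plates demo/plates/biolog_rep0.csv --layout pm1 \
    --cutoffs 0.15,0.30,1.00 --out out/biolog
phascreen media --medium MM_PHA1 --out out/media
phascreen quant --calibration demo/tables/gc_calibration.csv \
    --samples demo/tables/gc_samples.csv --out out/quant
phascreen simulate spectra --seed 1 --out sims -n 5
```

File formats: spectra are two-column CSV (`wavenumber_cm-1,absorbance`;
descending grids accepted, JCAMP-DX XYDATA read-only); kinetic plates are
CSV with a `time_h` column followed by well columns `A1`..`H12`; layouts,
substrate tables and GC tables are plain tidy CSV.

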