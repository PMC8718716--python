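# lakechl

A tested, reusable pipeline for satellite lake-chlorophyll analysis:

* **Quality-flag masking** — an 11-bit per-pixel flag vocabulary (water /
  cloud / cloud buffer / cloud shadow / cirrus / processor out-of-scope and
  out-of-range diagnostics / shoreline-shallow-water buffer) and the
  valid-pixel predicate: both required flags raised, no exclusion flag raised.
* **Shoreline & shallow-water exclusion** — inward 120 m shoreline buffer on
  the lake outline plus removal of areas shallower than the 95% quantile of
  the Secchi-depth record, rasterized to the 60 m scene grid.
* **Match-up selection** — in-situ samples paired with scenes within ±24 h;
  the 3×3 macropixel centred on the station must have ≥ 6 valid pixels whose
  population standard deviation is < 20% of their median; the satellite value
  is the mean of the valid pixels.
* **Regional calibration** — chlorophyll from absorption components,
  `Chl = A·(a_pig + B·(a_det + a_cdom))^C` with canonical coefficients
  (21, 0.77, 1.04); refitting by bounded nonlinear least squares on log(Chl),
  with r² and RMSE reported on the linear scale.
* **Patchiness composites** — for each scene covering ≥ 50% of the valid-water
  area, pixels within ±5% of the scene's Q50/Q25/Q75 are flagged; accumulated
  over the series this yields per-pixel relative-frequency maps (%) that
  identify representative sampling areas.
* **Synthetic mode** — lake geometries with bathymetry, IOP scene series with
  a known planted spatial pattern (IOPs invert the calibration model exactly),
  cloud/flag contamination, Secchi records and in-situ surveys, so the whole
  chain runs and is testable without any download.

## CLI

```sh
lakechl run all --outdir out --seed 7            # full synthetic end-to-end
lakechl run simulate --outdir out --config my.yaml
lakechl run mask     --outdir out                # valid-water mask + flags
lakechl run matchup  --outdir out                # QC'd match-up table (CSV)
lakechl run calibrate --outdir out               # coefficient refit (JSON)
lakechl run patchmap --outdir out                # 3-band composite GeoTIFF
lakechl show-config
```

Every stage writes per-stage record counts and the configuration hash into
`out/provenance.json`; reruns with the same seed are byte-identical.
Configuration defaults (buffer distance 120 m, Secchi quantile 0.95, ±24 h
window, 3×3 macropixel, ≥6 valid, 20% homogeneity, ±5% bands, 50% coverage,
coefficients 21/0.77/1.04) can be overridden via `--config config.yaml`.

## Layout

```
src/lakechl/
  grid.py            raster georeference + Scene container
  flags.py           flag bitmask vocabulary, valid-pixel rule, cloud buffer
  geometry.py        shoreline buffer, Secchi exclusion, valid-water mask
  matchup.py         time pairing, macropixel extraction, homogeneity QC
  calibration.py     chlorophyll-from-IOPs model, refit, diagnostics
  spatial_stats.py   scene quantiles, ±5% bands, frequency composites
  synthetic_data.py  lakes, truth fields, scenes, surveys, Secchi samples
  io.py              netCDF / CSV / GeoTIFF / GeoJSON readers and writers
  pipeline.py, cli.py  stage orchestration and command line
tests/               unit, property and acceptance suites
```
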