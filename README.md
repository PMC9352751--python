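# vegidx

Near-real-time vegetation-index production for agricultural drought
monitoring: from RED/NIR surface-reflectance rasters to daily NDVI,
weekly/biweekly maximum-value composites, per-pixel multi-year
climatologies, and the anomaly indices VCI, MVCI, RMVCI and RVCI,
encoded to an 8-bit raster product format with the operational
WMS/WCS naming convention.

It is written for people who run (or want to emulate) an operational
MODIS-style crop-condition service: remote-sensing engineers producing
weekly index maps over an area of interest, and analysts who need the
product conventions — byte scalings, no-data sentinel, week numbering,
layer names — reproduced exactly.

## The indices

With NIR and RED the surface-reflectance digital numbers (valid range
−100..16000 in the MOD09GQ convention),

```
NDVI  = (NIR − RED) / (NIR + RED)                       ∈ [−1, 1]
```

Weekly/biweekly NDVI is the **maximum value composite** (MVC): the
per-pixel maximum of the daily NDVI grids within an ISO week (or pair of
weeks), which suppresses cloud- and haze-depressed lows. From the
multi-year archive of composites, per pixel and week-of-year:

```
VCI   = (NDVI − NDVI_min) / (NDVI_max − NDVI_min)       ∈ [0, 1]
MVCI  = (NDVI − NDVI_mean)   / NDVI_mean
RMVCI = (NDVI − NDVI_median) / NDVI_median
RVCI  = (NDVI − NDVI_prev_year) / NDVI_prev_year
```

where min/max/mean/median are taken over the archived years for the same
week slot. The ratio indices are clamped at ±125%. Products are stored
as 8-bit bytes: NDVI via `round(v·125 + 125)`, VCI via `round(v·250)`,
the ratio indices via `round(v·100 + 125)` saturating at 0 and 250;
byte 255 marks no data and 251–254 never occur.

## Worked example

A three-year synthetic archive (the built-in generator produces
MOD09GQ-like scenes with a seasonal NDVI curve, spatial gradient,
inter-annual variability and optional cloud masks), run end to end:

```python
from vegidx import run_pipeline

cfg = {
    "input": {"synth": {"years": [2019, 2020, 2021], "n_rows": 64, "n_cols": 64}},
    "output_dir": "products",
    "seed": 7,
    "products": ["NDVI", "VCI", "MVCI", "RVCI"],
}
res = run_pipeline(cfg)
```

This writes 470 weekly GeoTIFFs and records 158 per-product failures —
the expected ones: no anomaly index can be derived for 2019 (the
archive's first year has no reference years), and week 53 of 2020 has no
week-53 reference in the 52-week year 2019. Decoding the 2021 week-23
products:

```
NDVI-WEEKLY_2021_23_2021.06.07_2021.06.13.tif: mean +0.682
VCI-WEEKLY_2021_23_2021.06.07_2021.06.13.tif:  mean +0.000
MVCI-WEEKLY_2021_23_2021.06.07_2021.06.13.tif: mean -0.134
RNDVI-WEEKLY_2021_23_2021.06.07_2021.06.13.tif: mean -0.085
```

Under this seed 2021 drew the lowest inter-annual level, so the scene
sits at the very bottom of its 2019–2020 envelope (VCI pinned at 0 —
severe drought relative to the archive), 13.4% below the multi-year mean
(MVCI) and 8.5% below the previous year (RVCI). Note the layer names:
RVCI and RMVCI keep their operational aliases `RNDVI` and `RMNDVI`.

The same pipeline is scriptable from the shell:

```
vegidx synth -o scenes/ --years 2021 --seed 7
vegidx ndvi scenes/red_2021-06-07.tif scenes/nir_2021-06-07.tif --date 2021-06-07 -o daily/
vegidx run config.yaml
vegidx name vci weekly 2021 23     # -> VCI-WEEKLY_2021_23_2021.06.07_2021.06.13
vegidx encode NDVI 0.0             # -> 125
```

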