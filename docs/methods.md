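# Methods

## Production chain

The pipeline mirrors an operational near-real-time vegetation-index
service: daily RED/NIR surface-reflectance scenes are validated against
the MOD09GQ digital-number range (−100..16000), mosaicked onto a common
lattice and clipped to an area of interest; daily NDVI is computed per
pixel; weekly/biweekly NDVI is the maximum value composite (MVC) over
the slot's daily grids; a multi-year archive of composites supplies
per-pixel, per-week-of-year min/max/mean/median reference fields; and
the anomaly indices VCI, MVCI, RMVCI and RVCI are derived, quantized to
8 bits and written as GeoTIFFs named by the operational layer
convention.

Assumptions worth stating explicitly:

* All grids in one run share a pixel lattice and CRS; the tool does no
  reprojection or resampling. The CRS is an opaque identifier it
  preserves, never interprets.
* Compositing operates on raw (unencoded, floating) NDVI; quantization
  happens exactly once, at product writing.
* A pixel's validity is binary. Cloud/fog/no-data screening beyond the
  input validity mask and the MVC's own robustness is out of scope.

## Calendar

Weekly slots are ISO-8601 weeks (Monday start; a year has 52 or 53
weeks, and a date near the year boundary belongs to its ISO year, so
2021‑01‑01 falls in week 53 of 2020). The first week of 2021 therefore
starts on Monday 2021‑01‑04, matching the operational products' week
numbering, and "files per year" counts ISO weeks. Biweekly slots pair
consecutive ISO weeks (1,2), (3,4), …; an unpaired week 53 forms a short
final 7-day period. Daily products are grouped by calendar year (365 or
366 per year), which is the one place the daily and weekly calendars
deliberately differ, as the operational naming does.

The climatology archive always exposes 53 week slots so the set of
multi-year reference layers is fixed; slot 53 is simply empty for years
without it.

## Quantization

* NDVI: `byte = round(v·125 + 125)`, v clamped to [−1, 1] first.
* VCI: `byte = round(v·250)`, v clamped to [0, 1] first (a near-real-time
  composite can exceed the archived extremes).
* MVCI/RMVCI/RVCI: `byte = round(v·100 + 125)` with hard saturation at
  0 (v ≤ −1.25) and 250 (v ≥ +1.25).

Rounding is nearest-integer with ties away from zero, so each byte bin's
decoded center is unbiased; truncation would bias every decoded value by
half a step. Decoding inverts the affine maps; saturated ratio bytes
decode to ±1.25 (the original magnitude is unrecoverable by design).
Bytes 251–254 are declared invalid and rejected on read. The decode∘encode
error bound is half a quantization step: 1/250 for NDVI, 1/500 for VCI,
1/200 for the ratio indices.

## Degenerate inputs and tie-breaks

* NDVI with NIR+RED = 0: masked (no index exists).
* VCI with max = min, and ratio indices with a zero reference: masked
  rather than forced to a number — no meaningful anomaly exists there,
  and 255 in the product says so.
* Mosaic overlaps: the first valid value in input order wins. Any
  deterministic rule would do; this one is trivially testable and lets
  callers express priority by ordering tiles.
* RVCI for week 53 of a year whose predecessor has 52 ISO weeks falls
  back to the predecessor's week 52 (logged).
* A composite built from fewer days than its slot spans is produced, and
  `n_days` on the grid records the count so callers can enforce a
  completeness policy (the operational practice is to publish once the
  slot's dailies are complete).

## Reference policy

The multi-year references for MVCI/RMVCI (and the VCI envelope) default
to the years strictly before the current product year: a reference that
contains the year being judged damps its own anomaly. A policy switch
(`include_current`) exposes the alternative reading. The archive keeps
every per-year composite grid rather than running summaries — the median
cannot be updated from sums, and retaining the grids makes the
incremental `update` path bitwise-identical to a batch rebuild, which
the tests assert. Persisted archives store the per-year composites as
float32 rasters (internal precision) and only the derived reference
fields as 8-bit products, so derived indices do not inherit quantization
error from the archive.

## Synthetic scenes

The generator produces the ground-truth NDVI field

    truth(x, y, d) = base + amplitude·sin(2π(doy − phase)/365)
                   + gradient·(x-ramp) + year_offset + ε

with defaults base 0.5 and amplitude 0.3 (the common vegetated NDVI
range 0.2–0.8), phase day 109 (seasonal peak near day 200, a
mid-latitude summer), an east–west ramp of total width 0.1 (fields are
not spatially flat), per-pixel daily Gaussian noise with σ = 0.02, and
per-year level offsets spread evenly over ±0.08 and assigned to years in
a seed-shuffled order. The inter-annual offsets are essential, not
decorative: without them every year repeats the same curve, the
historical min/max envelope collapses, and VCI is undefined everywhere.
The spread (±0.08) is of the order of year-to-year NDVI variability in
cropland and guarantees a non-degenerate envelope for the recovery
tests.

Truth fields invert exactly to integer reflectance pairs with a chosen
band sum (default 8000 DN), so NDVI computed from the synthetic scene
reproduces the truth to within 1/band-sum. Clouds are contiguous blobs
obtained by thresholding a Gaussian-smoothed noise field at the
requested coverage quantile, which pins the masked fraction to the
request and is deterministic given the seed and date; per-date random
streams are derived from (seed, ordinal date) so a scene never depends
on generation order.

What the generator does not emulate: radiative-transfer and BRDF
effects, view/sun geometry, spatially correlated sensor noise, snow and
water, or the MODIS sinusoidal tiling. Pipeline tests passing on these
fields demonstrate that the bookkeeping — masks, compositing,
climatology, encodings, naming — is correct, not that real-scene
retrievals are accurate.

## Problem sizes and determinism in the test suite

Property suites run on 128×128 grids: the MVC suite over 14 synthetic
days, the incremental-vs-batch climatology oracle over a 5-year weekly
archive (260 composites), and the end-to-end VCI recovery over a 3-year
archive. These sizes keep a full run in seconds while leaving tens of
thousands of pixels per assertion. The VCI recovery run uses zero noise
and zero clouds with a band sum of 16000 DN, so the NDVI inversion error
(≤ 1/16000) amplified by the envelope width stays below one VCI
quantization step and the encoded pipeline product must match the
truth's byte within 1. The cloud-cover monotonicity check also uses zero
noise: with noise the composite's max-statistic overshoot and the
cloud-induced undershoot mix, and no ordering is guaranteed; without it
the error is a pure undershoot that shrinks as cover shrinks. All
randomized tests are seeded (hypothesis runs derandomized).

## Known limitations

* No reprojection: inputs must share a lattice; MODIS sinusoidal tile
  handling and granule ingestion are out of scope.
* The AOI polygon test is pixel-center containment, not area-weighted.
* Idempotent re-runs are detected by output-file existence, not content
  hashing; touching an output forces nothing, deleting it forces a
  recompute.
* The ratio indices saturate at ±125% by design; magnitudes beyond that
  are unrecoverable from products.
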