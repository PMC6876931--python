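# ecgdigitize

Convert raster images of printed/scanned 12- or 13-lead ECG records into
calibrated digital signals (time in ms, voltage in mV), with PQRST
fiducial detection, interval measurement, and correlation-based
validation against reference signals.

The pipeline:

1. **image_io** — load PNG/JPEG, Rec.601 luminance, 3x3 median denoise.
2. **roi** — locate one bounding box per lead by sliding 5-row/5-column
   standard-deviation masks (half-max peak rule, 5% minimum spacing,
   left-margin scan over the first 10% of columns, vertical-flip for the
   right half).
3. **trace** — per lead: Otsu threshold x 1.2, 8-connected small-object
   removal, Hough near-horizontal centerline, iterative path growth from
   the centerline (<= 20 dilations), farthest-pixel fallback, linear gap
   interpolation, span-5 peak-preserving smoothing.
4. **calibration** — find the reference pulse left of aVF (search box:
   60% of the aVF box height, width 75% of that height), measure mV/px
   and ms/px from the binarized step, apply to the path.
5. **fiducials** — Pan-Tompkins QRS detection, P = nearest peak before
   Q, T = highest peak within 400 ms after S; PR/QRS/QT/RR intervals.
6. **validation** — resample both members of a pair to 1000 points,
   Pearson correlation, batch mean/SD, interval correlations, p-values.
7. **synthetic** — ground-truthed renderer: Gaussian-bump PQRST beats
   drawn as a printed two-column page with grid, calibration pulse,
   delimiter ticks, stray glyphs, and scan-like noise. Used by the test
   suite so no external data is needed.

## CLI

```sh
# render a synthetic ground-truthed page
ecgdigitize render --seed 1 --out-dir rendered/

# digitize a page image into per-lead CSVs + metadata + overlay
ecgdigitize digitize rendered/page.png --out-dir digitized/

# validate digitized CSVs against references via a manifest
# (CSV with columns: reference,digitized,lead)
ecgdigitize validate manifest.csv --out report.json
```

Useful `digitize` flags: `--n-leads {12,13}`, `--rhythm-lead II`,
`--pulse-mv/--pulse-ms` (calibration pulse physical constants),
`--scale-mv-per-px/--scale-ms-per-px` (manual fallback scale),
`--config cfg.json` (any `RunConfig` constant).

## Library use

```python
from ecgdigitize import cli, synthetic

spec = synthetic.SyntheticSpec(seed=1, heart_rate_bpm=72)
img, truth = synthetic.render(spec)
result = cli.digitize_page(img)
sig = result.leads["II"].signal     # t (ms), v (mV)
```
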