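# woolscale

Wool-fibre cuticle scale morphometry and acid-dye diffusion kinetics.

From a grayscale micrograph of a single straight fibre (plus a µm-per-pixel
scale), the package measures:

* **fibre diameter** — mean of 50 chords perpendicular to the fibre axis;
* **total scale perimeter per 100 µm** — chain-code length of the thinned
  scale-boundary skeleton, per 100 µm axial window;
* **visible-scale count** — connected scale regions per window, a fully
  visible scale counting 1 and a partially visible one 0.5;
* **SPI (scale perimeter index)** — perimeter per 100 µm divided by diameter;
* **scale-pattern class** — coronal (< 25 µm), coronal-reticulate (25–50 µm)
  or reticulate (> 50 µm).

From dye-bath uptake time series it estimates the **apparent diffusion
coefficient** D via the early-phase finite-bath relation
Mt/Me = 4·√(D·t/(π·r²)): a through-origin least-squares slope k of Mt/Me on
√t (seconds), restricted to Mt/Me below a cutoff (default 0.5), gives
D = k²·π·r²/16. Replicates are aggregated as mean ± standard error.

A correlation layer fits the no-intercept quadratic perimeter-vs-diameter
model y = a·x + b·x², checks SPI against diameter-banded reference ranges,
fits breed-level D-vs-morphology lines, and validates new fibres against the
fitted framework.

Because no image or dye-bath data ship with the package, `woolscale.synthetic`
generates seeded fibre rasters with exact analytic ground truth (boundary
length and scale count per window) and Fickian uptake series (early-time law
or exact Bessel-series cylinder solution), so the whole pipeline is testable
offline.

## CLI

```sh
# synthesize a fibre image (+ .json scale sidecar and .truth.json)
woolscale simulate-image --diameter 36 --pattern coronal_reticulate \
    --scales-per-100um 10 --out fibre.png

# measure it
woolscale measure --image fibre.png --out results/

# synthesize an uptake series and fit D
woolscale simulate-uptake --d-true 5e-10 --radius-um 36 --out uptake.csv
woolscale kinetics --uptake uptake.csv --bath uptake.bath.json --cutoff 0.5

# correlation model over a per-fibre table, prediction, validation
woolscale correlate --table fibres.csv --out model.json
woolscale predict --model model.json --diameter 36
woolscale validate --measurement welsh.csv --model model.json

# full pipeline (measure -> correlate -> kinetics) with plots
woolscale run --images a.png --images b.png --images c.png --out results/
```

Images need a JSON sidecar `<stem>.json` with `{"um_per_px": ...}`; physical
units are mandatory. Uptake CSVs carry `time_min` plus one of `mt_mg_g`,
`ce_mg_ml` or `absorbance` (the last requires a calibration in the bath
JSON), with an optional `replicate_id` column.

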