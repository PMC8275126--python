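# orgakit

Quantification toolkit for fish retinal-organoid time-lapse imaging:

- **synth** — synthetic-data generators with ground truth: sigmoidal
  fluorescence-onset cohorts, organoid image pairs (bright-field disk +
  1–4 fluorescent expression domains), and 3D nuclear tracks that switch
  from Brownian diffusion to radially directed migration, plus a Gaussian
  spot renderer producing calibrated movies.
- **onset** — reporter-expression onset per aggregate (maximum of the
  first derivative of the normalized intensity trace) and cohort
  summaries (mean ± SEM).
- **quantify** — morphometry on single images: minimum-method
  auto-threshold, organoid area, expression-area fraction, domain
  counting (8-connected components) and largest-circumference
  measurement via a sub-pixel contour.
- **tracking** — Laplacian-of-Gaussian spot detection with sub-pixel
  refinement and a simple linear tracker (greedy mutual nearest
  neighbour inside a hard distance gate, no gap closing).
- **motility** — time-averaged and ensemble MSD, a constrained fit of
  `MSD(τ) = 2·dim·D·τ + (v·τ)²` with diffusive/directed/mixed regime
  classification, normalized velocity autocorrelation, and a
  persistence-based estimator of the diffusive-to-directed switch time.
- **directionality** — outward/inward/static classification of tracks
  relative to the organoid centre, fraction summaries with binomial CIs,
  and angular histograms split by class.
- **stats** — two-sided Mann–Whitney U (exact for small tie-free
  samples) with significance-star annotation, and run-report assembly.
- **io / cli** — calibrated multi-page TIFF, TrackMate-dialect track
  CSVs, trace CSVs, YAML configs, and a `orgakit` command-line pipeline.

All interchange uses physical units (μm, hours; frame intervals in
minutes). Identical configurations (including the seed) produce
bit-identical outputs.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter
recovery on synthetic data at stated tolerances). One criterion —
rank-sum group separation at p < 0.001 in ≥ 90 % of replicates — is
implemented faithfully but is not attainable with the configured cohort
spreads and is expected to fail; everything else passes.

## CLI

```bash
# generate a fixture from a bundled preset
orgakit simulate --preset medaka-onset --seed 1 --out fix/

# onset detection on a trace table (id, time_h, intensity)
orgakit onset --traces fix/traces.csv --out out/

# morphometry on an image pair
orgakit simulate --preset morphometry --seed 1 --out fix4/
orgakit quantify --bright-field fix4/bright_field.tif \
                 --fluorescence fix4/fluorescence.tif --out out4/

# migration pipeline: simulate -> link -> motility -> direction -> report
orgakit simulate --preset migration --seed 1 --out fix5/
orgakit track --detections fix5/tracks.csv --max-disp-um 25 --out trk/
orgakit motility --tracks trk/tracks.csv --switch-time-h 10 --out run/
orgakit direction --tracks trk/tracks.csv --out run/
orgakit report --run-dir run/ --out report.json
```

Presets: `medaka-onset`, `medaka-embryo-onset`, `zebrafish-onset`,
`zebrafish-embryo-onset` (30-min frames), `morphometry`, `migration`
(15-min frames, 4600 cells, regime switch 10 h into a movie starting at
24 h post-aggregation).

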