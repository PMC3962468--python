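# choropoint

Quantitative topographic colocalization between marked lesion point patterns
(e.g. reticular pseudodrusen centers marked on infrared-reflectance fundus
images) and a binarized choroidal-vessel map derived from an en face OCT
C-scan, with a count-matched random-dot null and paired cohort inference.

The per-eye pipeline:

1. **preprocess** — extract one point per paint-mark on the marked IR image
   (connected-component centroid, 4/8-connectivity), threshold the C-scan
   into a vessel/stroma map (vessel iff intensity ≤ 60 by default), and
   remove artifact regions (retinal-vessel shadows) from the analysis region.
2. **distance_field** — exact Euclidean distance transform to the nearest
   vessel pixel; stroma points are binned by the pixel ceiling of their
   distance into 1–3 px, 4–6 px, and ≥7 px classes (10 μm/pixel at the
   default export geometry).
3. **colocalization** — per-eye counts and percentages for observed lesions
   and a count-matched uniform-random control set drawn from the same
   analysis region (**null_model**).
4. **cohort_stats** — mean ± SEM across eyes and one-tailed paired Student
   t-tests of observed vs control percentages, with fixed a-priori
   directions recorded in the output.
5. **calibration** — scan-protocol geometry (native A/B-scan spacings,
   exported-raster micron-per-pixel scale, pixel↔micron conversion).
6. **synthetic_data** — a generator of complete synthetic "eyes" (tubular
   vessel networks, exclusion strips, lesion point sets with tunable vessel
   affinity, marked-IR rasters) with known ground truth and closed-form
   expectations, used throughout the test suite in place of patient imagery.

Coordinate convention everywhere: 0-based `(row, col)`, row 0 at the top.
Masks are written as 8-bit rasters with foreground = 255.

## CLI

```sh
# generate a synthetic cohort (one directory per eye + a ready-to-run config)
choropoint simulate --out-dir sim/ --n-eyes 17 --seed 1 --affinity 5

# analyze a single co-registered (marked IR, C-scan) pair
choropoint analyze-eye --marked sim/eye00/marked_ir.png \
    --cscan sim/eye00/cscan.png --exclusion sim/eye00/exclusion.png --seed 1

# run the whole cohort: per-eye JSON, cohort CSV, summary, manifest
choropoint analyze-cohort --config sim/cohort_config.yaml --out-dir results/
```

Eyes with fewer than 50 included lesions are skipped (configurable
`min_lesions`); every eye's status and reason land in `manifest.json`.
Exit codes: 0 ok, 1 partial (eyes skipped but cohort summarized), 2 fatal.

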