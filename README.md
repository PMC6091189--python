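# musclehca

High-content analysis of immunofluorescently stained skeletal-muscle
cross-sections.

From a laminin (basal-lamina) channel the pipeline segments every muscle
fiber of a section, applies two quality controls (whole-section
segmented-area ratio with a user artifact tolerance; removal of fibers with
cross-sectional area above mean + 3 SD), and derives four regions of
interest per fiber whose margins scale with the minimum Feret diameter:

| ROI | definition | used for |
| --- | --- | --- |
| `roi_f`   | the fiber mask | morphometry, typing |
| `roi_cnf` | erosion by minFeret/5 (central zone) | centronuclei |
| `roi_sc`  | `roi_f` minus `roi_cnf` (sub-laminal annulus) | satellite cells, peripheral myonuclei |
| `roi_v`   | dilation by minFeret/8, outside all fibers | vessels |

On top of this geometry it quantifies, per fiber and per section:

- **morphometry** — CSA, min/max Feret diameter (rotating calipers),
  circularity, gravity center;
- **centronucleation** — DAPI nuclei detected by background subtraction +
  threshold + distance-transform watershed; a fiber is centronucleated when
  a nucleus centroid falls in `roi_cnf`; peripheral myonuclei counted in
  `roi_sc`; 4-bin distribution (0/1/2/≥3 centronuclei);
- **satellite cells** — Pax7 blobs accepted when ≥ 90% of their area
  overlaps the nuclei mask *and* the centroid lies in some fiber's
  `roi_sc`; density per mm²; minimum satellite–vessel distances;
- **vessels** — CD31 blobs counted per fiber in `roi_v` (overlapping bands
  of adjacent fibers may share a vessel), plus unique-object density per
  mm² and % of section area;
- **fiber typing** — up to three intrafiber stainings thresholded at
  background mode + k·robust-sigma of non-fiber tissue pixels; labels by
  positive-set cardinality (0 → IIX, 1 → I/IIA/IIB, 2 → hybrid, 3 → ND);
- **in situ cartographies** — the section repainted per fiber class for
  CSA (8 green octile bins), centronuclei (white/yellow/orange/red),
  vessels (6 purple classes), satellites (white/light/dark pink) and fiber
  type, with optional burned-in legends, saved as JPEG + PNG.

Everything is testable without external data: `musclehca.synthetic`
generates calibrated multichannel sections (centroidally relaxed random
tessellation, planted nuclei/Pax7/CD31 blobs, per-fiber type intensities)
with complete per-fiber ground truth, and `degrade` produces controlled
artifacts for the QC paths.

## CLI

```sh
musclehca run --config cfg.toml \
    [--input DIR --output DIR --features cnf,typing \
     --cartography csa,centronuclei --artifact-tolerance 0.1 --seed 42]
```

with a TOML config such as

```toml
input_dir = "images/"          # folder of TIFFs (multichannel, or z-stacks)
output_dir = "results/"
scale_um_per_px = 0.325        # omit to read from TIFF metadata
features = ["morphometry", "cnf", "satellites", "vessels"]
cartographies = ["csa", "centronuclei"]
artifact_tolerance = 0.10

[channels]                     # role -> 0-based channel index
laminin = 0
dapi = 1
pax7 = 2
cd31 = 3
```

A run creates four folders in the output directory — `Artefacts` (images
rejected by QC or quarantined after errors), `Cartography`, `Results by
file` (tab-delimited per-fiber tables + per-object CSVs) and `ROI` (zipped
ImageJ-compatible polygon archives per image) — plus a
`RunGlobalResult_<run id>.txt` summary table (one row per image) and a
`RunLog_<run id>.txt` with every configuration value and the per-channel
typing thresholds.

`musclehca synthesize --output DIR --n-images 3 --seed 1` writes synthetic
sections (TIFF + truth CSVs) that the `run` command can consume directly.

## Acceptance

The acceptance criteria are property-based (recovery of planted ground
truth on synthetic sections at stated tolerances) and live in
`tests/test_acceptance.py`. The report script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

exercises the full pipeline on seeded synthetic data and prints recovery
diagnostics; since no published headline number is recomputable without the
original microscopy images, the JSON report contains no target entries.
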