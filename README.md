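# synquant

Single-cell quantification of B-cell immune-synapse imaging.

When a B cell meets antigen, the B-cell receptor (BCR) triggers actin
remodeling, antigen internalization and downstream signalling.  Comparing
control cells with cells lacking an adaptor such as BCAP requires turning
multi-channel fluorescence images of single cells into numbers: where does
the antigen sit relative to the cell boundary, has the actin cup around an
antigen-coated bead cleared, how much NF-κB has moved into the nucleus, how
fast does surface-stained receptor disappear.  `synquant` implements these
measurements as a tested, scriptable pipeline for anyone quantifying
immune-synapse or endocytosis phenotypes from single-cell microscopy —
together with a synthetic scene generator with exact ground truth, so every
measurement is validated by parameter recovery rather than by eye.

## What it measures

For a segmented cell with centroid *c*, per-ray boundary distance
*R(θ)* and a channel intensity *I(x)*:

* **Clock-scan radial profile** — intensity sampled along rays from *c*,
  each ray normalized so its boundary crossing is 100%, scanned to 120%;
  reported both as the per-bin mean over rays and as the fraction of total
  fluorescence per 1% radial bin (area-element weighted, so a uniform disk
  reproduces annulus areas exactly).
* **Inside/outside internalization fraction** —
  `inside% = 100 · Σ_{ρ(x) ≤ 1} I(x) / Σ_{ρ(x) ≤ 1.2} I(x)` where
  `ρ(x) = |x − c| / R(θ(x))`; the boundary is the bright-field contour for
  soluble antigen and the cortical-actin contour for bead antigen.
* **Peripheral quarter / radial thirds** — fraction of total fluorescence
  at normalized radii in (0.75, 1.0], and in the inner/middle/outer thirds.
* **Bead-quadrant actin score** — the disk around a 3-µm bead is cut into
  four 90° sectors oriented along the bead→cell axis; the clearance index
  is the drop in the cell-proximal sector's share over time.
* **Synaptic-interface ROI and MFI** — a rectangle between cell and bead
  (width = quarter of the cell diameter) and the mean intensity within it.
* **Colocalization** — Pearson's r (no thresholding; undefined on constant
  input) and Manders' M1/M2 (Otsu or fixed thresholds).
* **Nuclear translocation ratio** — nuclear MFI / whole-cell MFI.
* **Surface-retention kinetics** — per-timepoint median surface-stain
  intensity normalized to t = 0; `% internalized = 100 − % remaining`.
* **KS comparison** — two-sample Kolmogorov–Smirnov test between radial
  distributions or score columns.

The generator emulates the control and knockout phenotypes these scores
were designed to separate: ~80% vs ~70% of soluble antigen internalized at
10 min, ~50% vs ~20% for bead-bound antigen, actin-cup clearance vs
persistence, nuclear NF-κB enrichment, and surface-receptor loss of
60%/80% (control) vs 30%/50% (knockout) at 5/30 min.

## Worked example

```python
import synquant as sq

cfg = sq.make_preset("control_bead", seed=7)       # bead-antigen control cell
scene = sq.generate_scene(cfg)                     # 6-channel 16 µm field

beads = sq.detect_beads(scene, expected_radius_um=1.5)
geom = sq.segment_cell(scene, "actin", beads=beads)   # cortical-actin boundary
geom = sq.segment_nucleus(scene, geom)

rf = sq.inside_outside_fraction(scene, geom, "antigen", background="auto")
q = sq.quadrant_actin(scene, geom, beads[0])
nr = sq.nuclear_ratio(scene, geom, "signal")

print(f"antigen inside the cell: {rf.inside_pct:.1f}%")
print(f"actin quadrants (proximal, lateral, lateral, distal): "
      f"{tuple(round(p, 1) for p in q.percentages)}")
print(f"nuclear NF-kB ratio: {nr.ratio:.2f}")
```

prints

```
antigen inside the cell: 49.9%
actin quadrants (proximal, lateral, lateral, distal): (51.9, 6.2, 6.0, 35.9)
nuclear NF-kB ratio: 1.74
```

The cell was generated with 50% of the antigen inside (the bead-antigen
control condition) and the measured 49.9% recovers it.  The actin quadrant
split reflects the configured cup clearance of 0.85 — most cup actin has
moved to the distal sector, while the proximal share includes the cell's
own cortical actin entering the bead margin.  The nuclear ratio of 1.74
reflects the configured nuclear NF-κB enrichment of the control state
(a ratio of 1 would mean no translocation).

Batch runs are available from the shell:

```sh
synquant simulate --preset ko_bead --n-cells 50 --seed 1 --out scenes/
synquant quantify --in scenes/ --out results/
synquant report --per-cell results/per_cell.csv --out results/summary.csv
```

`quantify` writes one row per cell (inside %, peripheral quarter, thirds,
nuclear ratio, Pearson, quadrant percentages, the 120-bin radial profile)
and a per-condition summary (n, mean, SEM).

## Acceptance script

`scripts/acceptance.py` recomputes the headline recovery numbers from
scratch: it simulates 200 cells for each of the four internalization
conditions and 5000 cells for each kinetics condition, runs the full
measurement path (bead detection, boundary segmentation, inside/outside
apportioning, kinetics normalization) and writes the recovered percentages
to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is ~30 s on one CPU.

## Layout

| module | contents |
| --- | --- |
| `synquant.scenegen` | scene/kinetics generator, presets, TIFF+sidecar I/O |
| `synquant.segment` | cell/nucleus segmentation, contour extraction, bead detection |
| `synquant.radialmap` | clock-scan profiles, inside/outside, peripheral/thirds, KS |
| `synquant.beadsynapse` | quadrant scores, clearance index, interface ROI/MFI |
| `synquant.coloc` | Pearson and Manders coefficients |
| `synquant.sigratios` | nuclear translocation ratio, surface-retention kinetics |
| `synquant.pipeline` | batch orchestration, summaries, manifests |

See `docs/methods.md` for the measurement conventions, generator model and
known limitations.
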