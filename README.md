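# fabriscope

Rapid screening of cloth facemask fabrics from smartphone-microscope
images.

During shortages of commercial masks, facemasks are sewn from locally
available woven or knitted fabrics, and their usefulness depends heavily
on two surface properties: **yarn packing** and **pore size**. A cheap
ball-lens smartphone microscope images a fabric in bright-field
transmitted light — yarns dark, inter-yarn pores bright — and those two
properties can be measured directly from the image. `fabriscope` is the
analysis side of that instrument: it calibrates the pixel scale from a
ruled grid slide, segments micrographs into yarn and pore pixels,
measures pore sizes and cover factor, and ranks candidate fabrics. It is
aimed at researchers and public-health practitioners who need an
affordable, reproducible fabric screen, and it ships a synthetic weave
generator with analytic ground truth so the whole pipeline is testable
without the original photographs.

## The measurements

For a binary yarn/pore classification of the in-focus central crop:

- **Cover factor** — the percentage of area occupied by yarn,
  estimated by pixel counting:
  `f′ = (n_yarn / n_total) × 100`,
  the image-based estimate of the true area ratio
  `f = (A_yarn / A_total) × 100`.
- **Porosity** — the open-area complement: `porosity = 100 − f′`.
- **Pore size** — for each connected bright component, the *longest
  dimension*: the maximum Feret diameter over its pixel centers
  (convex hull + rotating calipers), an upper estimate of the opening.
- **Pixel scale / field of view** — from a calibration grid of known
  pitch `p`: `FOV = (whole periods counted) × p`, and scale (μm/px) is
  that FOV divided by the pixel span of the counted periods.

Fabrics are ranked smallest pore first (ties to higher cover factor) and
flagged against two fixed reference scales: bio-aerosols (≤ 5 μm) and
respiratory droplets (5–100 μm). A bundled reference survey of sixteen
two-layer cloth masks (M1–M16, twelve with identical layers — "type I" —
and four with two distinct fabric layers — "type II") feeds the same
reporting machinery as freshly measured images.

## Worked example

Generate two synthetic plain-weave "fabrics" (three noisy regions each),
a 10 μm calibration grid, and screen them:

```sh
fabriscope calibrate --image grid.png --pitch-um 10 --out calib.json
fabriscope screen --manifest manifest.csv --calib calib.json --out report
```

The calibration output (a 1280 px frame at 1 μm/px; the 0.6 focus crop
holds 76 whole 10 μm periods):

```json
"x": {"pitch_um": 10.0, "grid_periods": 76, "pixel_scale": 1.0,
      "fov_um": 760.0, "axis": "x"}
```

i.e. an effective field of view of 760 μm at exactly 1.0 μm/px. The
screen step prints

```
screened 2 fabrics -> report; recommended TIGHT/L1 (pore 55 um, cover factor 81%)
```

and `report/summary.csv` holds the per-fabric aggregates:

| mask | pore size (μm) | cover factor (%) | porosity (%) |
|------|---------------:|-----------------:|-------------:|
| TIGHT | 55.2 | 81.1 | 18.9 |
| LOOSE | 168.3 | 62.8 | 37.2 |

The TIGHT weave was generated with a 95 μm pitch and 55 μm yarns — true
gap diagonal 56.6 μm, true cover factor 82.3% — and the LOOSE weave with
a 190 μm pitch and 70 μm yarns (169.7 μm, 60.1%), so the measured values
recover the ground truth to a few percent and the ranking picks the
tighter weave. Both measured pore sizes exceed 5 μm (flagged against
bio-aerosols) and the LOOSE one also exceeds the 100 μm droplet
reference, which is exactly the kind of verdict the screen is for.

The same pipeline is available as a library (`fabriscope.analyze_image`,
`fabriscope.run_pipeline`, `fabriscope.rank_fabrics`, …); `fabriscope
simulate` renders synthetic weaves with their analytic ground truth in a
JSON sidecar.

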