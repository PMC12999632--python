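# sarscan

Automated dosimetric quality assurance (QA) for microwave hyperthermia
applicators, based on relative specific absorption rate (SAR) measurements
with a scanned E-field probe in a liquid saline phantom — the hyperthermia
analogue of water-tank dosimetry in radiotherapy.

`sarscan` is written for medical physicists who characterize superficial
hyperthermia applicators (e.g. 434 MHz contact flexible microstrip
applicators, CFMAs, and geometrically similar systems). It covers the whole
workflow:

- **Scan planning** — coordinate frames (IEC 61217-style measurement frame,
  z positive with depth), flat and cylindrically curved contact surfaces,
  circumcircle fitting from three probe points, bounding-box raster paths,
  and G-code motion programs for a Cartesian scanner.
- **Virtual applicator** — a parametric CFMA-like SAR field plus
  diode-sensor and session-noise models, so every analysis stage can be
  exercised (and its statistics studied) without hardware.
- **Sensor calibration** — quadratic voltage-to-power response
  `P = A·V² + B·V + C`, converting scan voltages into power-proportional
  values and normalised relative SAR.
- **SAR metrics** — 0.1 cm grid interpolation, marching-squares isolines,
  and the guideline QA metrics.
- **QA studies** — spatial-resolution, repeatability and applicator
  characterization pipelines with JSON/Markdown reports.

## The metrics

Since SAR ∝ σ|E|²/2ρ and |E|² ∝ applied power, a relative calibration of the
diode sensor against generator power turns voltage maps into relative SAR
maps (normalised to 100% at the maximum of the 1 cm depth plane). From these:

- **EFS** (effective field size): extent of the region above 50% of the
  maximum SAR in the plane 1 cm below the bolus–phantom interface, reported
  as EFS_x × EFS_y along the applicator's main axes, plus the 50%-contour
  area.
- **Δx, Δy** (centre shifts): offset of the 50%-contour midpoint from the
  visually aligned applicator centre.
- **EPD** (effective penetration depth): additional depth at which the SAR
  falls to 50% of its value at 1 cm depth, at the maximum-SAR position.
- **ΔEPD(x, y)** = (EPD(x, y) − EPD(maxSAR)) / EPD(maxSAR) × 100%: maps how
  trustworthy a central-plane EPD is; if the central axes cross the region
  with |ΔEPD| ≤ 5% (equivalently, the high-SAR ≳80% region), scanning only
  the xz/yz planes suffices for routine QA.

## Worked example

```python
import sarscan as ss
from sarscan.simulator import SessionNoise
from sarscan import metrics as met

model = ss.scenario("5H-flat-1.3")          # 5H applicator, flat, 1.3 cm bolus
record, pct = ss.workflows.simulate_normalized_plane(
    model, "xy_at_depth", spacing=1.0, noise=SessionNoise.none(), seed=0)
grid = ss.interpolate_plane(record.data[["u", "v"]].to_numpy(), pct)
efs = met.compute_efs(grid)
print(f"EFS_x x EFS_y = {efs.efs_x:.1f} x {efs.efs_y:.1f} cm")
print(f"centre shift  = ({efs.dx:.1f}, {efs.dy:.1f}) cm")

record, pct = ss.workflows.simulate_normalized_plane(
    model, "xz", spacing=1.0, noise=SessionNoise.none(), seed=0)
grid_xz = ss.interpolate_plane(record.data[["u", "depth"]].to_numpy(), pct,
                               axis_names=("u", "depth"))
epd = met.compute_epd_from_plane(grid_xz)
print(f"EPD (additional depth) = {epd.value:.2f} cm")
```

prints

```
EFS_x x EFS_y = 20.9 x 12.5 cm
centre shift  = (0.8, -0.9) cm
EPD (additional depth) = 2.77 cm
```

i.e. the 50% isoline spans 20.9 cm along and 12.5 cm across the antenna slot,
the effective field centre sits 0.8 cm / −0.9 cm off the visually aligned
origin, and the SAR halves 2.77 cm below the 1 cm reference plane.

The same pipeline is available from the shell:

```sh
sarscan plan --plane xy_at_depth --spacing 1.0 --bbox -16,16,-12,12 \
        --out plan.json --gcode plan.nc
sarscan simulate --scenario 5H-flat-1.3 --plan plan.json --power 30 \
        --seed 7 --out scan.csv
sarscan calibrate --sweep scan.sweep.csv --session-id session-7 --out curve.json
sarscan analyze --scan scan.csv --curve curve.json --out metrics.json
```

plus `sarscan qa-resolution`, `sarscan qa-repeatability`,
`sarscan characterize` and `sarscan report` for the composed studies.

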