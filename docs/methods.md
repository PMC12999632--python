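# Methods

This note documents the models, conventions and numerical choices behind
`sarscan`, and what the synthetic studies do and do not demonstrate.

## Coordinate conventions and scan geometry

The **measurement frame** follows the IEC 61217 fixed reference system with
the z axis re-signed to be positive with increasing depth into the phantom.
Its origin is the applicator centre projected onto the bolus–phantom
interface; a per-setup translation maps it to the robot frame (the z flip is
an explicit flag on `CoordinateFrame`, because scanner vendors differ in
their native axis orientation).

Curved setups use a cylindrical contact surface with its axis along y. Scans
are planned in **surface coordinates** `(u, v, depth)`: `u` is arc length
along the curvature (so grid spacing is preserved as arc length on curved
rows), `v` runs along the cylinder axis, `depth` is radial distance below the
contact surface. The surface radius is recovered in practice from three probe
points at the 1 cm reference depth via a circumcircle fit
(`circle_from_three_points`); the fit declares inputs collinear when the
triangle area falls below 1e-9 cm². The flat setup is the infinite-radius
limit of the curved one, and is tested as such.

**Grid phase.** Grid nodes sit at integer multiples of the spacing from the
measurement origin, so the applicator centre is always sampled and a coarse
resampling of a fine scan is a strict point subset — the property the
resolution study depends on.

**Path ordering.** The 1 cm reference curve is scanned first, then the
remaining bounding-box points row-major by increasing depth, serpentine
within rows to minimise travel.

**Motion programs** are metric (`G21`), absolute (`G90`) G-code with one `G1`
move per point (robot coordinates, cm→mm), a `G4` settling dwell (default
0.8 s) and a `(READ n=3)` comment marker per point; the runner script, not
the controller, performs the voltage readings. Emission/parsing round-trips
the plan exactly (to 1e-9 cm). Analysis files store both frames; internal
units are cm everywhere, mm appears only in G-code text.

## Virtual applicator

The simulator is an explicit parametric stand-in, **not** an electromagnetic
solution. Relative SAR at surface position `(u, v)` and depth `d` (cm):

    S(u, v, d) = exp(−(u−cx)² / 2σx(d)²) · exp(−(v−cy)² / 2σy(d)²)
                 · exp(−2 (d−1) / δ),
    σ(d) = σ0 · (1 + κ (d−1))

| parameter | meaning | default (5H / 3H) |
|---|---|---|
| σx0, σy0 | lateral widths at 1 cm depth [cm] | 8.88, 5.31 / 6.46, 8.66 |
| δ | power-decay depth constant [cm] | 7.91 |
| κ | lateral broadening rate [1/cm] | 0.03 |
| (cx, cy) | true field-centre offset [cm] | (0.8, −0.9) |
| m, Λ | ripple amplitude, period [–, cm] | 0 (0.35 for bolus ≥ 2 cm), 9 |

Lateral widths derive from the published effective field sizes via the
Gaussian FWHM relation σ = EFS/(2√(2 ln 2)) and δ from the exponential EPD
closed form δ = 2·EPD/ln 2; both relations are exact at the field-centre
column, where the broadening term cancels. The published flat-setup metrics
for the two large CFMA geometries are therefore **tuning targets of the
simulator presets, not independent validations of the metrics code** — the
metrics code is validated against closed forms and brute-force oracles
instead. No EPD is published for the 3H flat setup, so the 3H preset reuses
the 5H depth constant (same antenna technology and frequency).

Design choices that are genuinely open in the physical system:

- **Non-separability** enters through depth-dependent lateral broadening
  (κ > 0): columns away from the field centre decay more slowly, so ΔEPD
  grows away from the maximum and the |ΔEPD| ≤ 5% region is a bounded
  neighbourhood of the maximum crossed by the central axes — the
  qualitative behaviour seen in measured volumes. κ = 0.03/cm was chosen
  once as the smallest value giving a clearly non-trivial ΔEPD map; no
  printed number constrains it.
- **Thick-bolus mode** (bolus ≥ 2 cm) multiplies the field by
  `1 + m·cos(2πu/Λ)·cos(2πv/Λ)` with m = 0.35, Λ = 9 cm, which splits the
  50% isoline region — mimicking the resonance-driven irregularities seen
  with excessive bolus thickness. The amplitude and period are qualitative.
- **Curvature coupling** is weak and directional only: δ is scaled by
  (1 + 1.0 cm/r) and σx0 by (1 − 2.0 cm/r). The published observation is a
  slight EPD increase and EFS_x decrease with curvature; magnitudes are not
  asserted against any printed value.
- **Diode sensor** truth defaults to A = 0.02 W/V², B = 0.5 W/V, C = 0
  (monotone over its 0–60 V range); the calibration pipeline never reads
  these directly, it only sees (power, voltage) sweeps.
- **Session noise**: one positioning offset per session (visual alignment
  happens once per day), Gaussian with 0.5 cm SD per axis; multiplicative
  per-reading noise with 0.4% SD, three readings per point. "Triplicate
  variation below 1%" is interpreted as the relative sample SD of the three
  readings, under which the default noise satisfies it for ≥ 99% of points.
- All randomness flows from a single seeded generator recorded in the scan
  metadata.

What the simulator does **not** emulate: true CFMA electromagnetics (feed
resonances, phantom boundary reflections), fat layers, air-pocket physics
(only their net repeatability effect), drifts within a session, or probe
directivity. Passing tests therefore demonstrate correctness of the
*analysis pipeline* under realistic noise and geometry, not fidelity of any
particular applicator's field.

## Calibration

The quadratic response is linear in (A, B, C), so the "nonlinear" fit
reduces to ordinary least squares on the design [V², V, 1]. The fit is
rejected if fewer than four distinct voltages are given, the design is
rank-deficient, or the fitted curve is non-monotone on the sweep range (the
inversion would be ambiguous). A coverage check warns when the sweep spans
less than 90% of a scan's voltage range; voltages more than 10% above the
calibrated maximum abort with an extrapolation error (wrong-session
calibration). Negative converted values (noise near V ≈ 0 with C < 0) are
clipped to the diode floor at zero and counted, making a miscalibrated C
visible. Scans refuse a calibration from another session id unless
overridden. Normalisation anchors at the maximum value among points at the
1 cm reference depth (±half a grid spacing) per scan; a deeper point
exceeding that reference yields values above 100% with a warning, not an
error. A `plane-max` rule is available for sensitivity checks.

## Metrics

Scattered points are linearly interpolated (Delaunay) onto a 0.1 × 0.1 cm
grid; cells outside the measured convex hull are masked and excluded from
maxima, contours and extents.

- **EFS** extents come from the marching-squares 50% contour (sub-cell
  linear accuracy), pooled over all connected components, unioned with the
  ≥50% cell extremes so regions cut by the grid edge are not lost; the cell
  region supplies the area (cells × 0.01 cm²) and a truncation warning when
  the region touches the measured boundary. Contour-based and cell-based
  extents agree within one grid cell — this is tested as an oracle pair.
- **EPD** is reported as *additional depth* beyond the 1 cm plane (a
  `from_interface` property re-expresses it from the bolus–phantom
  interface, since the guideline wording is ambiguous). The crossing is the
  first downward crossing of 50% of the column's own 1 cm value, linearly
  interpolated between depth samples — robust to non-monotone noise at
  depth. No crossing within the measured range gives a censored result
  carrying the lower bound. Ties in the plane maximum break toward the
  smallest |lateral position|, then lexicographically.
- **ΔEPD** uses the volume at the measurement spacing (1 cm), per-column,
  with the same crossing rule; the max-SAR position is taken on the 1 cm
  layer (ties toward the origin). The ≤5% region uses |ΔEPD| (the signed
  map is retained); censored columns are excluded and counted. Axis flags
  record whether the region touches the u = 0 and v = 0 lines within half a
  grid cell.
- **Resolution resampling** is a strict subset of measured points (integer
  multiples of the target spacing), never an interpolation.

## QA studies

- **Resolution study**: the 0.25 cm noiseless plane of the 3H-like preset is
  subset to 1/2/4 cm, each subset independently interpolated to 0.1 cm, and
  EFS differences reported relative to the fine reference. Deterministic.
- **Repeatability study**: each session is a fully independent pipeline —
  fresh offset, fresh calibration sweep and fit, xy/xz/yz scans, metrics.
  Default: 8 sessions. SD is the sample standard deviation (n−1; the
  statistical default, since the published table does not state the
  denominator); SD% divides by the absolute mean. Sessions with censored
  EPD are excluded with a note.
- **Characterization**: per scenario (applicator × curvature × bolus) one
  session measuring xy- and xz-planes; reports metrics, isoline component
  counts and the axis-crossing gate — the central-plane EPD is accepted
  when the v = 0 line crosses the xy ≥80% region (threshold configurable in
  [80, 90]). Cross-scenario deltas compare curved setups against the flat
  one within each (applicator, bolus) group.

## Problem sizes and runtimes

Default study sizes: xy plane 33 × 25 points at 1 cm (825 points; 12 513 at
0.25 cm), depth planes 33 × 6, volume 33 × 25 × 6. These match the physical
procedure's scan extents and keep the full test suite and the acceptance
script in the seconds-to-minutes range on a single CPU.

## Known limitations

- The simulator's field is smooth and unimodal (up to the ripple mode);
  multi-lobed antenna defects are out of scope.
- Interpolation-uncertainty propagation into EFS/EPD is not modelled; the
  resolution study bounds the effect empirically for smooth fields.
- Absolute SAR (W/kg) is intentionally out of scope: phantom conductivity
  and density are carried as metadata only, and all outputs are relative.
- The repeatability study treats the simulator's drawn offset as ground
  truth for centre-shift consistency checks; a real deployment would
  compare against independently logged positions.
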