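# windfirm

Mechanistic assessment of coniferous-tree resistance to wind-induced
uprooting.  The model balances the wind overturning moment on a conical
crown against two restoring terms — stem stiffness and the weight of the
root plate (a half-ellipsoid of coarse roots plus enclosed soil) — and
reduces the comparison to a wind-independent resistance index Δ′.
Thresholds calibrated from uprooted-tree reference data band standing
trees into High / Moderate / Low uprooting-hazard levels.

The package also covers the supporting field quantities: coarse-root
density from ground-penetrating-radar transect scans (with one-way ANOVA,
Tukey HSD, and a compact letter display), soil physical properties
(gravimetric water content, core bulk density, porosity), packaged
reference tables, and a seeded synthetic-stand generator so the whole
pipeline is testable without field data.

## Layout

| module | contents |
| --- | --- |
| `windfirm.core` | domain types and the moment balance: wind load, lever arms, stem/root-plate moments, plate volume and mass, resistance coefficient, Δ′ |
| `windfirm.hazard` | threshold calibration (mean + z·sd) and High/Moderate/Low classification |
| `windfirm.field` | radar root-density profiles, ANOVA + Tukey HSD + letters, soil physics |
| `windfirm.io` | CSV/TOML readers and writers, run configuration, the end-to-end assessment pipeline |
| `windfirm.fixtures` | the five packaged reference tables (CSV, shipped verbatim, anomalies flagged) |
| `windfirm.synth` | seeded generators for stands, root plates, radar scans, and uprooted-tree references |

## CLI

```sh
# calibrate thresholds from a reference summary (or --reference values.csv)
windfirm calibrate --mean 0.66 --sd 0.33 --species spruce --out thresholds.toml

# generate a synthetic stand with the standard CSV schemas
windfirm simulate --seed 7 --out sim/

# full assessment: moment balance, Δ′, hazard level per tree
windfirm assess --trees sim/trees.csv --rootplates sim/rootplates.csv \
    --thresholds thresholds.toml --out hazard.csv

# radar density profile with Tukey letter display
windfirm density --scans sim/scans.csv --out profile.csv --letters

# export the packaged reference tables
windfirm fixtures --export tables/
```

Exit codes: 0 success, 1 validation failure, 2 I/O failure.

## Conventions

* SI units internally (m, kg, N, N·m); DBH is carried in cm on input
  records, as in forest inventories.
* Crown radius is the mean of the two cardinal crown widths divided by 2;
  crown frontal area is radius × crown length (conical crown).
* Plate volume treats the depth as a semi-axis and the two horizontal
  dimensions as full axes: V = (π/6)·depth·length·width, which reduces to a
  half-sphere for axes (r, 2r, 2r).  A measured volume overrides the formula.
* The coarse-root allometries are evaluated per species under calibrated
  unit conventions (spruce: D in dm, output kg; Korean pine: D in cm,
  output g), configurable via `SpeciesParams`.
* Wind constants (air density 1.226 kg·m⁻³, drag coefficient 0.29, speed
  10 m·s⁻¹) rescale the resistance coefficient only; Δ′ and the hazard
  classification are independent of them.
* Thresholds are rounded to 2 decimals before classification; the boundary
  value at the 99% threshold is classified Low.
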