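# planktosink

Composition-based modelling and single-cell inference of phytoplankton
gravitational sinking.

The package links the molecular composition of a unicellular phytoplankton
cell (water, protein, lipid, carbohydrate, and a residual "other" pool) to
its biophysical state (volume, density, equivalent spherical radius) and its
creeping-flow settling velocity, and provides the analysis machinery to infer
those quantities from single-cell instrument measurements:

* **`planktosink.physics`** — the composition model (volume = sum of group
  volumes, density = volume-weighted mean of group densities), Stokes
  settling with unit handling (g/mL, fL, µm, µm/s), and Péclet/Reynolds
  transport numbers with nitrate (1,700 µm²/s) and virus-sized (10 µm²/s)
  diffusivity presets.
* **`planktosink.influence`** — first-order Taylor attribution of a settling
  change to cell density vs cell volume, or to water volume / dry volume /
  dry density; signed influences that always sum to one.
* **`planktosink.sweeps`** — fold sweeps of one molecular group (or all dry
  groups jointly) with a density/volume split, buoyancy-reversal threshold
  finding by bisection, and attribution of observed velocity changes to
  measured compositional changes.
* **`planktosink.populations`** — population biophysics from unpaired
  resonator (buoyant mass, pg) and impedance-counter (volume, fL) arms,
  small-particle filtering, the dual-fluid (normal/heavy-water) dry-content
  solver, and exponential proliferation rates.
* **`planktosink.study`** — replicate-level statistics (one-sample/paired/
  Welch t, one-way ANOVA + Tukey HSD, linear fits), paired low:high velocity
  ratio tests, and `run_study`, which turns a tidy measurement table into a
  full machine-readable report.
* **`planktosink.synth`** — synthetic measurement studies with known ground
  truth: lognormal cell-size variation, disjoint instrument sampling, a
  heavy-water arm with full water exchange, replicate-level compositional
  scatter, and per-condition volume fold-change effects.
* **`planktosink.io` / `planktosink.cli`** — YAML configuration, tidy-CSV
  interchange, a best-effort workbook importer, and the `planktosink`
  command-line tool.

## Command line

```sh
# synthetic nine-species high/low study with ground truth
planktosink synth study --seed 17 -o data/

# full analysis: per-replicate biophysics, fold-change tests, influence
# decompositions, Péclet table, proliferation rates
planktosink analyze study --input data/ -o report/

# composition sweeps and buoyancy thresholds
planktosink simulate sweep --component lipid --fold-min 0.25 --fold-max 20 \
    --steps 48 -o sweep.csv
planktosink simulate threshold --component water --mode accumulate

# influence decomposition between two states (density g/mL, radius µm)
planktosink decompose --baseline 1.08,2.0 --perturbed 1.10,2.1

# best-effort import of a sheet-per-figure workbook into tidy CSVs
planktosink import s1 --path workbook.xlsx -o imported/
```

Global flags: `--config study.yaml` (physics constants, per-species shape
factors, transport lengths, and small-particle thresholds), `-v/-vv` for
logging, `--json-errors` for machine-parseable error output, `--version`.

## Measurement schema

The canonical input is a tidy CSV with one row per measured cell:

```
species,condition,replicate_id,instrument,fluid,fluid_density_g_ml,value,unit
```

`instrument` is `resonator` (buoyant mass, `pg`) or `impedance_counter`
(volume, `fL`); `fluid` is `h2o` or `d2o`. Cell counts go in a separate
table with columns `species,condition,replicate_id,day,count_per_ml`.

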