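# ecoclimex

A CLIMEX-style mechanistic bioclimatic suitability model for
poikilothermic species on high-resolution gridded climate, parameterized
by default for the brown marmorated stink bug (*Halyomorpha halys*), an
invasive polyphagous fruit and vegetable pest.  The package is aimed at
pest-risk modellers who want an open, tested engine for mapping present
and future climatic suitability, voltinism and phenology in
topographically complex regions, plus everything around it: gridded
monthly climate I/O, delta-change scenario construction,
occurrence-record validation, and a synthetic alpine-climate generator
so the whole pipeline runs without proprietary climate data.

## The model

For each grid cell the engine runs a 52-week year and combines weekly
growth and stress functions into the annual **Ecoclimatic Index**:

* weekly growth index `GI_W = TI · MI · DI`, the product of a
  temperature response (piecewise-linear trapezoid over DV0–DV3), a
  soil-moisture response (trapezoid over SM0–SM3, driven by a weekly
  bucket water balance), and a binary winter-diapause indicator driven
  by day length and temperature;
* annual growth index `GI_A = 100 · mean(GI_W)`;
* five stress accumulators — cold, heat, dry, wet, hot-wet — each a
  capped linear sum of weekly threshold exceedances;
* degree days above DV0 and voltinism
  `generations = DD_annual / PDD`;
* `EI = GI_A · Π(1 − stress/100)`, forced to 0 when the annual degree
  days cannot complete one generation (`DD_annual < PDD`).

EI > 5 marks a climatically suitable location and EI > 15 a highly
suitable one; below EI 1 the species cannot persist.  For *H. halys*
the defaults are development between 12 °C and 33 °C (optimum
27–30 °C), PDD = 595 °C·days above 12 °C, and diapause induction below
12 h day length and 5 °C.  See `docs/methods.md` for the full model
description and the design choices.

## Worked example

```python
import ecoclimex as ec

# Synthetic alpine country: 20 x 15 cells, valley floor ~250 m,
# ridges to ~2300 m, deterministic for a fixed seed.
grid = ec.make_synthetic_grid(ec.SyntheticConfig(seed=0))
baseline = ec.run_grid(grid)
summary = ec.area_percentages(baseline)
print(f"suitable (EI > 5):        {summary.pct_suitable:.1f}%")
print(f"highly suitable (EI > 15): {summary.pct_highly_suitable:.1f}%")
print(f"one generation or more:    {summary.pct_one_gen:.1f}%")

# Delta-change scenario: +4.1 degC annual warming, 8% annual drying,
# both summer-accentuated.
signal = ec.make_change_signal("A2-like", "2070-2099", dT_annual=4.1, dP_annual=-8.0)
future = ec.run_grid(ec.apply_deltas(grid, signal))
fsum = ec.area_percentages(future)
print(f"suitable under +4.1 degC:  {fsum.pct_suitable:.1f}%  "
      f"({fsum.pct_suitable / summary.pct_suitable:.1f}-fold)")
```

prints

```
suitable (EI > 5):        38.3%
highly suitable (EI > 15): 19.0%
one generation or more:    38.3%
suitable under +4.1 degC:  77.0%  (2.0-fold)
```

38.3 % of the synthetic country's cells are climatically suitable at
baseline (the valley floors; the ridges fail the 595-degree-day budget),
and end-of-century warming roughly doubles that share by pushing the
suitability boundary upslope.  Per-location results follow the same
pattern — a valley cell goes from EI 15 with 1.36 generations and a
24-week growth season at baseline to EI 32 with 2.95 generations and 32
growth weeks under the warming scenario:

```python
q = ec.LocationQuery("valley", float(grid.lon[4]), float(grid.lat[1]))
ec.location_table({"reference": baseline, "A2-like 2070-2099": future}, [q])
```

The same pipeline is available from the shell:

```sh
ecoclimex synth --outdir data --seed 1          # synthetic climate, signals, records
ecoclimex run --climate data/climate.nc --outdir out
ecoclimex scenario --climate data/climate.nc --signals data/signals.csv --outdir out
ecoclimex validate --climate data/climate.nc --occurrences data/occurrences.csv --outdir out
```

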