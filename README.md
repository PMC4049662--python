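# livergrowth

Organ-scale modelling of liver growth and regeneration, built on a simple
mass balance: the nutrient influx of a growing organ is split between
maintaining existing tissue and producing new biomass, and the split is set
entirely by the organ's geometry.  The package is aimed at quantitative
physiologists and transplantation researchers who want to turn serial CT
volumetry of a regenerating liver into interpretable parameters — when the
organ resumed normal growth, what fraction of it was proliferating at the
start, and how fast tissue was recruited.

## Model

Let `S_max`, `V_max` be the surface and volume of the fully grown organ and
`Ŝ = S/S_max`, `V̂ = V/V_max` the relative surface and volume.  The
dimensionless **growth ratio**

```
G = Ŝ / V̂ − 1
```

is the fraction of the influx available for biomass production.  Because
volume outruns surface during growth, `G` decreases monotonically and
vanishes at the maximum size, which terminates growth.  With a volumetric
influx `K` (normalized to 1 — its value only sets the time unit) and tissue
density `ρ`, a normally growing organ obeys the separable ODE

```
ρ dV/dt = K · V · G(V)
```

integrated by a midpoint rule over the shape's growth variable.  Two
closed-form liver geometries are provided: a hemisphere-capped partial
torus sliced through its symmetry plane (whole dog livers, growing by pure
dilation with `d/r` fixed) and a cut trapezoidal prism (human lobes, whose
shape changes as the boundary plane advances).

After a transplant or major hepatectomy only a fraction `A` of the organ
proliferates at first.  The passive remainder shrinks as

```
V_passive(V) = (1 − A) V_b ((V_j − V) / (V_j − V_b))^p ,
ρ dV/dt = K · (V − V_passive) · G(V)
```

until the **joining volume** `V_j`, after which the whole organ grows
normally.  The fitting module calibrates the time scale, detects the
joining point by a changepoint scan, and fits `(A, p)` by alternating
bounded scalar searches.

## Worked example

`python examples/synthetic_recovery.py` generates noiseless synthetic CT
volumetry from the dog-2 scenario (initial volume 344.778 cm³, relative
growth ≈ 3.05, half the organ initially active, joining at 54% of the final
volume, 4 days per model time unit) and runs the full analysis pipeline:

```
joining detection (truth: fraction 0.54, 4.0 days per model unit)
  joining day        :    8.0
  volume fraction    : 0.5347
  time scale (d/unit): 4.0002
fit (truth: A=0.5, p=0.83)
  A_hat = 0.4989   p_hat = 0.8200   objective = 2.01e-04
  converged after 6 rounds
```

The detector localizes the joining point at 53.5% of the final volume
(truth 54%) and recovers the day-per-model-time factor to four digits; the
alternating fit then returns the initially active fraction `A` and the
recruitment exponent `p` within 0.01 of the generating values.  The other
example scripts print a dog growth curve (`dog_growth_curve.py`), the
left-versus-right lobe growth-ratio comparison (`lobe_comparison.py` — the
thin left lobe keeps a higher growth ratio at every matched volume, which
is why left remnants regrow fastest), and the closed-form graft-length
inversion (`graft_geometry.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```
livergrowth simulate -c config.yaml -o curve.csv
livergrowth synth    -c config.yaml --seed 7 -o obs.csv
livergrowth joining  -c config.yaml --obs obs.csv -o joining.json
livergrowth fit      -c config.yaml --obs obs.csv -o fit.json
livergrowth lobes    -c config.yaml -o lobes.csv
```

Configurations are YAML (see `tests/test_io_cli.py` for the schema);
curves and observations are commented CSV, results JSON.  Every command is
a pure function of its config, inputs and seed.

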