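# connectscape

Multi-species functional-connectivity modeling for terrestrial mammal
communities: estimate habitat suitability from camera-trap data with a
hierarchical multi-species occupancy model, estimate movement suitability
from GPS telemetry with per-individual step-selection functions (SSF),
transform suitability into landscape resistance with linear and negative-
exponential curves, combine species/individuals into group-level resistance
surfaces, and map least-cost corridors and circuit-theory pinch points
between occupancy-derived core areas.

The package is aimed at movement ecologists and corridor planners who want
a scripted, reproducible alternative to GIS-toolbox workflows (Linkage
Mapper-style corridor mapping) with the statistical models fitted in the
same pipeline, plus a fully synthetic landscape generator so every stage is
testable with known truth and no data downloads.

## Models

**Occupancy.** For species *i* at camera site *j* with standardized
covariates V1..Vn,

    logit(Ψ_ij) = α_i + α_i1 V1 + … + α_in Vn
    z_ij ~ Bernoulli(Ψ_ij),   y_ijk ~ Bernoulli(z_ij · p_i)

with species parameters drawn from community-level normal distributions
(α_in ~ N(μ_n, σ_n)), so rare species borrow strength from common ones.
Fitting is by seeded Metropolis-within-Gibbs MCMC with exact latent-z
updates; R-hat and effective sample sizes are reported.

**Step selection.** A step is the straight line between consecutive hourly
GPS fixes. Each observed step is matched with K = 100 control steps sharing
its start point (gamma-distributed lengths fitted by MLE to the observed
lengths, uniform turn angles), and selection is estimated by maximizing the
conditional-logistic likelihood

    ℓ(β) = Σ_strata [ β'x_obs − log Σ_steps exp(β'x) ].

A "Travel" mode keeps only steps above a species-specific length threshold
(ocelot 100 m, white-lipped peccary 150 m, puma 200 m). Movement
suitability per cell is S = Σ β_n V_n, min-max rescaled to [0, 1].

**Resistance.** R = 100 − 100·HS (linear) or
R = 100 − 99(1 − e^(−c·HS))/(1 − e^(−c)) with c = 3 or 8. Member surfaces
are z-scored, averaged, and rescaled so each group surface spans exactly
[1, 1000]; road/urban cells are burned at 85% (tolerant) or 95% (sensitive)
of the surface maximum.

**Connectivity.** 8-neighbor cost graph (edge cost = mean endpoint
resistance × center distance), multi-source Dijkstra cost-weighted
distances, corridors as {CWD_A + CWD_B − LCP ≤ 25,000}, and all-to-one
circuit solves on the graph Laplacian for current density and pinch points.

## Worked example

Simulate a track from a known step-selection model, refit it, and build a
resistance surface:

```python
import numpy as np
from connectscape.synthetic import LandscapeConfig, generate_landscape, simulate_ssf_track
from connectscape.covariates import standardize_stack
from connectscape.ssf import (LENGTH_ADJUSTMENT, make_steps, sample_random_steps,
                              fit_clogit, predict_suitability)
from connectscape.resistance import CURVES, transform

stack = generate_landscape(LandscapeConfig(rows=200, cols=200, seed=11))
prepared = standardize_stack(stack)
beta = {"FCOV": 0.62, "DWPA": -0.32, "elevation": -0.02}   # generating truth
track = simulate_ssf_track(stack, beta, kinetics=(1.5, 300.0), n_steps=1500,
                           start=stack.grid.cell_center(100, 100), seed=5)
steps = make_steps(track)
strata = sample_random_steps(steps, prepared, K=100, seed=7, covariates=list(beta))
model = fit_clogit(strata, list(beta) + LENGTH_ADJUSTMENT)
print(model.summary().round(3))
suit = predict_suitability(model, prepared)
resist = transform(suit, CURVES["exp_c8"])
print(f"resistance range: {np.nanmin(resist.data):.2f} - {np.nanmax(resist.data):.2f}")
```

This prints

```
            coef     se       z
FCOV       0.663  0.054  12.342
DWPA      -0.379  0.084  -4.495
elevation -0.017  0.041  -0.412
sl         0.511  0.158   3.236
log_sl    -0.013  0.053  -0.248
resistance range: 1.00 - 100.00
```

The habitat coefficients recover the generating values (0.62, −0.32,
−0.02) within about one standard error; `sl` and `log_sl` are the
movement-kernel correction terms (see `docs/methods.md`). The c = 8
exponential curve maps the [0, 1] suitability surface onto resistances
from 1 (best movement habitat) to 100 (worst).

The full scenario matrix — 2 species groups × 3 data sources (occupancy,
SSF-All, SSF-Travel) × 3 transformation curves = 18 resistance surfaces,
each followed by corridor and pinch-point mapping — runs end-to-end on a
synthetic landscape with:

```bash
connectscape run-all --outdir runs/demo --seed 42
# -> 18/18 scenarios completed; manifest at runs/demo/manifest.yaml
```

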