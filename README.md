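# gapcal

Tree-ring driven calibration of an individual-based forest gap model.

Dendroecologists and forest modellers who want to constrain gap-model
species parameters with tree-ring records face three obstacles: the field
observation (basal area reconstructed from cores) is a biased proxy — only
trees alive and large at sampling left a record (the *fading record*); the
stand's age at coring is unknown in successional time; and the simulator
is too expensive to embed in a statistical model directly. `gapcal`
implements a pragmatic pipeline for all three, validated end to end on
synthetic data with known ground truth:

1. **Toy gap simulator** (`gapcal.gapsim`) — individual trees with
   logistic diameter growth `g·D·(1−D/Dmax)` gated by growing degree-days,
   stress mortality after ≥2 years below a minimum increment `dbh_min`,
   background mortality `4.605/max_age`, bare-ground starts, seeded
   climate from monthly normals; doubles as the synthetic-data generator.
2. **Ring processing** (`gapcal.ringproc`) — outside-in basal-area
   increments from ring widths (`BAI_t = π(r_t² − r_{t−1}²)`), the
   measured-radius-vs-ring-sum rule, missing-outer-ring exclusion,
   species BA trajectories; CSV and Tucson-style decadal readers.
3. **Fading-record proxy** (`gapcal.fading_proxy`) — the *alive tree
   subset*: the stand's BA history rebuilt from only those trees alive
   and >10 cm DBH at a candidate coring year.
4. **Sensitivity analysis** (`gapcal.sensitivity`) — one-at-a-time
   designs over uniform priors, ranked by the variance of first
   principal-component scores of the BA trajectories.
5. **Optimal coring year** (`gapcal.coring_select`) — penalized additive
   model per candidate year (log-scale, subset as offset, ridge-penalized
   smooth of time) scored by AIC; the median arg-min across an ensemble
   of simulations estimates the coring year — and hence the stand age.
6. **Kennedy–O'Hagan calibration** (`gapcal.koh`) — a Latin-hypercube
   design, a heteroskedastic Matérn Gaussian-process surrogate of the
   simulator, a residual GP estimating the discrepancy (bias) b(t), a
   20×20 negative-log-likelihood surface over the two most sensitive
   parameters, the maximum-likelihood estimate û, and a bias-corrected
   prediction with 95% intervals, following
   `Y_F(t) = y_M(t, u*) + b(t) + ε`, `ε ~ N(0, σ_ε²)`.
7. **Pipeline & CLI** (`gapcal.pipeline`, `gapcal.harness`, `gapcal`
   console script) — one-config orchestration with per-stage seed
   streams, tidy CSV outputs, a run manifest, and closed-loop recovery
   experiments.

## Worked example

```python
import numpy as np
from gapcal import koh
from gapcal.gapsim import run_stand, synth_field_data
from gapcal.harness import (default_species, default_site, default_normals,
                            default_bounds, build_surrogate_designs,
                            fit_site_surrogates)

species, site, normals = default_species(), default_site(), default_normals()

# a 120-year stand and a synthetic ring record cored in year 120
stand = run_stand(species, site, normals, years=120, seed=42)
fields = synth_field_data(stand, coring_year=120, sigma_eps=0.0)

# 36-run Latin hypercube design -> per-species GP surrogates
bounds = default_bounds()                      # g_PIGL, dbh_min_PIMA priors
design_pts = koh.lhs_design(bounds, n=36, seed=7)
designs = build_surrogate_designs(design_pts, species, site, normals,
                                  years=120, coring_year=120, sim_seed=42,
                                  bounds=bounds)
gps = fit_site_surrogates(designs)

# 20x20 maximum-likelihood surface and bias-corrected prediction
result = koh.calibrate([gps[s] for s in sorted(species)],
                       [fields[s] for s in sorted(species)], grid_res=20)
print("cells:", result.surface.n_cells)
print("u_hat:", {k: round(v, 4) for k, v in result.u_hat.items()})
print("coverage:", koh.resolution_report(36, 20)["coverage_pct"], "%")
```

Output:

```
cells: 400
u_hat: {'g_PIGL': 0.0663, 'dbh_min_PIMA': 0.0779}
coverage: 9.0 %
```

400 cells is the full likelihood surface; the 36 simulations cover 9% of
it — the GP surrogate fills in the rest. The record was produced by this
very simulator at `g` = 0.065, `dbh_min` = 0.07, and `u_hat` lands
nearby: the growth axis is recovered to within half a grid cell, the
stress axis to within a few cells (it is the softer direction — see
`docs/methods.md` for the measured resolution of each axis).

The full pipeline (simulate → sensitivity → coring scan → calibration,
with CSV outputs, a manifest and a recovery report) runs from the shell:

```sh
gapcal all --seed 1 --mode synthetic --out runs/demo
```

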