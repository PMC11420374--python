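# riverpom

Pulse–shunt–storage modelling of particulate organic matter (POM) in river
networks.

Streams receive large pulses of terrestrial leaf litter each autumn. Floods
shunt that material downstream, but between events much of it sits on the
*dry* fraction of the streambed exposed when flow contracts laterally, where
decomposition is slow. `riverpom` is a mechanistic simulator for ecosystem
biogeochemists who want to quantify how this lateral hydrological
contraction controls how much POM a river network degrades in place versus
exports to its outlet — and how degraded the exported material is.

## Model

The simulator couples four components on a synthetic catchment:

1. **Network** — an optimal channel network (OCN) on a square lattice,
   annealed to minimize the energy `Σ_p A_p^0.5`; channel pixels
   (drained area ≥ 1 km²) are segmented into reaches between confluences,
   with slopes from the scaling law `s_i = s_O (A_i/A_O)^-0.5`.
2. **Hydrology** — daily effective rainfall as a marked Poisson process
   (rate λ, exponential depths of mean α chosen so every scenario delivers
   250 mm y⁻¹), downscaled to hours, filtered by an exponential unit
   hydrograph with response time *u*, and routed instantaneously:
   `Q_i = Σ_j W_ji Q_j + q_i`. Three scenarios (λ, u) = (0.5, 20),
   (0.2, 10), (0.05, 5) create low, mid and high flow variability, hence
   lateral contraction.
3. **Hydraulics** — downstream scaling `w̄ = 10 Q̄^0.5`, `d̄ = 0.25 Q̄^0.4`
   and at-a-station scaling `w = w̄ (Q/Q̄)^0.26`, `d = d̄ (Q/Q̄)^0.4`;
   velocity by continuity; bottom shear stress `τ = γ d s`; bankfull width
   at the discharge with a 2-year recurrence interval. The wet streambed
   fraction is `w(t)/w_BF`.
4. **POM** — a reactivity continuum: POM mass is a density over first-order
   decay rates `K`, initially Gamma(ν=1, mean ⟨K_W,LF⟩ = 0.01 d⁻¹), so bulk
   mass loss follows `(κ/(κ+t))^ν`. Dry conditions slow every component by
   `F_WD = K_D/K_W = 0.2`. Litterfall (2.4 kg m⁻¹ y⁻¹, Gaussian around
   Julian day 300) splits between wet and dry beds by the wet fraction;
   width change exchanges mass between the two pools; wet POM moves
   downstream at `δ = μ (τ−τ0)⁺ v / l` (τ0 = 8 Pa, μ = 0.03 Pa⁻¹); floods
   above bankfull sweep the dry stock to the floodplain. Every run closes a
   full mass budget (input = wet + dry degradation + export + overbank +
   storage change) to round-off.

A separate estimation module fits (ν, ⟨K_W,LF⟩, F_WD) to litterbag
ash-free-dry-mass time series — simultaneous wet/dry or sequential
wet→dry/dry→wet designs — by RMSE minimization
(`ReactivityContinuumModel(...).fit()`, statsmodels-style).

## Worked example

```python
import numpy as np
from riverpom import (RainScenario, SimulationConfig, generate_network,
                      run_simulation, summarize_fates)
from riverpom.config import headwater_outlet_slope

# a 41 km^2 headwater catchment (64x64 lattice, 100 m pixels)
net = generate_network(64, area_threshold=1e6,
                       s_outlet=headwater_outlet_slope(64 * 64 * 1e4), seed=5)
cfg = SimulationConfig(scenario=RainScenario(lambda_=0.2, u=10.0),
                       years=10, spinup_years=2, seed=1)
res = run_simulation(net, cfg)
print(f"reaches: {net.n_reaches}")
print(f"exported fraction: {res.export_fraction:.3f}")
print(f"exported mean K_W: {res.export_mean_reactivity:.4f} 1/d")
print(f"budget closure: {res.budget.closure_error:.1e}")
print(summarize_fates(res, 5)[["area_km2", "frac_export"]])
```

prints

```
reaches: 20
exported fraction: 0.947
exported mean K_W: 0.0096 1/d
budget closure: 3.9e-14
   area_km2  frac_export
0      2.81     0.976744
1     18.85     0.956755
2     24.25     0.952881
3     27.06     0.948991
4     40.96     0.947191
```

A 41 km² catchment under mid flow variability exports ~95 % of its litter
input: reaches this small are steep, shear stress is almost always above
the transport threshold, and POM is shunted out before it can decompose.
The exported material is nearly fresh (mean reactivity 0.0096 d⁻¹ against
0.01 d⁻¹ for fresh litter), and the exported fraction falls as the
subcatchment grows — decomposition wins with increasing residence time.
The budget closure line confirms that every kilogram of litter is accounted
for among the fates.

Command-line equivalents: `riverpom generate-network`,
`simulate-hydrology`, `simulate-pom`, `fit-rc`, `sweep`, `fixtures`.

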