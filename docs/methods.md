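# Methods

This note documents the model equations, the numerical choices, the
defaults and their rationale, what the synthetic inputs emulate, and the
known limitations of `riverpom`.

## Synthetic catchments

Drainage is generated on an `n x n` pixel lattice (100 m pixels by
default). Starting from a uniform random spanning drainage (Wilson's
loop-erased random walks toward an outlet placed mid-edge), single-pixel
flow redirections are proposed at random and accepted by the Metropolis
rule on the optimal-channel-network energy `E = Σ_p A_p^0.5` (drained area
in pixels) under a geometric temperature schedule (T: 1 → 1e-4 over
`30 n²` proposals by default). Moves that would create a cycle are rejected
outright, so the drainage remains a spanning tree by construction. On a
128² lattice the annealed drainage's area-exceedance exponent is ~0.42,
inside the 0.40–0.50 range typical of real river networks (a soft
diagnostic, not a hard guarantee of any individual realization).

Channel pixels are those draining at least the channelization threshold
(1 km² by default); chains of channel pixels between confluences form
reaches. Each channel pixel contributes its outgoing step length (pixel
length, or √2 times it for diagonal steps; one pixel length at the
outlet). Every lattice pixel is attributed to the first reach met along
its flow path, which defines the incremental areas; their sum is exactly
the lattice area (integer pixel arithmetic). Reach slopes follow
`s_i = s_O (A_i/A_O)^-0.5` from the outlet slope `s_O = 0.001`.

When a *reduced* catchment is simulated (tests, worked examples), its
outlet slope is set to `0.001 (A/A_ref)^-0.5` with `A_ref = 2621 km²`, i.e.
the small catchment is treated as a headwater subcatchment of the
reference system rather than as a miniature lowland basin. Without this,
shear stresses on a small standalone catchment would sit almost entirely
below the transport threshold and the transport pathway would be untested.

## Hydrology

Daily effective rainfall is a marked Poisson process: event counts per day
are Poisson with rate λ [d⁻¹], event depths exponential with mean α [mm],
and α is always derived from the mean annual effective precipitation
(250 mm) so that scenarios with different λ share the same mean annual
flow. The Poisson-count form (rather than a single Bernoulli event per
day) is required for the analytic shot-noise limit CV(Q) → (λu)^-1/2 to
hold, and it is the form that reproduces the published per-scenario flow
CVs; at λ ≤ 0.5 d⁻¹ the two differ mainly in allowing occasional
multi-event days.

Hourly downscaling gives each wet day an integer event duration uniform on
{1..24} h and a uniform start hour; hourly intensities are i.i.d.
exponential rescaled so the day's total is conserved exactly (an exact
daily total and exactly exponential hourly marginals are mutually
exclusive; conservation wins).

Each subcatchment's streamflow is the rainfall filtered by an exponential
instantaneous unit hydrograph with mean response time u [d], integrated
with the exact exponential state update of the equivalent linear reservoir
(`S ← S e^{-Δt/u} + input`), which is unconditionally stable and exact for
impulsive input. A constant baseflow of 0.5 % of the subcatchment mean
flow keeps every reach wetted. Routing is an instantaneous sum over the
drainage tree (flood-wave celerity is neglected: channel response is much
faster than hillslope response at these scales).

One rainfall series drives all subcatchments. Uniform forcing plus a
linear filter make the discharge field rank-one, `Q_i(t) = A_i g(t)`, so
the normalized series `Q_i/Q̄_i` — and therefore CV(Q), CV(w), the wet
fraction and the overbank indicator — are shared by all reaches. The
implementation stores this factorized form; memory stays O(reaches +
hours) instead of O(reaches × hours).

## Hydraulics

Geometry at mean flow: `w̄ = B_w Q̄^0.5`, `d̄ = B_d Q̄^0.4` (B_w = 10,
B_d = 0.25, SI units). At-a-station: `w = w̄ (Q/Q̄)^0.26`,
`d = d̄ (Q/Q̄)^0.4`; velocity `v = Q/(w d)` by continuity; bottom shear
stress `τ = γ d s` (γ = 9810 N m⁻³), assuming quasi-uniform flow with the
hydraulic radius approximated by the depth.

The bankfull discharge is the flood with a 2-year recurrence interval,
estimated as the empirical median of the annual maxima of a dedicated
200-year hourly simulation (return period 2 yr ⇔ annual exceedance
probability 0.5; the median needs no plotting-position convention). The
bankfull run uses its own seed: channel geometry is an equilibrium
property, not a property of the production realization. The wet streambed
fraction is `w(t)/w_BF`, clamped at 1 during overbank instants
(`Q > Q_BF`), which are flagged for the POM overbank rule.

## Reactivity continuum

POM mass is a density over first-order decay rates K; each component obeys
`dρ/dt = -Kρ`. Fresh litter in wet conditions is Gamma(ν, κ) with
ν = 1 and mean ⟨K_W,LF⟩ = ν/κ = 0.01 d⁻¹; bulk mass then decays as
`(κ/(κ+t))^ν`. Dry conditions slow every component linearly:
`K_D = F_WD K_W` with F_WD = 0.2.

Spectra are discretized on a logarithmic grid (64 bins by default,
spanning `[⟨K⟩/10⁵, 100⟨K⟩]`; bin centres are geometric means of edges;
initial bin masses integrate the Gamma density via the regularized
incomplete gamma function). The wide lower tail matters: mass below the
grid floor never decays, and truncating even 0.1 % of it dominates the
relative error of the bulk decay curve by t ≈ 1000 d, when only ~9 % of
the initial mass remains. With this span the 64-bin decay curve tracks the
analytic solution to < 0.2 % out to 1000 d and the error halves-or-better
with each bin doubling.

Dry spectra are stored in wet-reference coordinates with effective rate
`F_WD K_W`. Under the linear wet↔dry map the Jacobian of the density
transformation is absorbed exactly by this convention, so moving mass
between environments is a per-bin identity with zero rebinning error, and
a sequential exposure of t_wet wet days plus t_dry dry days decays like
`t_wet + F_WD t_dry` wet-equivalent days (used as an independent closed
form to validate the numerical integration).

## POM balance and integration

Within each hourly step the operators are applied in sequence — litterfall
input, wet/dry exchange, decay, transport — each mass-exact:

* **Input.** The litterfall rate (Gaussian over the year, peak Julian day
  300, sd 20 d, truncated to the year and renormalized so the annual total
  is exactly 2.4 kg per metre of stream) times reach length, split wet/dry
  by the instantaneous wet fraction, entering with the fresh spectrum.
* **Exchange.** The discrete width change over the hour moves the
  proportional share of the source pool: expansion submerges
  `Δw/(w_BF−w)` of the dry stock, contraction strands `|Δw|/w` of the wet
  stock (POM assumed uniformly spread across the streambed).
* **Decay.** Exact per-bin exponential factors (wet rate K, dry rate
  F_WD K), so the stiffest bins never constrain the time step.
* **Transport.** Each reach exports the fraction `δ_i Δt` of every wet bin
  to its downstream neighbour (the outlet exports out of the network),
  computed from pre-step masses in one explicit pass;
  `δ = μ (τ−τ0)⁺ v / l` converted to d⁻¹ (τ0 = 8 Pa, μ = 0.03 Pa⁻¹).

During overbank instants the dry stock is transferred to a floodplain-loss
term and input and exchange are suspended; wet-pool decay and transport
continue (transport is most active precisely during floods).

The scheme is forward Euler with a 1 h cap; the number of sub-steps per
hour grows so that the largest transported or exchanged fraction per
sub-step stays at or below 0.5, which preserves positivity (a kernel
assertion guards it). Halving the step changes decade-scale exported mass
by well under 1 %. Runs start from empty spectra with a 2-year spin-up
excluded from all accounting; the budget identity
input = wet degradation + dry degradation + export + overbank loss +
storage change holds to round-off (~1e-13 relative) on every run, so the
0.1 % closure tolerance in the tests is diagnostic of coding errors, not
of the scheme.

Backbone fate summaries aggregate cumulative per-reach masses over nested
subcatchments whose outlets lie on the main stem (always following the
larger tributary upstream); exported-POM reactivity is the
export-flux-weighted mean wet-reference K. Fractions are reported with the
storage and overbank terms shown explicitly so they sum to 1.

## Litterbag fitting

`simulate_afdm` evaluates AFDM remaining for arbitrary wet/dry exposure
schedules, numerically on a 128-bin grid whose span adapts to the Gamma
quantiles (so that shapes down to ν = 0.1 keep their mass on-grid), or
exactly via the effective-time closed form. Fitting minimizes the RMSE on
AFDM fractions (not log fractions) over (ν, ⟨K_W,LF⟩, F_WD) with
L-BFGS-B on log10-transformed parameters, bounds
⟨K⟩ ∈ [1e-4, 1] d⁻¹, ν ∈ [0.1, 10], F_WD ∈ [0.01, 1], restarted from 16
Latin-hypercube points (seeded, deterministic). F_WD is only fitted when
the design includes dry exposure; wet-only designs raise unless it is
pinned. A solution on a bound flags non-convergence (e.g. a no-mass-loss
series drives ⟨K⟩ to its floor). Parameters are shared across the series
passed to one model; per-series fits are just one-series models.

The synthetic-series generator draws observation schedules through the
exact continuum solution and adds Gaussian observation noise (sd 0.02 of
the fraction by default, none at t = 0 where the reference mass is known),
emulating simultaneous and sequential litterbag designs. It does not
emulate leaching spikes in the first days, mesh-size effects,
fragmentation losses during handling, or correlated errors within a
retrieval campaign — parameter-recovery results therefore show estimator
correctness under the model, not robustness to those field artefacts.

## Problem sizes used by the test suite

Statistical checks run at sizes where Monte-Carlo error is well below the
asserted tolerances: 50-year hourly series for flow/width CVs, 200-year
series for bankfull and dry-fraction statistics, 2000-year daily series
for the closed-form CV limit, decade-scale POM runs on catchments of 3–20
reaches, and 20 replicates for noisy parameter recovery. The full 512²
catchment (~1400 reaches) is exercised by `scripts/full_scale.py`, which
reports per-scenario budgets and backbone fate tables.

## Known limitations

* Transport magnitude is the least constrained part of the model: μ and τ0
  control the residence time of POM in the network, and network-scale
  export fractions respond strongly to both (the sensitivity sweep makes
  this explicit). Ordering results (across scenarios and parameters) are
  robust; absolute export percentages should be read as
  parameter-conditional.
* Spatially uniform rainfall makes all reaches wet and dry in unison; real
  networks desynchronize, which weakens network-scale exchange pulses.
* No floodplain return flux: overbank losses are terminal. No longitudinal
  drying (baseflow keeps every reach wetted), no hyporheic storage, no
  particle-size classes, wood or fine detritus, and no dissolved organic
  matter.
* The at-a-station exponents are fixed network-wide; bankfull geometry is
  in equilibrium with the simulated flow regime, so flow variability and
  streambed size cannot be varied independently.
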