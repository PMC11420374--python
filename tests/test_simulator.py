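import numpy as np
import pytest

from riverpom.hydrology import RainScenario
from riverpom.reactivity import RCParameters, analytic_mass_remaining
from riverpom.simulator import (
    LitterfallSchedule,
    PomForcing,
    SimulationConfig,
    TransportParameters,
    exchange_flux,
    integrate_pom,
    litter_split,
    overbank_dump,
    run_simulation,
    summarize_fates,
    transport_rate,
)

MID = RainScenario(0.2, 10.0)


def constant_forcing(
    n_reaches,
    n_steps,
    delta=0.0,
    wet_frac=None,
    litter=0.0,
    overbank=None,
):
    """Synthetic rank-one forcing with direct control of the transport rate
    (taucoef=2, tau0=1, rd=rv=1 makes delta_i = vcoef_i exactly)."""
    ones = np.ones(n_steps)
    return PomForcing(
        rd=ones,
        rv=ones,
        wet_frac=ones.copy() if wet_frac is None else np.asarray(wet_frac, float),
        overbank=np.zeros(n_steps, bool) if overbank is None else overbank,
        litter=np.full(n_steps, litter),
        taucoef=np.full(n_reaches, 2.0),
        vcoef=np.full(n_reaches, float(delta)),
        tau0=1.0,
    )


def chain_network(n, length=1000.0):
    from riverpom.network import RiverNetwork, assign_slopes

    areas = np.arange(1, n + 1) * 1e6
    net = RiverNetwork(
        length=np.full(n, length),
        area=areas,
        incr_area=np.full(n, 1e6),
        slope=np.full(n, np.nan),
        downstream=np.array(list(range(1, n)) + [-1], dtype=np.int64),
        outlet=n - 1,
    )
    return assign_slopes(net, 0.01)


def inert_config(**kw):
    """Configuration whose decay is negligible (mean K ~ 1e-12 / d)."""
    return SimulationConfig(
        scenario=MID, rc=RCParameters(nu=1.0, mean_k_wet=1e-12, f_wd=0.2), **kw
    )


# -- elementary rates --------------------------------------------------------


def test_transport_rate_hand_value():
    p = TransportParameters(tau0=8.0, mu=0.03)
    assert transport_rate(10.0, 0.5, 1000.0, p) == pytest.approx(2.592)
    assert transport_rate(8.0, 0.5, 1000.0, p) == 0.0
    assert transport_rate(7.0, 0.5, 1000.0, p) == 0.0
    # linear in the excess stress above threshold
    d1 = transport_rate(9.0, 0.5, 1000.0, p)
    d2 = transport_rate(10.0, 0.5, 1000.0, p)
    d3 = transport_rate(11.0, 0.5, 1000.0, p)
    assert d3 - d2 == pytest.approx(d2 - d1)


def test_exchange_flux_branches():
    rho_d = np.full(4, 0.25)  # 1 kg dry, uniform
    rho_w = np.full(4, 0.5)
    # expansion: 1 m/h into 5 m of dry bed moves 1/5 of the dry stock per h
    flux = exchange_flux(rho_d, rho_w, w=5.0, w_bf=10.0, dw_dt=1.0)
    assert flux.sum() == pytest.approx(0.2)
    assert np.all(flux > 0)
    # contraction strands the proportional share of the wet stock
    flux = exchange_flux(rho_d, rho_w, w=5.0, w_bf=10.0, dw_dt=-1.0)
    assert flux.sum() == pytest.approx(-2.0 / 5.0)
    assert exchange_flux(rho_d, rho_w, 5.0, 10.0, 0.0).sum() == 0.0
    with pytest.raises(ValueError):
        exchange_flux(rho_d, rho_w, 10.0, 10.0, 1.0)


def test_litterfall_schedule_total_peak_and_split():
    sched = LitterfallSchedule()
    hourly = sched.hourly_rates()
    assert hourly.sum() / 24.0 == pytest.approx(2.4, rel=1e-12)
    assert np.argmax(hourly) / 24.0 == pytest.approx(300.0, abs=1.0)
    wet, dry = litter_split(sched.rate(300.0), 500.0, 0.6)
    assert wet / (wet + dry) == pytest.approx(0.6)
    assert wet + dry == pytest.approx(sched.rate(300.0) * 500.0)


def test_overbank_dump():
    zeroed, lost = overbank_dump(np.array([0.1, 0.2]))
    assert lost == pytest.approx(0.3)
    assert np.all(zeroed == 0)


# -- kernel behaviour --------------------------------------------------------


def test_wet_decay_in_kernel_matches_analytic_gamma_curve():
    net = chain_network(1)
    cfg = SimulationConfig(scenario=MID)
    days = 400
    forcing = constant_forcing(1, days * 24)
    from riverpom.reactivity import ReactivityGrid, initial_spectrum

    grid = ReactivityGrid.for_params(cfg.rc, cfg.n_bins)
    init = initial_spectrum(cfg.rc, grid, 1.0).mass[None, :]
    res = integrate_pom(net, forcing, cfg, initial_wet=init)
    expect = analytic_mass_remaining(days, cfg.rc)
    assert res.wet.sum() == pytest.approx(expect, rel=0.005)
    assert res.budget.closure_error < 1e-9


def test_pulse_through_two_reach_cascade_matches_closed_form():
    # with constant transport rate delta and no decay, the chain is a linear
    # compartment cascade: m2(t) = m0 * delta * t * exp(-delta t)
    net = chain_network(2)
    cfg = inert_config()
    delta = 0.5  # 1/d
    days = 30
    forcing = constant_forcing(2, days * 24, delta=delta)
    init = np.zeros((2, cfg.n_bins))
    from riverpom.reactivity import ReactivityGrid, initial_spectrum

    grid = ReactivityGrid.for_params(cfg.rc, cfg.n_bins)
    init[0] = initial_spectrum(cfg.rc, grid, 1.0).mass
    res = integrate_pom(net, forcing, cfg, initial_wet=init)
    # cumulative export: 1 - e^{-dt}(1 + dt)
    expect_total = 1 - np.exp(-delta * days) * (1 + delta * days)
    assert res.transported_out[1] == pytest.approx(expect_total, rel=0.02)
    # the export flux delta * m2(t) peaks at t = 1/delta
    t = (np.arange(days * 24) + 1) / 24.0
    t_peak = t[np.argmax(res.outlet_export_series)]
    assert t_peak == pytest.approx(1.0 / delta, rel=0.1)
    # and the whole series tracks delta * m2(t) shifted by the one-step
    # transport lag of the explicit scheme
    m2 = delta * t * np.exp(-delta * t)
    expect_series = delta * m2 / 24.0
    err = np.abs(res.outlet_export_series[1:] - expect_series[:-1])
    assert err.max() < 0.05 * expect_series.max()
    assert res.budget.closure_error < 1e-9


def test_contraction_expansion_cycle_conserves_mass():
    net = chain_network(1)
    cfg = inert_config()
    steps = 24 * 20
    x = 0.55 + 0.4 * np.sin(np.linspace(0, 8 * np.pi, steps))
    forcing = constant_forcing(1, steps, wet_frac=x)
    init = np.zeros((1, cfg.n_bins))
    init[0, 10] = 1.0
    res = integrate_pom(net, forcing, cfg, initial_dry=init)
    assert res.storage_end.sum() == pytest.approx(1.0, rel=1e-9)
    assert res.wet.sum() > 0 and res.dry.sum() > 0  # mass really moved


def test_overbank_zeroes_dry_stock_and_books_the_loss():
    net = chain_network(1)
    cfg = inert_config()
    steps = 48
    over = np.zeros(steps, bool)
    over[24:30] = True
    forcing = constant_forcing(1, steps, overbank=over)
    init = np.zeros((1, cfg.n_bins))
    init[0, 5] = 0.3
    res = integrate_pom(net, forcing, cfg, initial_dry=init)
    assert res.overbank_loss.sum() == pytest.approx(0.3, rel=1e-12)
    assert res.dry.sum() == 0.0
    assert res.budget.closure_error < 1e-9


def test_no_overbank_means_no_overbank_loss(y_network):
    cfg = SimulationConfig(scenario=MID, years=1, spinup_years=0, seed=3)
    forcing_steps = 24 * 365
    forcing = constant_forcing(3, forcing_steps, litter=0.01)
    res = integrate_pom(y_network, forcing, cfg)
    assert res.overbank_loss.sum() == 0.0
    assert res.budget.closure_error < 1e-9


def test_positivity_under_violent_forcing():
    # transport rates far above 0.5/dt force the adaptive sub-stepping
    net = chain_network(3)
    cfg = SimulationConfig(scenario=MID)
    rng = np.random.default_rng(12)
    steps = 24 * 30
    forcing = constant_forcing(3, steps, delta=0.0, litter=0.05)
    forcing.vcoef = rng.uniform(0, 80.0, 3)  # delta up to 80 / d
    forcing.wet_frac = np.clip(rng.uniform(0.05, 1.0, steps), 0.05, 0.999)
    res = integrate_pom(net, forcing, cfg)
    assert np.all(res.wet >= 0) and np.all(res.dry >= 0)
    assert res.budget.closure_error < 1e-9


def test_halving_the_time_step_barely_changes_export(y_network):
    cfg = SimulationConfig(scenario=MID, years=1, spinup_years=0, seed=9)
    from riverpom.hydrology import DischargeField
    from riverpom.hydraulics import bankfull_discharge
    from riverpom.simulator import build_forcing

    field = DischargeField.from_scenario(y_network, MID, 1.0, seed=31)
    bf = DischargeField.from_scenario(np.array([1.0]), MID, 50, seed=32)
    ratio_bf = bankfull_discharge(bf.ratio)
    forcing = build_forcing(y_network, cfg, field, ratio_bf)
    res1 = integrate_pom(y_network, forcing, cfg)
    half = PomForcing(
        rd=np.repeat(forcing.rd, 2),
        rv=np.repeat(forcing.rv, 2),
        wet_frac=np.repeat(forcing.wet_frac, 2),
        overbank=np.repeat(forcing.overbank, 2),
        litter=np.repeat(forcing.litter, 2),
        taucoef=forcing.taucoef,
        vcoef=forcing.vcoef,
        tau0=forcing.tau0,
        dt_days=1.0 / 48.0,
    )
    res2 = integrate_pom(y_network, half, cfg)
    out1 = res1.transported_out[y_network.outlet]
    out2 = res2.transported_out[y_network.outlet]
    assert out1 == pytest.approx(out2, rel=0.01)


def test_forcing_rates_consistent_with_reference_formulas(y_network):
    # the rank-one factorization used by the kernel must reproduce the
    # plain per-reach transport rate delta = mu (tau - tau0)+ v / l
    from riverpom.hydrology import DischargeField
    from riverpom.hydraulics import geometry_at_mean_flow, instantaneous_geometry
    from riverpom.simulator import build_forcing

    cfg = SimulationConfig(scenario=MID, seed=0)
    field = DischargeField.from_scenario(y_network, MID, 1.0, seed=1)
    forcing = build_forcing(y_network, cfg, field, ratio_bf=2.0)
    for t in (100, 5000):
        ratio = field.ratio[t]
        for i in range(y_network.n_reaches):
            qbar = field.qbar[i]
            wbar, dbar = geometry_at_mean_flow(qbar)
            _, _, v, tau = instantaneous_geometry(
                qbar * ratio, qbar, wbar, dbar, y_network.slope[i]
            )
            expect = transport_rate(tau, v, y_network.length[i], cfg.transport)
            got = (
                forcing.vcoef[i]
                * max(forcing.taucoef[i] * forcing.rd[t] - forcing.tau0, 0.0)
                * forcing.rv[t]
            )
            assert got == pytest.approx(expect, rel=1e-10)


def test_full_run_budget_and_fates(y_network):
    cfg = SimulationConfig(scenario=MID, years=1, spinup_years=1, seed=17)
    res = run_simulation(y_network, cfg)
    assert res.budget.closure_error < 1e-3
    fates = summarize_fates(res, 3)
    sums = fates[
        ["frac_export", "frac_wet_deg", "frac_dry_deg", "frac_overbank", "frac_storage"]
    ].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-3)
    assert np.all(fates["mean_k_export"].dropna() <= cfg.rc.mean_k_wet + 1e-12)
    assert np.all(np.diff(fates["area_km2"]) > 0)
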