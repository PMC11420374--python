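import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riverpom.reactivity import (
    MassSpectrum,
    RCParameters,
    ReactivityGrid,
    analytic_mass_remaining,
    decay,
    initial_spectrum,
    mean_reactivity,
    transform_environment,
)

P = RCParameters(nu=1.0, mean_k_wet=0.01, f_wd=0.2)


@pytest.fixture
def grid():
    return ReactivityGrid.for_params(P, 64)


def test_grid_invariants(grid):
    assert np.all(np.diff(grid.edges) > 0)
    assert np.allclose(grid.centers, np.sqrt(grid.edges[:-1] * grid.edges[1:]))
    with pytest.raises(ValueError):
        ReactivityGrid(np.array([0.0, 1.0]))


def test_initial_spectrum_mass_and_mean(grid):
    spec = initial_spectrum(P, grid, 3.7)
    assert spec.total_mass == pytest.approx(3.7, rel=1e-12)
    assert mean_reactivity(spec) == pytest.approx(P.mean_k_wet, rel=0.005)


def test_initial_spectrum_exponential_bins_for_unit_shape(grid):
    # nu = 1: the Gamma is exponential, so bin masses are proportional to
    # differences of exp(-kappa K) at the edges
    spec = initial_spectrum(P, grid, 1.0)
    expect = -np.diff(np.exp(-P.kappa * grid.edges))
    expect /= expect.sum()
    assert np.allclose(spec.mass, expect, rtol=1e-9)


def test_spectrum_truncation_guard():
    bad = ReactivityGrid.logspaced(0.5, 1.0, 8)  # misses nearly all the mass
    with pytest.raises(ValueError):
        initial_spectrum(P, bad, 1.0)


@pytest.mark.parametrize(
    "env,t,expected",
    [
        ("wet", 100.0, 0.5),          # (100 / 200)^1
        ("dry", 100.0, 100.0 / 120.0),  # time slowed by F_WD = 0.2
    ],
)
def test_discretized_decay_matches_analytic(grid, env, t, expected):
    spec = initial_spectrum(P, grid, 1.0, environment=env)
    assert analytic_mass_remaining(t, P, env) == pytest.approx(expected, rel=1e-12)
    decayed, degraded = decay(spec, t)
    assert decayed.total_mass == pytest.approx(expected, rel=0.005)
    assert degraded == pytest.approx(1 - decayed.total_mass, abs=1e-12)


def test_decay_identity_and_validation(grid):
    spec = initial_spectrum(P, grid, 1.0)
    same, degraded = decay(spec, 0.0)
    assert degraded == 0.0
    assert np.array_equal(same.mass, spec.mass)
    with pytest.raises(ValueError):
        decay(spec, -1.0)


def test_mean_reactivity_follows_conjugate_update(grid):
    # after wet decay over t, the surviving Gamma mean is nu / (kappa + t)
    spec = initial_spectrum(P, grid, 1.0)
    aged, _ = decay(spec, 100.0)
    assert mean_reactivity(aged) == pytest.approx(P.nu / (P.kappa + 100.0), rel=0.01)


def test_environment_transform_is_mass_exact(grid):
    spec = initial_spectrum(P, grid, 2.0)
    dry = transform_environment(spec, "dry")
    back = transform_environment(dry, "wet")
    assert np.array_equal(back.mass, spec.mass)
    assert dry.total_mass == spec.total_mass
    # dry-coordinate mean reactivity is F_WD times the wet-coordinate mean
    dry_mean = float((dry.effective_rates * dry.mass).sum() / dry.total_mass)
    assert dry_mean == pytest.approx(P.f_wd * mean_reactivity(spec), rel=1e-12)


def test_analytic_solution_limits():
    assert analytic_mass_remaining(0.0, P) == 1.0
    t = np.geomspace(1, 1e5, 40)
    frac = analytic_mass_remaining(t, P)
    assert np.all(np.diff(frac) < 0)
    assert frac[-1] < 1e-2
    with pytest.raises(ValueError):
        analytic_mass_remaining(-1.0, P)


def test_discretization_error_shrinks_with_bin_doubling():
    times = np.array([1.0, 10.0, 100.0, 300.0, 1000.0])
    errs = []
    for n_bins in (32, 64, 128, 256):
        g = ReactivityGrid.for_params(P, n_bins)
        s = initial_spectrum(P, g, 1.0)
        num = np.array([(s.mass * np.exp(-g.centers * t)).sum() for t in times])
        errs.append(np.max(np.abs(num / analytic_mass_remaining(times, P) - 1)))
    assert errs[1] < 0.005  # reference 64-bin grid within 0.5 %
    assert all(a > b for a, b in zip(errs, errs[1:]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    dts=st.lists(st.floats(0.0, 200.0), min_size=1, max_size=6),
    env=st.sampled_from(["wet", "dry"]),
)
def test_decay_properties_hold_for_any_history(dts, env):
    grid = ReactivityGrid.for_params(P, 64)
    spec = initial_spectrum(P, grid, 1.0, environment=env)
    mean0 = mean_reactivity(spec)
    for dt in dts:
        spec, degraded = decay(spec, dt)
        assert degraded >= 0
        assert np.all(spec.mass >= 0)
    mean1 = mean_reactivity(spec)
    assert mean1 <= mean0 * (1 + 1e-12)  # decay removes high-K mass fastest
    # never exceeds the fresh-litter mean (up to quadrature bias of the grid)
    assert mean1 <= P.mean_k_wet * 1.01
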