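"""Scenario presets, configuration files, fixtures and sensitivity sweeps.

The three lateral-contraction scenarios differ only in rainfall frequency
``lambda`` and catchment response time ``u``; the mean event depth is always
derived so that every scenario delivers the same 250 mm of annual effective
precipitation (and hence the same mean annual flow), isolating the effect of
flow variability.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hydraulics import HydraulicConstants
from .hydrology import RainScenario
from .litterbag import generate_litterbag_series
from .network import RiverNetwork, generate_network
from .reactivity import RCParameters
from .simulator import (
    LitterfallSchedule,
    SimulationConfig,
    TransportParameters,
    run_simulation,
)

__all__ = [
    "SCENARIOS",
    "SENSITIVITY_GRID",
    "scenario",
    "load_config",
    "config_echo",
    "make_fixture",
    "sensitivity_sweep",
    "headwater_outlet_slope",
]

#: (lambda [1/d], u [d]) per lateral-contraction scenario
SCENARIOS: dict[str, tuple[float, float]] = {
    "low": (0.5, 20.0),
    "mid": (0.2, 10.0),
    "high": (0.05, 5.0),
}

#: sensitivity-analysis axes; the middle entry of each is the reference value
SENSITIVITY_GRID: dict[str, tuple[float, float, float]] = {
    "mean_k_wet": (0.005, 0.01, 0.02),
    "f_wd": (0.1, 0.2, 0.3),
    "mu": (0.012, 0.030, 0.046),
}

#: reference full-catchment configuration (512^2 pixels of 100 m)
REFERENCE_AREA_M2 = 512 * 512 * 100.0**2
REFERENCE_OUTLET_SLOPE = 0.001


def scenario(name: str, annual_depth: float = 250.0, baseflow_frac: float = 0.005) -> RainScenario:
    """Preset rain scenario by name (low | mid | high)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario '{name}' (choose from {sorted(SCENARIOS)})")
    lam, u = SCENARIOS[name]
    return RainScenario(lambda_=lam, u=u, annual_depth=annual_depth, baseflow_frac=baseflow_frac)


def headwater_outlet_slope(area_m2: float) -> float:
    """Outlet slope for a catchment embedded as a headwater subcatchment of
    the reference system, via the slope-area scaling law."""
    return REFERENCE_OUTLET_SLOPE * (area_m2 / REFERENCE_AREA_M2) ** -0.5


_DEFAULTS = {
    "scenario": "mid",
    "lambda": None,
    "u": None,
    "annual_depth_mm": 250.0,
    "baseflow_frac": 0.005,
    "nu": 1.0,
    "mean_k_wet": 0.01,
    "f_wd": 0.2,
    "tau0": 8.0,
    "mu": 0.030,
    "annual_litter": 2.4,
    "litter_peak_day": 300.0,
    "litter_sd_days": 20.0,
    "years": 10,
    "spinup_years": 2,
    "n_bins": 64,
    "bankfull_years": 200,
    "seed": 0,
}


def load_config(path) -> SimulationConfig:
    """Read a YAML run configuration, validate and fill defaults.

    Unknown keys and out-of-range values raise; a missing seed is filled
    with the default and reported in the echo. An empty file yields the full
    default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = {**_DEFAULTS, **raw}
    if cfg["lambda"] is not None and cfg["u"] is not None:
        rain = RainScenario(
            lambda_=float(cfg["lambda"]),
            u=float(cfg["u"]),
            annual_depth=float(cfg["annual_depth_mm"]),
            baseflow_frac=float(cfg["baseflow_frac"]),
        )
    else:
        rain = scenario(
            cfg["scenario"],
            annual_depth=float(cfg["annual_depth_mm"]),
            baseflow_frac=float(cfg["baseflow_frac"]),
        )
    return SimulationConfig(
        scenario=rain,
        rc=RCParameters(
            nu=float(cfg["nu"]),
            mean_k_wet=float(cfg["mean_k_wet"]),
            f_wd=float(cfg["f_wd"]),
        ),
        transport=TransportParameters(tau0=float(cfg["tau0"]), mu=float(cfg["mu"])),
        litterfall=LitterfallSchedule(
            annual_total=float(cfg["annual_litter"]),
            peak_day=float(cfg["litter_peak_day"]),
            sd_days=float(cfg["litter_sd_days"]),
        ),
        years=int(cfg["years"]),
        spinup_years=int(cfg["spinup_years"]),
        n_bins=int(cfg["n_bins"]),
        bankfull_years=int(cfg["bankfull_years"]),
        seed=int(cfg["seed"]),
    )


def config_echo(config: SimulationConfig) -> dict:
    """Flat, JSON-serializable echo of a configuration (run manifest)."""

    def flatten(obj, prefix=""):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if dataclasses.is_dataclass(v):
                out.update(flatten(v, f"{prefix}{f.name}."))
            else:
                out[f"{prefix}{f.name}"] = v
        return out

    return flatten(config)


def make_fixture(kind: str, seed: int = 0, outdir=".") -> Path:
    """Write a small deterministic input fixture to ``outdir``.

    kinds: ``tiny-network`` (an 8 x 8 lattice reach network as an edge
    list), ``litterbag`` (synthetic wet/dry and sequential AFDM series at
    the reference parameters), ``short-run`` (a 1-year mid-scenario YAML
    run configuration).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny-network":
        net = generate_network(
            8,
            pixel_len=100.0,
            area_threshold=20e4,
            s_outlet=headwater_outlet_slope(64 * 1e4),
            seed=seed,
        )
        path = outdir / "tiny_network.csv"
        net.to_csv(path)
        return path
    if kind == "litterbag":
        params = RCParameters()
        times = np.array([0.0, 7, 14, 30, 60, 100, 150, 220])
        rng = np.random.default_rng(seed)
        rows = []
        designs = {
            "wet": [("wet", float("inf"))],
            "dry": [("dry", float("inf"))],
            "seq_wet_dry": [("wet", 100.0), ("dry", float("inf"))],
            "seq_dry_wet": [("dry", 100.0), ("wet", float("inf"))],
        }
        def condition_at(phases, t):
            start = 0.0
            for c, dur in phases:
                if t <= start + dur + 1e-9:
                    return c
                start += dur
            return phases[-1][0]

        for sid, phases in designs.items():
            s = generate_litterbag_series(params, phases, times, 0.02, rng, sid)
            for t, f in zip(s.times, s.fractions):
                rows.append(
                    {
                        "time_d": t,
                        "afdm_frac": f,
                        "condition": condition_at(phases, t),
                        "series_id": sid,
                    }
                )
        path = outdir / "litterbags.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path
    if kind == "short-run":
        path = outdir / "short_run.yml"
        path.write_text(
            yaml.safe_dump(
                {"scenario": "mid", "years": 1, "spinup_years": 0, "seed": int(seed)}
            )
        )
        return path
    raise ValueError(f"unknown fixture kind '{kind}'")


def sensitivity_sweep(
    network: RiverNetwork,
    base_config: SimulationConfig,
    grid: dict[str, tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Run the parameter sensitivity grid for one contraction scenario.

    One POM run per grid point of (mu, <K_W,LF>, F_WD); every run shares the
    base configuration (and its seed, so the hydrological forcing is
    identical across points). Returns one row per point with the exported
    fraction and the exported mean reactivity normalized by the fresh-litter
    mean (K_W / <K_W,LF>).
    """
    grid = dict(SENSITIVITY_GRID if grid is None else grid)
    rows = []
    for mu in grid["mu"]:
        for mk in grid["mean_k_wet"]:
            for fwd in grid["f_wd"]:
                cfg = dataclasses.replace(
                    base_config,
                    rc=RCParameters(nu=base_config.rc.nu, mean_k_wet=mk, f_wd=fwd),
                    transport=TransportParameters(tau0=base_config.transport.tau0, mu=mu),
                )
                res = run_simulation(network, cfg)
                rows.append(
                    {
                        "mu": mu,
                        "mean_k_wet": mk,
                        "f_wd": fwd,
                        "frac_export": res.export_fraction,
                        "k_export_norm": res.export_mean_reactivity / mk,
                    }
                )
    return pd.DataFrame(rows)
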