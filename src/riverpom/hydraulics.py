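"""Hydraulic geometry: width, depth, velocity, shear stress, bankfull width.

Downstream scaling relates the channel geometry at mean flow to the mean
discharge (``wbar = B_w Qbar^beta_w``, ``dbar = B_d Qbar^beta_d``);
at-a-station scaling modulates it with the instantaneous discharge
(``w = wbar (Q/Qbar)^alpha_w`` etc.). Velocity follows from continuity and
the bottom shear stress from the quasi-uniform-flow approximation
``tau = gamma * d * s``.

The bankfull discharge of a reach is taken as the flood with a 2-year
recurrence interval, estimated as the empirical median of the annual maxima
of a long (default 200-year) hourly simulation; bankfull width is the
at-a-station width at that discharge. The ratio ``w(t)/w_BF`` is the wet
fraction of the streambed; its complement is the dry fraction exposed by
lateral hydrological contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydrology import DischargeField, RainScenario, cv

__all__ = [
    "HydraulicConstants",
    "geometry_at_mean_flow",
    "instantaneous_geometry",
    "bankfull_discharge",
    "bankfull",
    "wet_fraction_series",
    "dry_fraction_percent",
]

HOURS_PER_YEAR = 365 * 24


@dataclass(frozen=True)
class HydraulicConstants:
    """Downstream (B, beta) and at-a-station (alpha) scaling parameters plus
    the specific weight of water [N/m^3]."""

    b_w: float = 10.0
    beta_w: float = 0.5
    b_d: float = 0.25
    beta_d: float = 0.4
    alpha_w: float = 0.26
    alpha_d: float = 0.4
    gamma_w: float = 9810.0

    def __post_init__(self):
        for name in ("b_w", "beta_w", "b_d", "beta_d", "alpha_w", "alpha_d", "gamma_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def geometry_at_mean_flow(qbar, const: HydraulicConstants = HydraulicConstants()):
    """Width and depth at the mean discharge: (wbar, dbar) [m]."""
    qbar = np.asarray(qbar, dtype=float)
    if np.any(qbar <= 0):
        raise ValueError("mean discharge must be positive")
    return const.b_w * qbar**const.beta_w, const.b_d * qbar**const.beta_d


def instantaneous_geometry(
    q, qbar, wbar, dbar, slope, const: HydraulicConstants = HydraulicConstants()
):
    """At-a-station geometry (w, d, v, tau) for instantaneous discharge ``q``.

    Returns width [m], depth [m], velocity [m/s] (by continuity, so
    ``v * w * d == q`` to machine precision) and bottom shear stress [Pa].
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(np.asarray(qbar) <= 0):
        raise ValueError("discharges must be positive")
    rel = q / qbar
    w = wbar * rel**const.alpha_w
    d = dbar * rel**const.alpha_d
    v = q / (w * d)
    tau = const.gamma_w * d * np.asarray(slope)
    return w, d, v, tau


def bankfull_discharge(q_series: np.ndarray, hours_per_year: int = HOURS_PER_YEAR) -> float:
    """2-year-recurrence discharge: median of the annual-maximum series."""
    q = np.asarray(q_series, dtype=float)
    n_years = q.size // hours_per_year
    if n_years < 2:
        raise ValueError("need at least two complete years of discharge")
    ann_max = q[: n_years * hours_per_year].reshape(n_years, hours_per_year).max(axis=1)
    return float(np.median(ann_max))


def bankfull(
    network_or_areas,
    scenario: RainScenario,
    const: HydraulicConstants = HydraulicConstants(),
    years: int = 200,
    seed=None,
):
    """Per-reach bankfull discharge and width from a dedicated long run.

    Runs ``years`` of hourly hydrology (independent of any production run)
    and returns ``(q_bf, w_bf)`` arrays. Because forcing is uniform, the
    normalized 2-year flood ``Q_BF/Qbar`` is shared by all reaches.
    """
    if years < 10:
        raise ValueError("bankfull estimation needs at least 10 years")
    field = DischargeField.from_scenario(network_or_areas, scenario, years, seed=seed)
    ratio_bf = bankfull_discharge(field.ratio)
    qbar = field.qbar
    q_bf = qbar * ratio_bf
    wbar, _ = geometry_at_mean_flow(qbar, const)
    w_bf = wbar * ratio_bf**const.alpha_w
    return q_bf, w_bf


def wet_fraction_series(
    ratio: np.ndarray, ratio_bf: float, const: HydraulicConstants = HydraulicConstants()
) -> np.ndarray:
    """w(t)/w_BF from the normalized discharge series, clamped at 1 during
    overbank instants (Q > Q_BF)."""
    return np.minimum((np.asarray(ratio) / ratio_bf) ** const.alpha_w, 1.0)


def dry_fraction_percent(
    scenario: RainScenario,
    const: HydraulicConstants = HydraulicConstants(),
    years: int = 200,
    seed=None,
) -> float:
    """Time-averaged dry streambed percentage, 100 * (1 - E[w/w_BF]).

    Simulates ``years`` of hourly discharge for a single reach, sets the
    bankfull width at the median annual-maximum discharge of the same run,
    and averages the dry fraction of the streambed. The result is
    independent of reach size because the normalized discharge series is.
    """
    field = DischargeField.from_scenario(np.array([1.0]), scenario, years, seed=seed)
    ratio = field.ratio
    ratio_bf = bankfull_discharge(ratio)
    wet = wet_fraction_series(ratio, ratio_bf, const)
    return float(100.0 * (1.0 - wet.mean()))
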