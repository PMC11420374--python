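"""Stochastic effective rainfall and streamflow generation.

Daily effective (streamflow-producing) rainfall follows a marked Poisson
process: the number of events on a day is Poisson with rate ``lambda_``
(events per day) and each event carries an exponentially distributed depth
with mean ``alpha``. Daily totals are downscaled to hourly by assigning each
wet day a random event window (uniform duration 1-24 h, uniform start) and
exponential i.i.d. hourly intensities rescaled to conserve the daily total
exactly.

Each subcatchment converts rainfall to streamflow through an exponential
instantaneous unit hydrograph with mean response time ``u`` (a linear
reservoir, integrated with the exact exponential state update), plus a
constant baseflow equal to a small fraction of the subcatchment mean flow.
Flows are routed downstream instantaneously by summing tributaries in
topological order.

Because the forcing is spatially uniform and the rainfall-runoff filter is
linear, the discharge field is rank-one: ``Q_i(t) = A_i * g(t)`` where
``g(t)`` is the specific (per unit area) discharge. :class:`DischargeField`
stores this factorized form so that network-scale series of arbitrary length
stay cheap; the normalized series ``Q_i(t)/Qbar_i`` is then identical across
reaches, which is why all reaches share the same flow and width coefficients
of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import RiverNetwork

__all__ = [
    "RainScenario",
    "RainfallSeries",
    "DischargeField",
    "generate_daily_rainfall",
    "downscale_hourly",
    "subcatchment_flow",
    "route",
    "cv",
]

SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class RainScenario:
    """Effective-rainfall and catchment-response parameters.

    Parameters
    ----------
    lambda_ : float
        Rainfall event frequency [1/d].
    u : float
        Mean catchment response time of the unit hydrograph [d].
    annual_depth : float
        Mean annual effective precipitation depth [mm/y]; the mean event
        depth ``alpha`` is always derived from it so that scenarios with
        different ``lambda_`` share the same mean annual flow.
    baseflow_frac : float
        Constant baseflow as a fraction of the mean annual flow.
    """

    lambda_: float
    u: float
    annual_depth: float = 250.0
    baseflow_frac: float = 0.005

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.lambda_ * 1.0 > 1.0:
            raise ValueError("lambda_ * dt > 1 day^-1 is unphysical here")
        if self.u <= 0:
            raise ValueError("response time u must be positive")
        if not 0 <= self.baseflow_frac < 1:
            raise ValueError("baseflow_frac must be in [0, 1)")

    @property
    def alpha(self) -> float:
        """Mean daily event depth [mm]."""
        return self.annual_depth / (DAYS_PER_YEAR * self.lambda_)

    @property
    def mean_specific_flow(self) -> float:
        """lambda * alpha as a specific discharge [m/s per m^2], excluding
        baseflow."""
        return self.lambda_ * self.alpha / 1000.0 / SECONDS_PER_DAY


@dataclass
class RainfallSeries:
    """Hourly effective rainfall depths [mm] with their daily parent series."""

    hourly: np.ndarray
    daily: np.ndarray
    scenario: RainScenario
    seed: int | None = None

    @property
    def n_hours(self) -> int:
        return self.hourly.size


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_daily_rainfall(
    scenario: RainScenario,
    n_days: int,
    seed=None,
    return_events: bool = False,
):
    """Daily effective rainfall depths [mm] from the marked Poisson process.

    Event counts per day are Poisson(``lambda_``); each event depth is
    exponential with mean ``alpha``, so a day's depth is the sum of its event
    marks. With ``return_events=True`` the individual event marks are also
    returned (their marginal is exactly Exponential(alpha)).
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = _rng(seed)
    counts = rng.poisson(scenario.lambda_, size=n_days)
    total_events = int(counts.sum())
    marks = rng.exponential(scenario.alpha, size=total_events)
    daily = np.zeros(n_days)
    np.add.at(daily, np.repeat(np.arange(n_days), counts), marks)
    if return_events:
        return daily, marks
    return daily


def downscale_hourly(daily: np.ndarray, scenario: RainScenario, seed=None) -> RainfallSeries:
    """Distribute daily depths over random intra-day event windows.

    Each wet day receives an integer duration D ~ Uniform{1..24} and start
    hour ~ Uniform{0..24-D}; within the window, hourly intensities are drawn
    i.i.d. exponential and rescaled so the hourly sum equals the daily depth
    exactly.
    """
    daily = np.asarray(daily, dtype=float)
    if np.any(~np.isfinite(daily)) or np.any(daily < 0):
        raise ValueError("daily series must be finite and non-negative")
    rng = _rng(seed)
    hourly = np.zeros(daily.size * 24)
    wet = np.nonzero(daily > 0)[0]
    for d in wet:
        dur = int(rng.integers(1, 25))
        start = int(rng.integers(0, 25 - dur))
        w = rng.exponential(1.0, size=dur)
        w *= daily[d] / w.sum()
        hourly[d * 24 + start : d * 24 + start + dur] = w
    return RainfallSeries(hourly=hourly, daily=daily, scenario=scenario)


def subcatchment_flow(
    rain_mm: np.ndarray,
    incr_area: float,
    scenario: RainScenario,
    dt_days: float = 1.0 / 24.0,
    initial_storage: float | None = None,
) -> np.ndarray:
    """Streamflow q_i(t) [m^3/s] of one subcatchment from a rainfall series.

    Linear-reservoir (exponential IUH) response with exact per-step decay:
    each rainfall depth enters the reservoir as an impulse at its time step,
    the sampled discharge is storage / u, and storage decays by
    ``exp(-dt/u)`` between steps. Baseflow is ``baseflow_frac`` of the
    subcatchment mean flow ``lambda * alpha * a``.
    """
    if incr_area <= 0:
        raise ValueError("incremental area must be positive")
    if scenario.u <= 0:
        raise ValueError("response time u must be positive")
    rain_m = np.asarray(rain_mm, dtype=float) / 1000.0
    u_s = scenario.u * SECONDS_PER_DAY
    if initial_storage is None:
        # stationary mean storage, avoids a start-up transient
        initial_storage = scenario.mean_specific_flow * incr_area * u_s
    decay = np.exp(-dt_days / scenario.u)
    storage = float(initial_storage)
    q = np.empty(rain_m.size)
    vol = rain_m * incr_area
    for t in range(rain_m.size):
        storage += vol[t]
        q[t] = storage / u_s
        storage *= decay
    baseflow = scenario.baseflow_frac * scenario.mean_specific_flow * incr_area
    return q + baseflow


def route(network: RiverNetwork, q: np.ndarray) -> np.ndarray:
    """Instantaneously route per-reach local inflows down the network.

    ``q`` has shape (n_reaches, n_times); returns Q of the same shape with
    ``Q_i(t) = sum_j W_ji Q_j(t) + q_i(t)`` evaluated in topological order.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[0] != network.n_reaches:
        raise ValueError("q must have one row per reach")
    Q = q.copy()
    for j in network.topo_order():
        i = int(network.downstream[j])
        if i >= 0:
            Q[i] += Q[j]
    return Q


def cv(series: np.ndarray) -> float:
    """Coefficient of variation: standard deviation over mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for a coefficient of variation")
    m = x.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(x.std() / m)


@dataclass
class DischargeField:
    """Per-reach discharge under spatially uniform forcing, factorized as
    ``Q_i(t) = A_i * specific(t)`` (specific discharge includes baseflow)."""

    areas: np.ndarray            # drained areas A_i [m^2]
    specific: np.ndarray         # shared specific discharge series [m/s]
    scenario: RainScenario

    @property
    def n_hours(self) -> int:
        return self.specific.size

    @property
    def qbar(self) -> np.ndarray:
        """Theoretical mean discharge per reach, baseflow included [m^3/s]."""
        m = self.scenario.mean_specific_flow
        return self.areas * m * (1.0 + self.scenario.baseflow_frac)

    @property
    def ratio(self) -> np.ndarray:
        """Shared normalized series Q_i(t)/Qbar_i (identical for all reaches)."""
        m = self.scenario.mean_specific_flow
        return self.specific / (m * (1.0 + self.scenario.baseflow_frac))

    def discharge(self, reach: int) -> np.ndarray:
        return self.areas[reach] * self.specific

    @classmethod
    def from_scenario(
        cls,
        network_or_areas,
        scenario: RainScenario,
        years: float,
        seed=None,
        dt_days: float = 1.0 / 24.0,
    ) -> "DischargeField":
        """Simulate a shared rainfall series and build the discharge field.

        ``network_or_areas`` is a :class:`RiverNetwork` (drained areas used)
        or an array of areas [m^2]. One rainfall series drives all
        subcatchments (spatially uniform forcing).
        """
        if isinstance(network_or_areas, RiverNetwork):
            areas = np.asarray(network_or_areas.area, dtype=float)
        else:
            areas = np.atleast_1d(np.asarray(network_or_areas, dtype=float))
        rng = _rng(seed)
        n_days = int(round(years * DAYS_PER_YEAR))
        daily = generate_daily_rainfall(scenario, n_days, rng)
        if dt_days == 1.0:
            rain = daily
        else:
            rain = downscale_hourly(daily, scenario, rng).hourly
        specific = subcatchment_flow(rain, 1.0, scenario, dt_days=dt_days)
        return cls(areas=areas, specific=specific, scenario=scenario)
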