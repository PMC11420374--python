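import numpy as np
import pytest

from riverpom.config import headwater_outlet_slope
from riverpom.network import (
    LatticeCatchment,
    RiverNetwork,
    assign_slopes,
    generate_network,
)


def build_hand_lattice() -> LatticeCatchment:
    """8 x 8 drainage with a hand-traceable structure.

    Every pixel in rows 1..7 flows north along its column; row 0 flows west
    to the outlet at (0, 0). Drained areas follow by counting.
    """
    n = 8
    flow = np.full(n * n, -1, dtype=np.int64)
    for r in range(1, n):
        for c in range(n):
            flow[r * n + c] = (r - 1) * n + c
    for c in range(1, n):
        flow[c] = c - 1
    area = np.zeros(n * n, dtype=np.int64)
    for r in range(n):
        for c in range(n):
            area[r * n + c] = n - r if r > 0 else n * (n - c)
    return LatticeCatchment(grid_n=n, pixel_len=100.0, flow_dir=flow, drained_area=area, outlet=0)


@pytest.fixture
def hand_lattice() -> LatticeCatchment:
    lat = build_hand_lattice()
    lat.validate()
    return lat


@pytest.fixture
def y_network() -> RiverNetwork:
    """Three reaches: two headwaters (0, 1) joining at the outlet reach 2,
    sized and sloped as a 10 km^2 headwater subcatchment of the reference
    2625 km^2 system."""
    net = RiverNetwork(
        length=np.array([1500.0, 2000.0, 1000.0]),
        area=np.array([3e6, 4e6, 10e6]),
        incr_area=np.array([3e6, 4e6, 3e6]),
        slope=np.full(3, np.nan),
        downstream=np.array([2, 2, -1], dtype=np.int64),
        outlet=2,
    )
    return assign_slopes(net, headwater_outlet_slope(1e7))


@pytest.fixture(scope="session")
def tiny_ocn() -> RiverNetwork:
    """Small annealed catchment (16^2 pixels, ~26 km^2) with slopes
    consistent with a headwater subcatchment of the reference system."""
    area = 16 * 16 * 1e4
    return generate_network(
        16, area_threshold=2e5, s_outlet=headwater_outlet_slope(area), seed=2
    )


@pytest.fixture(scope="session")
def small_ocn() -> RiverNetwork:
    """Reduced 64^2 catchment (~41 km^2) for network-scale pattern tests."""
    area = 64 * 64 * 1e4
    return generate_network(
        64, area_threshold=1e6, s_outlet=headwater_outlet_slope(area), seed=5
    )
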