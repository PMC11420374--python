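"""Synthetic river networks on a square lattice.

An optimal channel network (OCN) is a spanning drainage tree on a pixel
lattice that minimizes the total energy dissipation functional
``E = sum_p A_p^0.5`` (drained area in pixels). Such networks share the
aggregation statistics (Horton ratios, area exceedance exponents) of real
river networks and are standard synthetic catchments for network-scale
ecological modelling.

The module provides:

* :func:`generate_drainage` — simulated annealing of the OCN energy from a
  random spanning drainage (Wilson's algorithm), single flow direction.
* :func:`extract_reaches` — channelization by a drained-area threshold and
  segmentation of channel pixels into reaches between confluences.
* :func:`assign_slopes` — downstream slope scaling s_i = s_O (A_i/A_O)^-0.5.
* Backbone utilities and a plain-text edge-list reader/writer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LatticeCatchment",
    "RiverNetwork",
    "generate_drainage",
    "extract_reaches",
    "assign_slopes",
    "backbone_subcatchments",
    "generate_network",
    "ocn_energy",
]

# 8-connected neighbourhood: 4 cardinal then 4 diagonal moves
_DR = np.array([-1, 1, 0, 0, -1, -1, 1, 1], dtype=np.int64)
_DC = np.array([0, 0, -1, 1, -1, 1, -1, 1], dtype=np.int64)
_DIAG = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int64)


@dataclass
class LatticeCatchment:
    """Pixel-level spanning drainage on an ``grid_n x grid_n`` lattice.

    ``flow_dir[p]`` is the flat index of the single downstream neighbour of
    pixel ``p`` (-1 at the outlet). ``drained_area`` counts upstream pixels,
    inclusive of the pixel itself.
    """

    grid_n: int
    pixel_len: float
    flow_dir: np.ndarray
    drained_area: np.ndarray
    outlet: int

    @property
    def n_pixels(self) -> int:
        return self.grid_n * self.grid_n

    @property
    def energy(self) -> float:
        return float(np.sqrt(self.drained_area.astype(float)).sum())

    def validate(self) -> None:
        n = self.n_pixels
        if self.flow_dir[self.outlet] != -1:
            raise ValueError("outlet must have no downstream neighbour")
        if int(self.drained_area[self.outlet]) != n:
            raise ValueError("outlet must drain the whole lattice")
        # spanning-tree check: every pixel reaches the outlet without cycles
        seen = np.zeros(n, dtype=bool)
        for p in range(n):
            path = []
            q = p
            while q != self.outlet and not seen[q]:
                path.append(q)
                q = int(self.flow_dir[q])
                if len(path) > n:
                    raise ValueError("cycle detected in flow directions")
            seen[p] = True
            for r in path:
                seen[r] = True


@dataclass
class RiverNetwork:
    """Reach-level river network extracted from a lattice drainage.

    Arrays are indexed by 0-based reach id. ``downstream[i]`` is the id of
    the reach that reach ``i`` drains into (-1 at the outlet); this encodes
    the connectivity matrix W (W_ji = 1 iff downstream[j] == i).
    """

    length: np.ndarray       # reach length l_i [m]
    area: np.ndarray         # drained catchment area A_i [m^2]
    incr_area: np.ndarray    # incremental (directly drained) area a_i [m^2]
    slope: np.ndarray        # reach slope s_i [-] (NaN until assigned)
    downstream: np.ndarray   # downstream reach id, -1 at outlet
    outlet: int
    pixel_len: float = 100.0

    @property
    def n_reaches(self) -> int:
        return self.length.size

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_reaches)]
        for j, i in enumerate(self.downstream):
            if i >= 0:
                kids[int(i)].append(j)
        return kids

    def topo_order(self) -> np.ndarray:
        """Reach ids ordered so every reach precedes its downstream reach."""
        n = self.n_reaches
        indeg = np.zeros(n, dtype=np.int64)
        for i in self.downstream:
            if i >= 0:
                indeg[int(i)] += 1
        order = np.empty(n, dtype=np.int64)
        stack = [i for i in range(n) if indeg[i] == 0]
        k = 0
        while stack:
            j = stack.pop()
            order[k] = j
            k += 1
            i = int(self.downstream[j])
            if i >= 0:
                indeg[i] -= 1
                if indeg[i] == 0:
                    stack.append(i)
        if k != n:
            raise ValueError("network connectivity contains a cycle")
        return order

    def upstream_accumulate(self, x: np.ndarray) -> np.ndarray:
        """Sum a per-reach quantity over each reach's upstream subcatchment."""
        out = np.array(x, dtype=float, copy=True)
        for j in self.topo_order():
            i = int(self.downstream[j])
            if i >= 0:
                out[i] += out[j]
        return out

    def connectivity_matrix(self):
        """Sparse W with W[j, i] = 1 iff reach j drains directly into i."""
        from scipy import sparse

        j = np.nonzero(self.downstream >= 0)[0]
        i = self.downstream[j]
        n = self.n_reaches
        return sparse.coo_matrix(
            (np.ones(j.size), (j, i)), shape=(n, n)
        ).tocsr()

    def backbone(self) -> np.ndarray:
        """Main-stem reach ids, source to outlet, following the larger
        drained area at every confluence (ids in increasing-area order)."""
        kids = self.children()
        path = [self.outlet]
        while kids[path[-1]]:
            up = kids[path[-1]]
            path.append(max(up, key=lambda j: self.area[j]))
        return np.array(path[::-1], dtype=np.int64)

    def validate(self) -> None:
        self.topo_order()  # raises on cycles
        total = self.incr_area.sum()
        if not math.isclose(total, float(self.area[self.outlet]), rel_tol=1e-9):
            raise ValueError("incremental areas do not sum to the outlet area")
        up = self.upstream_accumulate(self.incr_area)
        if not np.allclose(up, self.area, rtol=1e-9):
            raise ValueError("A_i != a_i + sum of tributary areas")

    # -- plain-text edge list -------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "reach_id": np.arange(self.n_reaches),
                "downstream_id": self.downstream,
                "length_m": self.length,
                "area_m2": self.area,
                "incr_area_m2": self.incr_area,
                "slope": self.slope,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiverNetwork":
        df = pd.read_csv(path)
        down = df["downstream_id"].to_numpy(dtype=np.int64)
        outlet = int(np.nonzero(down == -1)[0][0])
        net = cls(
            length=df["length_m"].to_numpy(dtype=float),
            area=df["area_m2"].to_numpy(dtype=float),
            incr_area=df["incr_area_m2"].to_numpy(dtype=float),
            slope=df["slope"].to_numpy(dtype=float),
            downstream=down,
            outlet=outlet,
        )
        net.validate()
        return net


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _wilson_tree(grid_n, outlet, seed):
    """Random spanning drainage via Wilson's loop-erased random walks."""
    np.random.seed(seed)
    n = grid_n * grid_n
    recv = np.full(n, -1, dtype=np.int64)
    in_tree = np.zeros(n, dtype=np.uint8)
    in_tree[outlet] = 1
    for start in range(n):
        if in_tree[start]:
            continue
        # random walk, overwriting recv performs the loop erasure
        p = start
        while not in_tree[p]:
            r = p // grid_n
            c = p % grid_n
            while True:
                k = np.random.randint(8)
                rr = r + _DR[k]
                cc = c + _DC[k]
                if 0 <= rr < grid_n and 0 <= cc < grid_n:
                    break
            q = rr * grid_n + cc
            recv[p] = q
            p = q
        # commit the loop-erased path
        p = start
        while not in_tree[p]:
            in_tree[p] = 1
            p = recv[p]
    return recv


@njit(cache=True)
def _drained_areas(recv):
    n = recv.size
    indeg = np.zeros(n, dtype=np.int64)
    for p in range(n):
        q = recv[p]
        if q >= 0:
            indeg[q] += 1
    area = np.ones(n, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    m = 0
    for p in range(n):
        if indeg[p] == 0:
            stack[m] = p
            m += 1
    while m > 0:
        m -= 1
        p = stack[m]
        q = recv[p]
        if q >= 0:
            area[q] += area[p]
            indeg[q] -= 1
            if indeg[q] == 0:
                stack[m] = q
                m += 1
    return area


@njit(cache=True)
def _anneal(recv, area, grid_n, outlet, n_iter, t_start, t_end, seed):
    """Metropolis annealing of the OCN energy sum(sqrt(A)).

    Proposal: redirect one random pixel to a random in-grid neighbour;
    rejected outright if the move creates a cycle. Acceptance follows the
    Metropolis rule with a geometric temperature schedule.
    """
    np.random.seed(seed)
    n = grid_n * grid_n
    path_old = np.empty(n, dtype=np.int64)
    path_new = np.empty(n, dtype=np.int64)
    energy = 0.0
    for p in range(n):
        energy += math.sqrt(area[p])
    if n_iter <= 0:
        return energy
    cool = (t_end / t_start) ** (1.0 / n_iter)
    temp = t_start
    for _ in range(n_iter):
        temp *= cool
        p = np.random.randint(n)
        if p == outlet:
            continue
        r = p // grid_n
        c = p % grid_n
        k = np.random.randint(8)
        rr = r + _DR[k]
        cc = c + _DC[k]
        if rr < 0 or rr >= grid_n or cc < 0 or cc >= grid_n:
            continue
        q = rr * grid_n + cc
        if q == recv[p]:
            continue
        # cycle check and new downstream path (q -> outlet)
        n2 = 0
        ok = True
        x = q
        while x >= 0:
            if x == p:
                ok = False
                break
            path_new[n2] = x
            n2 += 1
            x = recv[x]
        if not ok:
            continue
        # old downstream path (current receiver -> outlet)
        n1 = 0
        x = recv[p]
        while x >= 0:
            path_old[n1] = x
            n1 += 1
            x = recv[x]
        # strip the shared tail below the junction of both paths
        i1 = n1 - 1
        i2 = n2 - 1
        while i1 >= 0 and i2 >= 0 and path_old[i1] == path_new[i2]:
            i1 -= 1
            i2 -= 1
        ap = area[p]
        d_en = 0.0
        for t in range(i1 + 1):
            a = area[path_old[t]]
            d_en += math.sqrt(a - ap) - math.sqrt(a)
        for t in range(i2 + 1):
            a = area[path_new[t]]
            d_en += math.sqrt(a + ap) - math.sqrt(a)
        if d_en <= 0.0 or np.random.random() < math.exp(-d_en / temp):
            for t in range(i1 + 1):
                area[path_old[t]] -= ap
            for t in range(i2 + 1):
                area[path_new[t]] += ap
            recv[p] = q
            energy += d_en
    return energy


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ocn_energy(lattice: LatticeCatchment) -> float:
    """Total energy dissipation sum over pixels of sqrt(drained area)."""
    return lattice.energy


def generate_drainage(
    grid_n: int,
    pixel_len: float = 100.0,
    seed: int = 0,
    n_iter: int | None = None,
    t_start: float = 1.0,
    t_end: float = 1e-4,
) -> LatticeCatchment:
    """Generate an OCN-like spanning drainage by simulated annealing.

    Starts from a uniform random spanning drainage (Wilson's algorithm)
    rooted at an outlet placed mid-edge of the lattice and anneals the
    energy ``sum_p A_p^0.5`` with single-flow-direction redirection moves.
    ``n_iter=0`` returns the random initial drainage unchanged. Deterministic
    given ``seed``.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be at least 2")
    n = grid_n * grid_n
    if n_iter is None:
        n_iter = 30 * n
    if n_iter < 0:
        raise ValueError("n_iter must be non-negative")
    ss = np.random.SeedSequence(seed)
    s_tree, s_anneal = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    outlet = (grid_n // 2) * grid_n  # mid-edge (left border) pixel
    recv = _wilson_tree(grid_n, outlet, s_tree)
    area = _drained_areas(recv)
    _anneal(recv, area, grid_n, outlet, n_iter, t_start, t_end, s_anneal)
    if int(area[outlet]) != n:  # internal assertion: annealing kept a tree
        raise AssertionError("annealing corrupted the drainage tree")
    return LatticeCatchment(
        grid_n=grid_n,
        pixel_len=float(pixel_len),
        flow_dir=recv,
        drained_area=area,
        outlet=outlet,
    )


def _step_length(p: int, q: int, grid_n: int, pixel_len: float) -> float:
    dr = abs(p // grid_n - q // grid_n)
    dc = abs(p % grid_n - q % grid_n)
    return pixel_len * math.sqrt(2.0) if (dr and dc) else pixel_len


def extract_reaches(lattice: LatticeCatchment, area_threshold: float) -> RiverNetwork:
    """Extract the reach network from a lattice drainage.

    Channel pixels are those whose drained area (in m^2) meets
    ``area_threshold``; maximal channel-pixel chains between confluences form
    reaches. Each channel pixel contributes the length of its outgoing step
    (the outlet pixel contributes one pixel length). Every lattice pixel is
    attributed to the first channel reach met along its flow path, which
    defines the incremental areas.
    """
    n = lattice.n_pixels
    grid_n = lattice.grid_n
    px2 = lattice.pixel_len**2
    total = n * px2
    if not (0 < area_threshold <= total):
        raise ValueError(
            f"no channel: threshold {area_threshold} outside (0, {total}]"
        )
    thr_pix = area_threshold / px2
    is_chan = lattice.drained_area >= thr_pix
    chan = np.nonzero(is_chan)[0]
    # channel in-degree: number of channel pixels draining into each pixel
    ch_parents = np.zeros(n, dtype=np.int64)
    for p in chan:
        q = int(lattice.flow_dir[p])
        if q >= 0:
            ch_parents[q] += 1
    # reach start pixels: channel heads and confluence pixels
    starts = [
        int(p) for p in chan if ch_parents[p] == 0 or ch_parents[p] >= 2
    ]
    starts.sort(key=lambda p: lattice.drained_area[p])
    reach_of = np.full(n, -1, dtype=np.int64)
    reach_pixels: list[list[int]] = []
    for s in starts:
        rid = len(reach_pixels)
        pix = []
        p = s
        while True:
            pix.append(p)
            reach_of[p] = rid
            q = int(lattice.flow_dir[p])
            if q < 0 or ch_parents[q] >= 2:
                break
            p = q
        reach_pixels.append(pix)
    n_reach = len(reach_pixels)
    length = np.zeros(n_reach)
    area = np.zeros(n_reach)
    downstream = np.full(n_reach, -1, dtype=np.int64)
    outlet_reach = -1
    for rid, pix in enumerate(reach_pixels):
        tot = 0.0
        for p in pix:
            q = int(lattice.flow_dir[p])
            tot += (
                lattice.pixel_len
                if q < 0
                else _step_length(p, q, grid_n, lattice.pixel_len)
            )
        length[rid] = tot
        last = pix[-1]
        area[rid] = lattice.drained_area[last] * px2
        q = int(lattice.flow_dir[last])
        if q < 0:
            outlet_reach = rid
        else:
            downstream[rid] = reach_of[q]
    # attribute every pixel to the first channel reach on its flow path
    order = np.argsort(lattice.drained_area, kind="stable")[::-1]
    for p in order:  # larger areas first: receivers resolved before sources
        if reach_of[p] < 0:
            reach_of[p] = reach_of[int(lattice.flow_dir[p])]
    incr = np.bincount(reach_of, minlength=n_reach) * px2
    net = RiverNetwork(
        length=length,
        area=area,
        incr_area=incr.astype(float),
        slope=np.full(n_reach, np.nan),
        downstream=downstream,
        outlet=outlet_reach,
        pixel_len=lattice.pixel_len,
    )
    net.validate()
    return net


def assign_slopes(network: RiverNetwork, s_outlet: float) -> RiverNetwork:
    """Set reach slopes by the scaling law s_i = s_O (A_i / A_O)^-0.5."""
    if s_outlet <= 0:
        raise ValueError("outlet slope must be positive")
    a_out = float(network.area[network.outlet])
    if a_out <= 0 or np.any(network.area <= 0):
        raise ValueError("reach areas must be positive to assign slopes")
    slope = s_outlet * (network.area / a_out) ** -0.5
    return replace(network, slope=slope)


def backbone_subcatchments(network: RiverNetwork, n_points: int) -> np.ndarray:
    """Subsample the main backbone to about ``n_points`` nested subcatchment
    outlets with strictly increasing drained area (the outlet is always the
    last entry; ``n_points=1`` returns just the outlet)."""
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    bb = network.backbone()
    if n_points > bb.size:
        warnings.warn(
            f"n_points={n_points} exceeds backbone length {bb.size}; "
            "returning the full backbone"
        )
        return bb
    idx = np.unique(np.round(np.linspace(bb.size - 1, 0, n_points)).astype(int))
    sel = bb[idx]
    # enforce strictly increasing areas (duplicates possible on tiny nets)
    areas = network.area[sel]
    keep = np.concatenate(([True], np.diff(areas) > 0))
    return sel[keep]


def generate_network(
    grid_n: int,
    pixel_len: float = 100.0,
    area_threshold: float = 1e6,
    s_outlet: float = 0.001,
    seed: int = 0,
    n_iter: int | None = None,
) -> RiverNetwork:
    """Convenience pipeline: drainage -> reaches -> slopes."""
    lat = generate_drainage(grid_n, pixel_len=pixel_len, seed=seed, n_iter=n_iter)
    net = extract_reaches(lat, area_threshold)
    return assign_slopes(net, s_outlet)
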