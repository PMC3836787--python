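"""Force-directed 2D/3D network layout by molecular-dynamics relaxation.

Nodes behave as unit-mass charged particles: every pair repels by a Coulomb
force of magnitude ``k_c / d^2`` and every edge pulls its endpoints together
with a Hookean force of magnitude ``k_s * d`` (zero rest length). A viscous
drag ``-lam * v`` dissipates kinetic energy so the system settles into a
minimal-energy configuration; the equations of motion are integrated with the
classical 4th-order Runge–Kutta scheme. Two connected particles in isolation
equilibrate at separation ``d* = (k_c / k_s)^(1/3)`` — the natural length
scale of the drawing.

The exact all-pairs repulsion costs O(n^2) per evaluation; a Barnes–Hut
octree approximation (``repulsion="barnes_hut"``, opening angle ``theta``)
trades accuracy for speed on large graphs and converges to the exact forces
as ``theta`` approaches 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "LayoutParams",
    "LayoutState",
    "init_layout",
    "forces",
    "step",
    "run_layout",
    "energy",
]

_JITTER = 1e-9  # separation applied to coincident particles, layout units


@dataclass
class LayoutParams:
    """Force constants and integrator settings.

    ``k_c`` (Coulomb) and ``k_s`` (spring) set the length scale
    ``(k_c/k_s)^(1/3)``; ``lam`` is the viscosity that cools the system;
    ``dt`` the Runge–Kutta time step; ``speed_tol`` the maximum node speed
    below which the layout counts as relaxed.
    """

    k_c: float = 1.0
    k_s: float = 1.0
    lam: float = 0.5
    mass: float = 1.0
    dt: float = 0.01
    dim: int = 2
    max_iter: int = 50_000
    speed_tol: float = 1e-3
    seed: int = 0
    repulsion: str = "exact"  # or "barnes_hut"
    theta: float = 0.7

    def __post_init__(self) -> None:
        for name in ("k_c", "k_s", "mass", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.repulsion not in ("exact", "barnes_hut"):
            raise ValueError("repulsion must be 'exact' or 'barnes_hut'")


@dataclass
class LayoutState:
    """Positions and velocities for the sorted node list of a network."""

    nodes: list
    positions: np.ndarray  # (n, dim)
    velocities: np.ndarray  # (n, dim)
    iteration: int = 0
    converged: bool = False

    def position_of(self) -> dict:
        return {n: self.positions[i].copy() for i, n in enumerate(self.nodes)}

    @property
    def max_speed(self) -> float:
        return float(np.sqrt((self.velocities ** 2).sum(axis=1).max()))


def _node_order(net: nx.Graph) -> list:
    # fixed evaluation order makes runs bit-reproducible
    return sorted(net.nodes())


def _edge_index(net: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    pos = {n: i for i, n in enumerate(nodes)}
    if net.number_of_edges() == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    pairs = np.array([(pos[u], pos[v]) for u, v in sorted(map(sorted, net.edges()))])
    return pairs[:, 0], pairs[:, 1]


def init_layout(net: nx.Graph, params: LayoutParams) -> LayoutState:
    """Random uniform positions in the unit square/cube, zero velocities."""
    nodes = _node_order(net)
    if not nodes:
        raise ValueError("cannot lay out an empty network")
    rng = np.random.default_rng(params.seed)
    pos = rng.random((len(nodes), params.dim))
    vel = np.zeros_like(pos)
    return LayoutState(nodes=nodes, positions=pos, velocities=vel)


def _repulsion_exact(p: np.ndarray, k_c: float, jitter: np.ndarray) -> np.ndarray:
    diff = p[:, None, :] - p[None, :, :]
    d2 = (diff ** 2).sum(axis=-1)
    coincident = d2 < _JITTER ** 2
    np.fill_diagonal(coincident, False)
    if coincident.any():
        # per-node deterministic offsets keep the pair term antisymmetric
        i, j = np.nonzero(coincident)
        diff[i, j] = jitter[i] - jitter[j]
        d2 = (diff ** 2).sum(axis=-1)
    np.fill_diagonal(d2, 1.0)
    inv_d3 = d2 ** (-1.5)
    np.fill_diagonal(inv_d3, 0.0)
    return k_c * (diff * inv_d3[:, :, None]).sum(axis=1)


class _BHCell:
    __slots__ = ("center", "half", "count", "com", "children", "points")

    def __init__(self, center, half):
        self.center = center
        self.half = half
        self.count = 0
        self.com = np.zeros_like(center)
        self.children = None
        self.points: list[int] = []


def _bh_build(p: np.ndarray) -> _BHCell:
    lo, hi = p.min(axis=0), p.max(axis=0)
    center = (lo + hi) / 2
    half = float((hi - lo).max()) / 2 + 1e-12
    root = _BHCell(center, half)

    def insert(cell: _BHCell, idx: int, depth: int) -> None:
        cell.com = (cell.com * cell.count + p[idx]) / (cell.count + 1)
        cell.count += 1
        if cell.children is None and (cell.count == 1 or depth >= 48):
            cell.points.append(idx)
            return
        if cell.children is None:  # split an occupied leaf
            old = cell.points
            cell.points = []
            cell.children = {}
            for k in old:
                _child(cell, k, depth)
        _child(cell, idx, depth)

    def _child(cell: _BHCell, idx: int, depth: int) -> None:
        key = tuple(p[idx] > cell.center)
        child = cell.children.get(key)
        if child is None:
            offs = (np.array(key, dtype=float) * 2 - 1) * cell.half / 2
            child = _BHCell(cell.center + offs, cell.half / 2)
            cell.children[key] = child
        insert(child, idx, depth + 1)

    for i in range(p.shape[0]):
        insert(root, i, 0)
    return root


def _repulsion_barnes_hut(
    p: np.ndarray, k_c: float, theta: float, jitter: np.ndarray
) -> np.ndarray:
    root = _bh_build(p)
    out = np.zeros_like(p)
    for i in range(p.shape[0]):
        acc = np.zeros(p.shape[1])
        stack = [root]
        while stack:
            cell = stack.pop()
            if cell.count == 0:
                continue
            if cell.children is None:
                for j in cell.points:
                    if j == i:
                        continue
                    d = p[i] - p[j]
                    dd = float(d @ d)
                    if dd < _JITTER ** 2:
                        d = jitter[i] - jitter[j]
                        dd = float(d @ d)
                    acc += d * dd ** (-1.5)
                continue
            d = p[i] - cell.com
            dd = float(d @ d)
            # cells containing the target are never accepted for theta <= 1
            if dd > 0 and (2 * cell.half) ** 2 < theta ** 2 * dd:
                acc += cell.count * d * dd ** (-1.5)
            else:
                stack.extend(cell.children.values())
        out[i] = k_c * acc
    return out


def _force_field(
    p: np.ndarray,
    v: np.ndarray,
    ei: np.ndarray,
    ej: np.ndarray,
    params: LayoutParams,
    jitter: np.ndarray,
) -> np.ndarray:
    if params.repulsion == "barnes_hut":
        f = _repulsion_barnes_hut(p, params.k_c, params.theta, jitter)
    else:
        f = _repulsion_exact(p, params.k_c, jitter)
    if ei.size:
        pull = p[ej] - p[ei]  # spring force k_s * d toward the neighbour
        np.add.at(f, ei, params.k_s * pull)
        np.add.at(f, ej, -params.k_s * pull)
    f -= params.lam * v
    return f


def _jitter_offsets(n: int, dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed + 0x5EED)
    off = rng.standard_normal((n, dim))
    return _JITTER * off / np.linalg.norm(off, axis=1, keepdims=True)


def forces(net: nx.Graph, state: LayoutState, params: LayoutParams) -> np.ndarray:
    """Total force on every node, aligned with ``state.nodes``.

    Sum of all-pairs Coulomb repulsion, edge-wise spring attraction and the
    viscous drag ``-lam * v``. Coincident particles are separated by a
    deterministic, seeded jitter before evaluation.
    """
    if not np.isfinite(state.positions).all():
        raise ValueError("non-finite coordinates in layout state")
    ei, ej = _edge_index(net, state.nodes)
    jit = _jitter_offsets(len(state.nodes), params.dim, params.seed)
    return _force_field(state.positions, state.velocities, ei, ej, params, jit)


def step(net: nx.Graph, state: LayoutState, params: LayoutParams) -> LayoutState:
    """One classical 4th-order Runge–Kutta update of positions/velocities."""
    ei, ej = _edge_index(net, state.nodes)
    jit = _jitter_offsets(len(state.nodes), params.dim, params.seed)
    return _step_cached(state, ei, ej, params, jit)


def _step_cached(state, ei, ej, params, jit) -> LayoutState:
    p, v, m, dt = state.positions, state.velocities, params.mass, params.dt

    def deriv(pp, vv):
        return vv, _force_field(pp, vv, ei, ej, params, jit) / m

    k1p, k1v = deriv(p, v)
    k2p, k2v = deriv(p + dt / 2 * k1p, v + dt / 2 * k1v)
    k3p, k3v = deriv(p + dt / 2 * k2p, v + dt / 2 * k2v)
    k4p, k4v = deriv(p + dt * k3p, v + dt * k3v)
    new_p = p + dt / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
    new_v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
    if not (np.isfinite(new_p).all() and np.isfinite(new_v).all()):
        raise FloatingPointError(
            "integration diverged (non-finite coordinates); reduce dt"
        )
    return LayoutState(
        nodes=state.nodes,
        positions=new_p,
        velocities=new_v,
        iteration=state.iteration + 1,
        converged=state.converged,
    )


def run_layout(net: nx.Graph, params: LayoutParams) -> LayoutState:
    """Relax from a random start until the system is (nearly) at rest.

    Iterates Runge–Kutta steps until the maximum node speed drops below
    ``params.speed_tol`` or ``params.max_iter`` is reached; non-convergence
    is flagged, not an error.
    """
    state = init_layout(net, params)
    ei, ej = _edge_index(net, state.nodes)
    jit = _jitter_offsets(len(state.nodes), params.dim, params.seed)
    for _ in range(params.max_iter):
        state = _step_cached(state, ei, ej, params, jit)
        # ignore the cold start: speeds are zero before forces act
        if state.iteration > 1 and state.max_speed <= params.speed_tol:
            state.converged = True
            break
    return state


def energy(net: nx.Graph, state: LayoutState, params: LayoutParams) -> tuple[float, float]:
    """(kinetic, potential) energy of the particle system.

    Potential is the sum whose negative gradient yields the conservative
    forces: ``k_c / d`` per node pair plus ``k_s d^2 / 2`` per edge.
    """
    kin = 0.5 * params.mass * float((state.velocities ** 2).sum())
    p = state.positions
    diff = p[:, None, :] - p[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(p.shape[0], k=1)
    dd = np.maximum(d[iu], _JITTER)
    pot = params.k_c * float((1.0 / dd).sum())
    ei, ej = _edge_index(net, state.nodes)
    if ei.size:
        de = np.sqrt(((p[ei] - p[ej]) ** 2).sum(axis=1))
        pot += 0.5 * params.k_s * float((de ** 2).sum())
    return kin, pot
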