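"""Free-energy surfaces and their analysis: minima, saddles, minimum-energy
paths, activation and reaction free energies.

A converged well-tempered bias V(s) estimates the free energy as

    F(s) = -gamma/(gamma - 1) * V(s),

min-shifted so the global minimum sits at zero.  Stationary points are
located on the grid and refined by a local quadratic (finite-difference
Newton) fit; the minimum-energy path between two basins is the minimax
path on the 8-connected node graph — the path whose highest node is as low
as possible — optionally smoothed by steepest-descent relaxation from the
path maximum, so that max(F along path) − F(reactant) is the activation
free energy ΔG‡ and F(product) − F(reactant) the reaction free energy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_formats import HillSeries
from .engine import ModelPotential, bias_potential

__all__ = [
    "FESGrid",
    "StationaryPoint",
    "MEPPath",
    "fes_from_hills",
    "fes_from_grid",
    "find_minima",
    "find_saddles",
    "minimum_energy_path",
    "profile_barrier",
]


@dataclass
class FESGrid:
    """Free energy tabulated on a regular grid over CV space."""

    axes: list
    values: np.ndarray
    cv_names: list = None
    normalized: bool = False

    def __post_init__(self):
        self.axes = [np.asarray(ax, dtype=float) for ax in self.axes]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(len(ax) for ax in self.axes):
            raise ValueError("values shape does not match axes")
        for ax in self.axes:
            if len(ax) > 1:
                d = np.diff(ax)
                if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
                    raise ValueError("grid axes must be uniformly spaced")
        if not self.cv_names:
            self.cv_names = [f"cv{i + 1}" for i in range(len(self.axes))]

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def spacing(self) -> tuple:
        return tuple(ax[1] - ax[0] for ax in self.axes)

    def normalize(self) -> "FESGrid":
        """Shift so the minimum over finite nodes is exactly zero."""
        finite = np.isfinite(self.values)
        if finite.any():
            self.values = self.values - np.min(self.values[finite])
        self.normalized = True
        return self

    def node_point(self, idx) -> np.ndarray:
        return np.array([ax[i] for ax, i in zip(self.axes, np.atleast_1d(idx))])

    def nearest_node(self, point) -> tuple:
        point = np.atleast_1d(np.asarray(point, dtype=float))
        return tuple(int(np.argmin(np.abs(ax - x))) for ax, x in zip(self.axes, point))

    def interpolate(self, point) -> float:
        """Multilinear interpolation at a CV point."""
        point = np.atleast_1d(np.asarray(point, dtype=float))
        coords = [
            np.clip((x - ax[0]) / (ax[1] - ax[0]), 0, len(ax) - 1)
            for ax, x in zip(self.axes, point)
        ]
        return float(ndimage.map_coordinates(
            self.values, [[c] for c in coords], order=1, mode="nearest")[0])


@dataclass
class StationaryPoint:
    """A refined minimum or index-1 saddle of an FES grid."""

    kind: str
    location: np.ndarray
    free_energy: float
    curvature_signs: tuple = ()
    node: tuple = None

    def __post_init__(self):
        self.location = np.atleast_1d(np.asarray(self.location, dtype=float))


@dataclass
class MEPPath:
    """Minimum-energy path between two basins with barrier bookkeeping."""

    points: np.ndarray
    energies: np.ndarray
    barrier: float
    reaction_free_energy: float


def grid_spec_axes(grid_spec) -> list:
    """Normalize a grid spec — a list of ``(lo, hi, spacing)`` per CV — to axes."""
    axes = []
    for lo, hi, spacing in grid_spec:
        n = int(round((hi - lo) / spacing)) + 1
        axes.append(lo + spacing * np.arange(n))
    return axes


def fes_from_hills(hills: HillSeries, grid_spec, gamma: float | None = None,
                   upto_time: float | None = None,
                   time_average: int | None = None) -> FESGrid:
    """Well-tempered FES estimate F(s) = −γ/(γ−1)·V_bias(s), min-shifted to 0.

    ``grid_spec`` is a list of ``(lo, hi, spacing)`` per CV; ``gamma``
    defaults to the hill series' recorded bias factor.  ``np.inf`` for
    ``gamma`` gives the standard-metadynamics limit (prefactor 1).

    With ``time_average = n`` the estimator is averaged over ``n`` evenly
    spaced checkpoints covering the second half of the deposition record,
    which suppresses the kernel-scale ripple of the instantaneous estimate
    at negligible cost; the default is the instantaneous estimate at the
    final time.
    """
    if len(hills) == 0:
        raise ValueError("need at least one hill to estimate an FES")
    gamma = hills.bias_factor if gamma is None else gamma
    if gamma <= 1:
        raise ValueError("bias factor must be > 1")
    prefactor = 1.0 if np.isinf(gamma) else gamma / (gamma - 1.0)
    axes = grid_spec_axes(grid_spec)
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    pts = mesh.reshape(-1, hills.n_cvs)
    if time_average is None or len(hills) < 2:
        v = bias_potential(hills, pts, upto_time=upto_time)
    else:
        t_end = upto_time if upto_time is not None else hills.times[-1]
        checkpoints = np.linspace(0.5 * t_end, t_end, int(time_average))
        hill_idx = np.searchsorted(hills.times, checkpoints + 1e-12)
        running = np.zeros(pts.shape[0])
        acc = np.zeros(pts.shape[0])
        prev = 0
        for stop in hill_idx:
            running += bias_potential(
                HillSeries(hills.times[prev:stop], hills.centers[prev:stop],
                           hills.widths[prev:stop], hills.heights[prev:stop],
                           hills.bias_factor, list(hills.cv_names))
                if stop > prev else HillSeries.empty(hills.n_cvs), pts)
            acc += running
            prev = stop
        v = acc / len(checkpoints)
    values = -prefactor * np.asarray(v).reshape(mesh.shape[:-1])
    return FESGrid(axes=axes, values=values, cv_names=list(hills.cv_names)).normalize()


def fes_from_grid(potential: ModelPotential, grid_spec) -> FESGrid:
    """Tabulate an analytic potential on a grid, min-shifted to 0."""
    axes = grid_spec_axes(grid_spec)
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    values = np.asarray(potential.energy(mesh), dtype=float)
    return FESGrid(axes=axes, values=values).normalize()


def profile_barrier(grid: FESGrid, dividing_value: float = 0.0) -> float:
    """Barrier of a 1D profile: free energy at the divide above the global
    minimum over finite bins."""
    if grid.ndim != 1:
        raise ValueError("profile_barrier expects a 1D grid")
    finite = np.isfinite(grid.values)
    idx = int(np.argmin(np.abs(grid.axes[0] - dividing_value)))
    if not np.isfinite(grid.values[idx]):
        raise ValueError("dividing bin is unoccupied")
    return float(grid.values[idx] - np.min(grid.values[finite]))


# ---------------------------------------------------------------------------
# Stationary points


def _derivatives_at(grid: FESGrid, idx):
    """Finite-difference gradient and Hessian at an interior node."""
    h = grid.spacing
    F = grid.values
    idx = tuple(idx)
    nd = grid.ndim
    g = np.zeros(nd)
    H = np.zeros((nd, nd))
    for d in range(nd):
        up = list(idx); up[d] += 1
        dn = list(idx); dn[d] -= 1
        g[d] = (F[tuple(up)] - F[tuple(dn)]) / (2 * h[d])
        H[d, d] = (F[tuple(up)] - 2 * F[idx] + F[tuple(dn)]) / h[d] ** 2
    for d1 in range(nd):
        for d2 in range(d1 + 1, nd):
            pp = list(idx); pp[d1] += 1; pp[d2] += 1
            pm = list(idx); pm[d1] += 1; pm[d2] -= 1
            mp = list(idx); mp[d1] -= 1; mp[d2] += 1
            mm = list(idx); mm[d1] -= 1; mm[d2] -= 1
            H[d1, d2] = H[d2, d1] = (
                F[tuple(pp)] - F[tuple(pm)] - F[tuple(mp)] + F[tuple(mm)]
            ) / (4 * h[d1] * h[d2])
    return g, H


def _refine_quadratic(grid: FESGrid, idx):
    """Newton refinement from the local quadratic model at a node.

    Returns (location, value, hessian); the step is clamped to one cell so
    the refinement never leaves the node's neighbourhood.
    """
    g, H = _derivatives_at(grid, idx)
    x0 = grid.node_point(idx)
    try:
        step = -np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        step = np.zeros_like(g)
    h = np.asarray(grid.spacing)
    step = np.clip(step, -h, h)
    value = grid.values[tuple(idx)] + g @ step + 0.5 * step @ H @ step
    return x0 + step, float(value), H


def _is_interior(idx, shape) -> bool:
    return all(0 < i < n - 1 for i, n in zip(idx, shape))


def find_minima(grid: FESGrid) -> list:
    """Local minima: interior nodes strictly below all neighbours, refined
    by a quadratic fit and checked to have a positive-definite Hessian."""
    if any(n < 3 for n in grid.values.shape):
        raise ValueError("grid needs at least 3 nodes per axis")
    footprint = np.ones((3,) * grid.ndim, dtype=bool)
    neigh_min = ndimage.minimum_filter(grid.values, footprint=footprint, mode="nearest")
    # strict: node value equals neighbourhood min and is unique in neighbourhood
    candidates = np.argwhere(grid.values <= neigh_min)
    out = []
    for idx in candidates:
        idx = tuple(idx)
        if not _is_interior(idx, grid.values.shape):
            continue
        # strictly below all neighbours
        sl = tuple(slice(i - 1, i + 2) for i in idx)
        patch = grid.values[sl]
        if np.sum(patch == patch.min()) != 1:
            continue
        loc, val, H = _refine_quadratic(grid, idx)
        eigvals = np.linalg.eigvalsh(H)
        if np.any(eigvals <= 0):
            continue
        out.append(StationaryPoint("minimum", loc, val,
                                   tuple(np.sign(eigvals).astype(int)), idx))
    out.sort(key=lambda p: p.free_energy)
    return out


def find_saddles(grid: FESGrid, merge_radius: float | None = None,
                 min_curvature: float = 1e-3) -> list:
    """Index-1 saddle points of a 2D FES grid.

    Candidates are interior nodes whose Newton step stays within one cell
    (a stationary point of the local quadratic model lies nearby) and whose
    Hessian has exactly one negative eigenvalue; duplicates within
    ``merge_radius`` (default 2 grid spacings) are merged keeping the
    lowest.  ``min_curvature`` (kcal/mol/Å²) rejects numerically flat
    nodes whose indefinite signature is finite-difference noise.
    """
    if grid.ndim != 2:
        raise ValueError("saddle search requires a 2D grid (use the path maximum in 1D)")
    if any(n < 3 for n in grid.values.shape):
        raise ValueError("grid needs at least 3 nodes per axis")
    h = np.asarray(grid.spacing)
    if merge_radius is None:
        merge_radius = 2.0 * float(np.max(h))
    nx, ny = grid.values.shape
    found = []
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            g, H = _derivatives_at(grid, (i, j))
            det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
            if det >= 0:
                continue
            try:
                step = -np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.abs(step) > 0.75 * h):
                continue
            loc = grid.node_point((i, j)) + step
            val = grid.values[i, j] + g @ step + 0.5 * step @ H @ step
            eigvals = np.linalg.eigvalsh(H)
            if np.min(np.abs(eigvals)) < min_curvature:
                continue
            found.append(StationaryPoint("saddle", loc, float(val),
                                         tuple(np.sign(eigvals).astype(int)), (i, j)))
    # merge duplicates (several nodes around the same saddle pass the test)
    found.sort(key=lambda p: p.free_energy)
    merged: list[StationaryPoint] = []
    for cand in found:
        if all(np.linalg.norm(cand.location - m.location) > merge_radius for m in merged):
            merged.append(cand)
    merged.sort(key=lambda p: p.free_energy)
    return merged


# ---------------------------------------------------------------------------
# Minimum-energy path


def _neighbors(idx, shape):
    nd = len(shape)
    deltas = np.indices((3,) * nd).reshape(nd, -1).T - 1
    for delta in deltas:
        if not delta.any():
            continue
        nb = tuple(i + d for i, d in zip(idx, delta))
        if all(0 <= i < n for i, n in zip(nb, shape)):
            yield nb


def _minimax_path(grid: FESGrid, start: tuple, goal: tuple) -> list:
    """Path of nodes minimizing the maximum free energy (Dijkstra variant)."""
    F = grid.values
    best = np.full(F.shape, np.inf)
    prev: dict = {}
    if not (np.isfinite(F[start]) and np.isfinite(F[goal])):
        raise ValueError("path endpoints lie on non-finite grid nodes")
    heap = [(F[start], start)]
    best[start] = F[start]
    while heap:
        cost, node = heapq.heappop(heap)
        if node == goal:
            break
        if cost > best[node]:
            continue
        for nb in _neighbors(node, F.shape):
            if not np.isfinite(F[nb]):
                continue
            new_cost = max(cost, F[nb])
            if new_cost < best[nb]:
                best[nb] = new_cost
                prev[nb] = node
                heapq.heappush(heap, (new_cost, nb))
    if not np.isfinite(best[goal]):
        raise ValueError("endpoints are not connected through finite grid regions")
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return path


def _steepest_descent(grid: FESGrid, start_point, target_node, max_steps=20000):
    """Relax from a point downhill (gradient descent on the interpolated grid)."""
    h = np.asarray(grid.spacing)
    step_len = 0.5 * float(np.min(h))
    lo = np.array([ax[0] for ax in grid.axes])
    hi = np.array([ax[-1] for ax in grid.axes])
    grads = np.gradient(grid.values, *grid.axes)
    if grid.ndim == 1:
        grads = [grads]

    def local_gradient(x):
        # multilinear interpolation of the precomputed gradient fields
        t = (x - lo) / h
        idx = np.clip(t.astype(int), 0, np.array(grid.values.shape) - 2)
        f = t - idx
        g = np.empty(grid.ndim)
        for d in range(grid.ndim):
            comp = grads[d]
            if grid.ndim == 1:
                g[d] = comp[idx[0]] * (1 - f[0]) + comp[idx[0] + 1] * f[0]
            else:
                i, j = idx
                fx, fy = f
                g[d] = (comp[i, j] * (1 - fx) * (1 - fy)
                        + comp[i + 1, j] * fx * (1 - fy)
                        + comp[i, j + 1] * (1 - fx) * fy
                        + comp[i + 1, j + 1] * fx * fy)
        return g

    x = np.asarray(start_point, dtype=float)
    target = grid.node_point(target_node)
    pts = [x.copy()]
    for _ in range(max_steps):
        g = local_gradient(x)
        norm = np.linalg.norm(g)
        if norm < 1e-8:
            break
        x = np.clip(x - step_len * g / norm, lo, hi)
        pts.append(x.copy())
        if np.linalg.norm(x - target) < 1.5 * float(np.max(h)):
            break
    return pts


def minimum_energy_path(grid: FESGrid, a: StationaryPoint, b: StationaryPoint,
                        smooth: bool = True) -> MEPPath:
    """Minimum-energy path from minimum ``a`` to minimum ``b``.

    The node path minimizes the maximum free energy along the way; with
    ``smooth`` the final path is rebuilt by steepest-descent relaxation
    from the path maximum toward both endpoints.  ``barrier`` is
    max(F) − F(a) and ``reaction_free_energy`` is F(b) − F(a).
    """
    start = tuple(a.node) if a.node is not None else grid.nearest_node(a.location)
    goal = tuple(b.node) if b.node is not None else grid.nearest_node(b.location)
    if start == goal:
        pt = grid.node_point(start)[None, :]
        return MEPPath(points=pt, energies=np.array([grid.values[start]]),
                       barrier=0.0, reaction_free_energy=0.0)
    node_path = _minimax_path(grid, start, goal)
    node_energies = np.array([grid.values[n] for n in node_path])
    top = int(np.argmax(node_energies))
    top_point = grid.node_point(node_path[top])
    if smooth and 0 < top < len(node_path) - 1:
        down_a = _steepest_descent(grid, top_point, start)
        down_b = _steepest_descent(grid, top_point, goal)
        points = np.array(down_a[::-1] + down_b[1:])
    else:
        points = np.array([grid.node_point(n) for n in node_path])
    energies = np.array([grid.interpolate(p) for p in points])
    f_a = float(a.free_energy)
    f_b = float(b.free_energy)
    barrier = float(max(np.max(energies), np.max(node_energies)) - f_a)
    return MEPPath(points=points, energies=energies,
                   barrier=barrier, reaction_free_energy=f_b - f_a)
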