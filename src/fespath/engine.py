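"""Overdamped Langevin dynamics and well-tempered metadynamics in CV space.

The engine propagates a walker on an analytic model potential with the
Brownian (overdamped) update

    x <- x - (dt/friction) * grad(U + V_bias) + sqrt(2*kB*T*dt/friction) * xi

and, every ``pace`` steps, deposits a Gaussian bias kernel whose height is
tempered by the accumulated bias:

    w = w0 * exp(-V_bias(x) / (kB * dT)),   dT = (gamma - 1) * T

This is a collective-variable-space surrogate for biased molecular
dynamics: it reproduces the sampling statistics of the well-tempered
scheme (hill-height decay, bias convergence, reweighting behaviour)
without atomistic forces.  For speed, the model potential and the growing
bias are tabulated on regular grids and linearly interpolated inside a
compiled inner loop; grid spacing is a small fraction of the kernel width
so interpolation error is negligible against sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .constants import KB
from .io_formats import HillSeries, CVTrajectory

__all__ = [
    "ModelPotential",
    "MetaDParams",
    "run_langevin",
    "run_wtmetad",
    "tempered_height",
    "bias_potential",
]


@dataclass
class ModelPotential:
    """Analytic potential over 1D or 2D CV space.

    ``energy`` and ``gradient`` must accept arrays of shape ``(..., dim)``
    and return shapes ``(...)`` and ``(..., dim)`` respectively; energies in
    kcal/mol, coordinates in Å.
    """

    dimension: int
    energy: Callable
    gradient: Callable
    domain: tuple

    def __post_init__(self):
        if self.dimension not in (1, 2):
            raise ValueError("only 1D and 2D potentials are supported")
        self.domain = tuple((float(lo), float(hi)) for lo, hi in np.reshape(
            np.asarray(self.domain, dtype=float), (self.dimension, 2)))
        for lo, hi in self.domain:
            if not lo < hi:
                raise ValueError(f"invalid domain bounds ({lo}, {hi})")

    def contains(self, point) -> bool:
        point = np.atleast_1d(np.asarray(point, dtype=float))
        return all(lo <= x <= hi for x, (lo, hi) in zip(point, self.domain))

    def check_gradient(self, n_points: int = 50, seed: int = 0, rtol: float = 1e-4) -> None:
        """Verify gradient against central finite differences at random points."""
        rng = np.random.default_rng(seed)
        lo = np.array([d[0] for d in self.domain])
        hi = np.array([d[1] for d in self.domain])
        pts = lo + (hi - lo) * rng.uniform(0.05, 0.95, size=(n_points, self.dimension))
        h = 1e-5
        g_analytic = np.asarray(self.gradient(pts), dtype=float)
        for d in range(self.dimension):
            plus = pts.copy(); plus[:, d] += h
            minus = pts.copy(); minus[:, d] -= h
            g_fd = (np.asarray(self.energy(plus)) - np.asarray(self.energy(minus))) / (2 * h)
            scale = np.maximum(np.abs(g_fd), 1.0)
            if not np.allclose(g_analytic[:, d], g_fd, atol=rtol, rtol=rtol):
                worst = np.max(np.abs(g_analytic[:, d] - g_fd) / scale)
                raise ValueError(
                    f"gradient inconsistent with energy along dim {d} "
                    f"(max relative deviation {worst:.2e})"
                )


@dataclass
class MetaDParams:
    """Protocol parameters of the well-tempered scheme.

    Defaults follow the deposition protocol used for the phosphoryl-transfer
    study: 0.5 kcal/mol initial height, 0.25 Å width, one kernel every 100
    steps of 0.5 fs, bias factor 34.77 (a 20 kcal/mol tempering energy at
    298 K).  ``friction`` sets the mobility of the overdamped walker.
    """

    height: float = 0.5
    sigma: float | Sequence[float] = 0.25
    pace: int = 100
    timestep_fs: float = 0.5
    bias_factor: float = 34.77
    temperature: float = 298.0
    friction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("initial hill height must be positive")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("hill width sigma must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must be > 1")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    def sigma_array(self, dim: int) -> np.ndarray:
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if len(sig) == 1:
            sig = np.repeat(sig, dim)
        if len(sig) != dim:
            raise ValueError(f"sigma has {len(sig)} entries for a {dim}D potential")
        return sig

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs * 1e-3


def tempered_height(w0: float, bias_here: float, gamma: float, temperature: float) -> float:
    """Height of the next kernel: w0·exp(−V/(kB·ΔT)) with ΔT = (γ−1)·T."""
    if gamma <= 1:
        raise ValueError("bias factor must be > 1 for tempering")
    kb_dT = KB * (gamma - 1.0) * temperature
    return w0 * float(np.exp(-bias_here / kb_dT))


def bias_potential(hills: HillSeries, point, upto_time: float | None = None):
    """Metadynamics bias at ``point`` from all hills with time ≤ ``upto_time``.

    ``point`` may be a single CV point or an array of shape ``(..., n_cvs)``.
    """
    if len(hills) == 0:
        point = np.asarray(point, dtype=float)
        shape = point.shape[:-1] if point.ndim > 1 else ()
        return np.zeros(shape) if shape else 0.0
    mask = np.ones(len(hills), dtype=bool)
    if upto_time is not None:
        mask = hills.times <= upto_time
    centers = hills.centers[mask]
    widths = hills.widths[mask]
    heights = hills.heights[mask]
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim <= 1
    pts = np.atleast_2d(pts)
    # (n_points, n_hills, d) exponent, summed over d
    z = (pts[:, None, :] - centers[None, :, :]) / widths[None, :, :]
    v = np.sum(heights[None, :] * np.exp(-0.5 * np.sum(z * z, axis=2)), axis=1)
    return float(v[0]) if scalar and len(v) == 1 else v


# ---------------------------------------------------------------------------
# Compiled kernels


@njit(cache=False)
def _interp1(values, x0, dx, x):
    i = int((x - x0) / dx)
    n = values.shape[0]
    if i < 0:
        i = 0
    if i > n - 2:
        i = n - 2
    f = (x - (x0 + i * dx)) / dx
    return values[i] * (1.0 - f) + values[i + 1] * f


@njit(cache=False)
def _run_kernel_1d(x_start, n_steps, dt, friction, kT, lo, hi,
                   ugrad, gx0, gdx,
                   bias, bias_grad,
                   pace, w0, sigma, kb_dT,
                   stride, seed,
                   hill_centers, hill_heights, traj):
    np.random.seed(seed)
    mob = dt / friction
    noise = np.sqrt(2.0 * kT * dt / friction)
    x = x_start
    n_grid = bias.shape[0]
    window = int(8.0 * sigma / gdx) + 1
    n_hills = 0
    n_rec = 0
    for step in range(n_steps):
        g = _interp1(ugrad, gx0, gdx, x)
        if n_hills > 0:
            g += _interp1(bias_grad, gx0, gdx, x)
        x = x - mob * g + noise * np.random.randn()
        # reflecting walls
        for _ in range(4):
            if x < lo:
                x = 2.0 * lo - x
            elif x > hi:
                x = 2.0 * hi - x
            else:
                break
        if x < lo:
            x = lo
        if x > hi:
            x = hi
        if pace > 0 and (step + 1) % pace == 0 and n_hills < hill_centers.shape[0]:
            v_here = _interp1(bias, gx0, gdx, x) if n_hills > 0 else 0.0
            h = w0 * np.exp(-v_here / kb_dT)
            ic = int((x - gx0) / gdx)
            j0 = max(0, ic - window)
            j1 = min(n_grid, ic + window + 1)
            inv2s2 = 1.0 / (2.0 * sigma * sigma)
            for j in range(j0, j1):
                xg = gx0 + j * gdx
                e = h * np.exp(-(xg - x) * (xg - x) * inv2s2)
                bias[j] += e
                bias_grad[j] += -e * (xg - x) / (sigma * sigma)
            hill_centers[n_hills] = x
            hill_heights[n_hills] = h
            n_hills += 1
        if stride > 0 and (step + 1) % stride == 0:
            traj[n_rec] = x
            n_rec += 1
    return n_hills, n_rec


@njit(cache=False)
def _interp2(values, x0, dx, y0, dy, x, y):
    nx, ny = values.shape
    i = int((x - x0) / dx)
    j = int((y - y0) / dy)
    if i < 0:
        i = 0
    if i > nx - 2:
        i = nx - 2
    if j < 0:
        j = 0
    if j > ny - 2:
        j = ny - 2
    fx = (x - (x0 + i * dx)) / dx
    fy = (y - (y0 + j * dy)) / dy
    return (values[i, j] * (1 - fx) * (1 - fy)
            + values[i + 1, j] * fx * (1 - fy)
            + values[i, j + 1] * (1 - fx) * fy
            + values[i + 1, j + 1] * fx * fy)


@njit(cache=False)
def _run_kernel_2d(x_start, y_start, n_steps, dt, friction, kT,
                   lox, hix, loy, hiy,
                   ugx, ugy, gx0, gdx, gy0, gdy,
                   bias, bias_gx, bias_gy,
                   pace, w0, sx, sy, kb_dT,
                   stride, seed,
                   hill_centers, hill_heights, traj):
    np.random.seed(seed)
    mob = dt / friction
    noise = np.sqrt(2.0 * kT * dt / friction)
    x = x_start
    y = y_start
    nx, ny = bias.shape
    wx = int(8.0 * sx / gdx) + 1
    wy = int(8.0 * sy / gdy) + 1
    n_hills = 0
    n_rec = 0
    for step in range(n_steps):
        gx = _interp2(ugx, gx0, gdx, gy0, gdy, x, y)
        gy = _interp2(ugy, gx0, gdx, gy0, gdy, x, y)
        if n_hills > 0:
            gx += _interp2(bias_gx, gx0, gdx, gy0, gdy, x, y)
            gy += _interp2(bias_gy, gx0, gdx, gy0, gdy, x, y)
        x = x - mob * gx + noise * np.random.randn()
        y = y - mob * gy + noise * np.random.randn()
        for _ in range(4):
            if x < lox:
                x = 2.0 * lox - x
            elif x > hix:
                x = 2.0 * hix - x
            else:
                break
        for _ in range(4):
            if y < loy:
                y = 2.0 * loy - y
            elif y > hiy:
                y = 2.0 * hiy - y
            else:
                break
        if x < lox:
            x = lox
        if x > hix:
            x = hix
        if y < loy:
            y = loy
        if y > hiy:
            y = hiy
        if pace > 0 and (step + 1) % pace == 0 and n_hills < hill_centers.shape[0]:
            v_here = _interp2(bias, gx0, gdx, gy0, gdy, x, y) if n_hills > 0 else 0.0
            h = w0 * np.exp(-v_here / kb_dT)
            ic = int((x - gx0) / gdx)
            jc = int((y - gy0) / gdy)
            i0 = max(0, ic - wx)
            i1 = min(nx, ic + wx + 1)
            j0 = max(0, jc - wy)
            j1 = min(ny, jc + wy + 1)
            inv2sx2 = 1.0 / (2.0 * sx * sx)
            inv2sy2 = 1.0 / (2.0 * sy * sy)
            for i in range(i0, i1):
                xg = gx0 + i * gdx
                ex = np.exp(-(xg - x) * (xg - x) * inv2sx2)
                for j in range(j0, j1):
                    yg = gy0 + j * gdy
                    e = h * ex * np.exp(-(yg - y) * (yg - y) * inv2sy2)
                    bias[i, j] += e
                    bias_gx[i, j] += -e * (xg - x) / (sx * sx)
                    bias_gy[i, j] += -e * (yg - y) / (sy * sy)
            hill_centers[n_hills, 0] = x
            hill_centers[n_hills, 1] = y
            hill_heights[n_hills] = h
            n_hills += 1
        if stride > 0 and (step + 1) % stride == 0:
            traj[n_rec, 0] = x
            traj[n_rec, 1] = y
            n_rec += 1
    return n_hills, n_rec


# ---------------------------------------------------------------------------
# Drivers


def _tabulate_gradient(potential: ModelPotential, points_per_sigma: float, sigma):
    """Tabulate the potential gradient on a regular grid for interpolation."""
    axes = []
    for d, (lo, hi) in enumerate(potential.domain):
        spacing = min(sigma[d] / points_per_sigma, (hi - lo) / 200)
        n = int(np.ceil((hi - lo) / spacing)) + 1
        axes.append(np.linspace(lo, hi, n))
    if potential.dimension == 1:
        pts = axes[0][:, None]
        grad = np.asarray(potential.gradient(pts), dtype=float).reshape(len(axes[0]), 1)
        return axes, [np.ascontiguousarray(grad[:, 0])]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    grad = np.asarray(potential.gradient(mesh), dtype=float)
    return axes, [np.ascontiguousarray(grad[..., d]) for d in range(2)]


def _run(potential: ModelPotential, params: MetaDParams, n_steps: int,
         start, stride: int | None, metad: bool):
    start = np.atleast_1d(np.asarray(start, dtype=float))
    if len(start) != potential.dimension:
        raise ValueError("start point dimensionality mismatch")
    if not potential.contains(start):
        raise ValueError(f"start point {start} outside potential domain {potential.domain}")
    sigma = params.sigma_array(potential.dimension)
    stride = int(stride) if stride else params.pace
    pace = params.pace if metad else 0
    dt = params.timestep_ps
    kT = KB * params.temperature
    kb_dT = KB * (params.bias_factor - 1.0) * params.temperature
    seed = int(params.seed) % (2**31 - 1)

    axes, grads = _tabulate_gradient(potential, 5.0, sigma)
    n_hills_max = (n_steps // pace) if pace else 0
    n_rec_max = n_steps // stride
    heights = np.empty(max(n_hills_max, 1))
    if potential.dimension == 1:
        centers = np.empty(max(n_hills_max, 1))
        traj = np.empty(max(n_rec_max, 1))
        bias = np.zeros(len(axes[0]))
        bias_grad = np.zeros(len(axes[0]))
        n_hills, n_rec = _run_kernel_1d(
            float(start[0]), int(n_steps), dt, params.friction, kT,
            potential.domain[0][0], potential.domain[0][1],
            grads[0], axes[0][0], axes[0][1] - axes[0][0],
            bias, bias_grad,
            pace, params.height, float(sigma[0]), kb_dT,
            stride, seed, centers, heights, traj)
        centers = centers[:n_hills, None]
        traj_values = traj[:n_rec, None]
    else:
        centers = np.empty((max(n_hills_max, 1), 2))
        traj = np.empty((max(n_rec_max, 1), 2))
        shape = (len(axes[0]), len(axes[1]))
        bias = np.zeros(shape)
        bias_gx = np.zeros(shape)
        bias_gy = np.zeros(shape)
        n_hills, n_rec = _run_kernel_2d(
            float(start[0]), float(start[1]), int(n_steps), dt, params.friction, kT,
            potential.domain[0][0], potential.domain[0][1],
            potential.domain[1][0], potential.domain[1][1],
            grads[0], grads[1],
            axes[0][0], axes[0][1] - axes[0][0],
            axes[1][0], axes[1][1] - axes[1][0],
            bias, bias_gx, bias_gy,
            pace, params.height, float(sigma[0]), float(sigma[1]), kb_dT,
            stride, seed, centers, heights, traj)
        centers = centers[:n_hills]
        traj_values = traj[:n_rec]

    traj_times = dt * stride * np.arange(1, n_rec + 1)
    trajectory = CVTrajectory(times=traj_times, values=traj_values)
    if metad:
        hill_times = dt * pace * np.arange(1, n_hills + 1)
        if n_hills:
            hills = HillSeries(
                times=hill_times, centers=centers,
                widths=np.tile(sigma, (n_hills, 1)), heights=heights[:n_hills],
                bias_factor=params.bias_factor,
            )
        else:
            hills = HillSeries.empty(potential.dimension, params.bias_factor)
        return trajectory, hills
    return trajectory


def run_langevin(potential: ModelPotential, params: MetaDParams, n_steps: int,
                 start, stride: int | None = None) -> CVTrajectory:
    """Unbiased overdamped Langevin trajectory on ``potential``."""
    return _run(potential, params, n_steps, start, stride, metad=False)


def run_wtmetad(potential: ModelPotential, params: MetaDParams, n_steps: int,
                start, stride: int | None = None):
    """Well-tempered metadynamics run; returns ``(trajectory, hills)``.

    Hills are deposited at the instantaneous walker position every
    ``params.pace`` steps with tempered heights.  If ``pace`` exceeds
    ``n_steps`` the hill series is empty and the trajectory reduces to
    plain Langevin dynamics.
    """
    return _run(potential, params, n_steps, start, stride, metad=True)
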