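"""Convergence diagnostics and reweighting of well-tempered trajectories.

Unbiasing follows the time-dependent-offset scheme: frame t sampled under
bias V(s, t) carries weight

    w_t ∝ exp(+[V(s_t, t) − c(t)] / kB·T)

with the offset

    c(t) = (1/β)·ln( ∫ exp(β·γ/(γ−1)·V(s, t)) ds / ∫ exp(β·V(s, t)/(γ−1)) ds )

evaluated on a grid over the biased CV space.  The weights feed
histogram-based free-energy estimates on arbitrary new collective
variables, block-average error analysis, and convergence time series of
the activation and reaction free energies; barrier-crossing counting with
a hysteresis filter provides the diffusivity criterion (a run is well
sampled once several genuine crossings are seen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .io_formats import HillSeries, CVTrajectory
from .landscape import FESGrid, fes_from_hills, find_minima, minimum_energy_path, grid_spec_axes

__all__ = [
    "ReweightResult",
    "BlockAnalysisResult",
    "BarrierSeries",
    "unbias_weights",
    "reweight_to_new_cvs",
    "block_error",
    "crossing_count",
    "barrier_time_series",
]


@dataclass
class ReweightResult:
    """Free energy over new CVs from a reweighted histogram."""

    grid: FESGrid
    effective_sample_size: float
    weights: np.ndarray


@dataclass
class BlockAnalysisResult:
    """Average free-energy error versus number of blocks, per CV."""

    n_blocks: np.ndarray          # block counts examined
    errors: np.ndarray            # shape (len(n_blocks), n_cvs), kcal/mol
    cv_names: list

    def error_curve(self, cv: int = 0) -> np.ndarray:
        return np.column_stack([self.n_blocks, self.errors[:, cv]])


@dataclass
class BarrierSeries:
    """Activation and reaction free energy versus simulation time."""

    times: np.ndarray
    activation: np.ndarray        # ΔG‡(t); NaN where a basin is missing
    reaction: np.ndarray          # Δ_R_G(t)


# ---------------------------------------------------------------------------
# Unbiasing


def _bias_axes(hills: HillSeries, grid_spec):
    if grid_spec is not None:
        return grid_spec_axes(grid_spec)
    axes = []
    for d in range(hills.n_cvs):
        smax = hills.widths[:, d].max()
        lo = hills.centers[:, d].min() - 4 * smax
        hi = hills.centers[:, d].max() + 4 * smax
        spacing = hills.widths[:, d].min() / 4
        axes.append(lo + spacing * np.arange(int(np.ceil((hi - lo) / spacing)) + 1))
    return axes


def _interp_linear(axes, values, pts):
    """Multilinear interpolation of ``values`` (1D/2D grid) at points."""
    pts = np.atleast_2d(pts)
    lo = np.array([ax[0] for ax in axes])
    h = np.array([ax[1] - ax[0] for ax in axes])
    t = (pts - lo) / h
    idx = np.clip(t.astype(int), 0, np.array(values.shape) - 2)
    f = t - idx
    if len(axes) == 1:
        i = idx[:, 0]
        return values[i] * (1 - f[:, 0]) + values[i + 1] * f[:, 0]
    i, j = idx[:, 0], idx[:, 1]
    fx, fy = f[:, 0], f[:, 1]
    return (values[i, j] * (1 - fx) * (1 - fy)
            + values[i + 1, j] * fx * (1 - fy)
            + values[i, j + 1] * (1 - fx) * fy
            + values[i + 1, j + 1] * fx * fy)


def unbias_weights(traj: CVTrajectory, hills: HillSeries, temperature: float = 298.0,
                   scheme: str = "offset", grid_spec=None) -> np.ndarray:
    """Per-frame unbiasing weights, normalized to sum 1.

    ``scheme='offset'`` uses the time-dependent offset c(t); ``'final'``
    is the simpler final-bias variant w ∝ exp(+V(s, t_end)/kBT) provided
    for cross-checking.  The trajectory CVs must be the CVs the bias was
    deposited on.
    """
    n = len(traj)
    if len(hills) == 0:
        return np.full(n, 1.0 / n)
    if traj.n_cvs != hills.n_cvs:
        raise ValueError("trajectory and hills have different CV dimensionality")
    dt_hills = np.min(np.diff(hills.times)) if len(hills) > 1 else hills.times[0]
    if traj.times[-1] > hills.times[-1] + dt_hills + 1e-9 or traj.times[0] < 0:
        raise ValueError("trajectory extends outside the hill record")
    beta = 1.0 / (KB * temperature)
    gamma = hills.bias_factor
    axes = _bias_axes(hills, grid_spec)
    shape = tuple(len(ax) for ax in axes)
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, hills.n_cvs)
    bias_flat = np.zeros(mesh.shape[0])

    if scheme == "final":
        for k in range(len(hills)):
            z = (mesh - hills.centers[k]) / hills.widths[k]
            bias_flat += hills.heights[k] * np.exp(-0.5 * np.sum(z * z, axis=1))
        v_frames = _interp_linear(axes, bias_flat.reshape(shape), traj.values)
        log_w = beta * v_frames
        log_w -= logsumexp(log_w)
        return np.exp(log_w)
    if scheme != "offset":
        raise ValueError(f"unknown scheme {scheme!r}")

    # number of hills active at each frame time; a frame synchronous with a
    # deposition was sampled under the bias *before* that hill
    k_frames = np.searchsorted(hills.times, traj.times - 1e-12, side="right")
    log_w = np.empty(n)
    pos = 0
    order = np.arange(n)  # frames are time ordered by construction
    c_t = 0.0
    gfac1 = beta * gamma / (gamma - 1.0)
    gfac2 = beta / (gamma - 1.0)
    log_ngrid = np.log(bias_flat.size)
    for k in range(len(hills) + 1):
        # frames whose bias state is exactly k hills
        sel = order[pos:]
        sel = sel[k_frames[sel] == k]
        if len(sel):
            v = _interp_linear(axes, bias_flat.reshape(shape), traj.values[sel])
            log_w[sel] = beta * (v - c_t)
            pos += len(sel)
        if pos == n or k == len(hills):
            break
        z = (mesh - hills.centers[k]) / hills.widths[k]
        bias_flat += hills.heights[k] * np.exp(-0.5 * np.sum(z * z, axis=1))
        c_t = (logsumexp(gfac1 * bias_flat) - logsumexp(gfac2 * bias_flat)) / beta
    log_w -= logsumexp(log_w)
    return np.exp(log_w)


def reweight_to_new_cvs(weights: np.ndarray, new_cv_series: CVTrajectory,
                        grid_spec, temperature: float = 298.0) -> ReweightResult:
    """Weighted histogram over new CVs → F = −kBT·ln ρ, min-shifted to 0.

    Bins that collect no weight are marked non-finite (+inf).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(new_cv_series):
        raise ValueError(
            f"{len(weights)} weights for {len(new_cv_series)} frames")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    weights = weights / weights.sum()
    axes = grid_spec_axes(grid_spec)
    edges = [np.concatenate([ax - (ax[1] - ax[0]) / 2, [ax[-1] + (ax[1] - ax[0]) / 2]])
             for ax in axes]
    hist, _ = np.histogramdd(new_cv_series.values, bins=edges, weights=weights)
    with np.errstate(divide="ignore"):
        f = -KB * temperature * np.log(hist)
    grid = FESGrid(axes=axes, values=f, cv_names=list(new_cv_series.cv_names)).normalize()
    ess = 1.0 / float(np.sum(weights**2))
    return ReweightResult(grid=grid, effective_sample_size=ess, weights=weights)


# ---------------------------------------------------------------------------
# Block-average error analysis


def _block_profile(values, weights, edges):
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    return hist


def block_error(weights: np.ndarray, cv_series: CVTrajectory, n_blocks,
                temperature: float = 298.0, n_bins: int = 50,
                grid_spec=None) -> BlockAnalysisResult:
    """Block-average error of the weighted free-energy profile per CV.

    Frames are split into equal contiguous blocks; each block yields a
    weighted marginal free-energy profile, and the error for a CV is the
    mean over bins occupied in every block of the weighted standard error
    of the block free energies.  ``n_blocks`` may be an integer or a
    sequence (a log-spaced grid is typical).
    """
    weights = np.asarray(weights, dtype=float)
    n = len(cv_series)
    if len(weights) != n:
        raise ValueError("weights/frames length mismatch")
    ns = np.atleast_1d(np.asarray(n_blocks, dtype=int))
    if np.any(ns < 2):
        raise ValueError("need at least 2 blocks")
    if np.any(ns > n):
        raise ValueError(f"more blocks than frames ({ns.max()} > {n})")
    if grid_spec is not None:
        axes = grid_spec_axes(grid_spec)
        all_edges = [np.concatenate([ax - (ax[1]-ax[0])/2, [ax[-1] + (ax[1]-ax[0])/2]])
                     for ax in axes]
    else:
        all_edges = []
        for d in range(cv_series.n_cvs):
            v = cv_series.values[:, d]
            lo, hi = v.min(), v.max()
            pad = 1e-9 + 1e-9 * (hi - lo)
            all_edges.append(np.linspace(lo - pad, hi + pad, n_bins + 1))
    kT = KB * temperature
    errors = np.empty((len(ns), cv_series.n_cvs))
    for a, nb in enumerate(ns):
        bounds = np.linspace(0, n, nb + 1).astype(int)
        for d in range(cv_series.n_cvs):
            edges = all_edges[d]
            profiles = []
            block_w = []
            for b in range(nb):
                sl = slice(bounds[b], bounds[b + 1])
                hist = _block_profile(cv_series.values[sl, d], weights[sl], edges)
                w_tot = hist.sum()
                if w_tot <= 0:
                    continue
                profiles.append(hist / w_tot)
                block_w.append(w_tot)
            profiles = np.array(profiles)
            block_w = np.array(block_w)
            if len(profiles) < 2:
                errors[a, d] = np.nan
                continue
            # weighted block statistics on the probability densities (blocks
            # that miss a bin contribute zero probability, not a dropped
            # sample), then propagate to the free energy: dF = kT dp / p
            w_norm = block_w / block_w.sum()
            p_mean = np.sum(w_norm[:, None] * profiles, axis=0)
            var = np.sum(w_norm[:, None] * (profiles - p_mean) ** 2, axis=0)
            n_eff = 1.0 / np.sum(w_norm**2)
            se_p = np.sqrt(var / max(n_eff - 1.0, 1e-12))
            # bins holding less than 1e-5 of the peak probability carry only
            # shot noise; exclude them from the average
            occupied = p_mean > 1e-5 * p_mean.max()
            f_err = kT * se_p[occupied] / p_mean[occupied]
            errors[a, d] = float(np.mean(f_err)) if occupied.any() else np.nan
    return BlockAnalysisResult(n_blocks=ns, errors=errors,
                               cv_names=list(cv_series.cv_names))


# ---------------------------------------------------------------------------
# Barrier crossings and convergence series


def crossing_count(cv_series, dividing_value: float, hysteresis: float = 0.25,
                   direction_insensitive: bool = True) -> int:
    """Hysteresis-filtered count of crossings of a dividing value.

    A crossing counts only when the series penetrates at least
    ``hysteresis`` beyond the divide on the far side (suppressing grazing
    recrossings); with ``direction_insensitive`` both directions count,
    otherwise only upward (below → above) transitions.
    """
    values = cv_series.values[:, 0] if isinstance(cv_series, CVTrajectory) \
        else np.asarray(cv_series, dtype=float)
    if values.ndim != 1:
        raise ValueError("crossing counting requires a 1D series")
    side = np.zeros(len(values), dtype=int)
    side[values > dividing_value + hysteresis] = 1
    side[values < dividing_value - hysteresis] = -1
    decisive = side[side != 0]
    if len(decisive) < 2:
        return 0
    flips = np.diff(decisive)
    if direction_insensitive:
        return int(np.sum(flips != 0))
    return int(np.sum(flips > 0))


def barrier_time_series(hills: HillSeries, checkpoint_times, grid_spec,
                        r_region, p_region, gamma: float | None = None,
                        time_average: int | None = None) -> BarrierSeries:
    """ΔG‡(t) and Δ_R_G(t) from FES snapshots rebuilt at checkpoints.

    ``r_region``/``p_region`` are per-CV (lo, hi) boxes designating the
    reactant and product basins; checkpoints where a box holds no minimum
    yield NaN rather than an error.
    """
    checkpoint_times = np.atleast_1d(np.asarray(checkpoint_times, dtype=float))
    if len(hills) and np.any(checkpoint_times > hills.times[-1] + 1e-9):
        raise ValueError("checkpoints extend beyond the hill record")
    r_region = np.atleast_2d(np.asarray(r_region, dtype=float))
    p_region = np.atleast_2d(np.asarray(p_region, dtype=float))

    def in_box(point, box):
        return all(lo <= x <= hi for x, (lo, hi) in zip(point, box))

    activation = np.full(len(checkpoint_times), np.nan)
    reaction = np.full(len(checkpoint_times), np.nan)
    for i, t in enumerate(checkpoint_times):
        sub = hills.upto(t)
        if len(sub) == 0:
            continue
        grid = fes_from_hills(sub, grid_spec, gamma, time_average=time_average)
        minima = find_minima(grid)
        r_min = next((m for m in minima if in_box(m.location, r_region)), None)
        p_min = next((m for m in minima if in_box(m.location, p_region)), None)
        if r_min is None or p_min is None:
            continue
        mep = minimum_energy_path(grid, r_min, p_min, smooth=False)
        activation[i] = mep.barrier
        reaction[i] = mep.reaction_free_energy
    return BarrierSeries(times=checkpoint_times, activation=activation, reaction=reaction)
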