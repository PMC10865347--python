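"""Synthetic inputs with known answers.

Provides every input the rest of the toolkit needs without touching
external data: a 2D reference free-energy surface calibrated so that its
stationary points reproduce the printed energetics of the first
(phosphoryl-transfer) reaction step, an analytic 1D double well used as an
oracle for the sampling machinery, planted docking-pose ensembles with
known cluster labels, and a toy active-site structure exposing the atoms
that enter the CV definitions (SG of Cys215, P/OH and terminal phosphate
oxygens of pTyr306, the Asp181 carboxylate and its proton).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .engine import ModelPotential
from .io_formats import Structure
from .consensus import PoseEnsemble

__all__ = [
    "ReferenceSurfaceSpec",
    "PlantedEnsembleSpec",
    "ActiveSiteGeometry",
    "CalibrationError",
    "GaussianWell",
    "GaussianMixturePotential",
    "reference_mechanism_surface",
    "double_well_1d",
    "planted_pose_ensemble",
    "toy_active_site",
]


class CalibrationError(RuntimeError):
    """Raised when the reference-surface fit cannot reach its targets."""


# ---------------------------------------------------------------------------
# Gaussian-mixture model potential


@dataclass
class GaussianWell:
    """Anisotropic 2D Gaussian well: depth > 0 lowers the surface by
    depth·exp(−½ Δᵀ P Δ) around ``center``; ``theta`` orients the principal
    axis with standard deviation ``s1`` (``s2`` transverse)."""

    center: tuple
    depth: float
    s1: float
    s2: float
    theta: float

    def precision(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        r = np.array([[c, -s], [s, c]])
        return r @ np.diag([1.0 / self.s1**2, 1.0 / self.s2**2]) @ r.T


class GaussianMixturePotential:
    """Plateau minus a sum of anisotropic Gaussian wells; fully analytic."""

    def __init__(self, wells, plateau: float, domain):
        self.wells = list(wells)
        self.plateau = float(plateau)
        self.domain = tuple((float(lo), float(hi)) for lo, hi in domain)
        self._centers = np.array([w.center for w in self.wells])
        self._depths = np.array([w.depth for w in self.wells])
        self._precisions = np.array([w.precision() for w in self.wells])

    def _gauss(self, pts):
        # pts (..., 2) -> per-well exp factor (..., n_wells)
        delta = pts[..., None, :] - self._centers          # (..., nw, 2)
        pd = np.einsum("...wi,wij->...wj", delta, self._precisions)
        q = np.einsum("...wi,...wi->...w", delta, pd)
        return np.exp(-0.5 * q), delta, pd

    def energy(self, pts):
        pts = np.asarray(pts, dtype=float)
        e, _, _ = self._gauss(pts)
        return self.plateau - np.sum(self._depths * e, axis=-1)

    def gradient(self, pts):
        pts = np.asarray(pts, dtype=float)
        e, _, pd = self._gauss(pts)
        return np.sum(self._depths[:, None] * e[..., :, None] * pd, axis=-2)

    def hessian(self, pts):
        pts = np.asarray(pts, dtype=float)
        e, _, pd = self._gauss(pts)
        outer = pd[..., :, :, None] * pd[..., :, None, :]
        h = self._depths[:, None, None] * e[..., :, None, None] * (
            self._precisions - outer)
        return np.sum(h, axis=-3)

    def as_model_potential(self) -> ModelPotential:
        pot = ModelPotential(dimension=2, energy=self.energy,
                             gradient=self.gradient, domain=self.domain)
        pot.mixture = self
        return pot


# ---------------------------------------------------------------------------
# Reference mechanism surface


@dataclass(frozen=True)
class StationaryTarget:
    label: str           # "R", "TS" or "P"
    location: tuple      # CV point, Å (range targets collapsed to midpoints)
    free_energy: float   # kcal/mol relative to the product basin (P = 0)


@dataclass(frozen=True)
class ReferenceSurfaceSpec:
    """Targets of the reference surface calibration.

    Defaults are the stationary points of the first reaction step: the
    reactant channel at CV1 = 3.38–4.28, CV2 = 1.68 Å (midpoint 3.83) with
    ΔG_r = 5.7 kcal/mol, the saddle at (3.05, 2.40) with ΔG_t = 12.8, and
    the product basin at CV1 = 2.20, CV2 = 3.51–4.68 Å (midpoint 4.10) as
    the global minimum.  ``plateau`` is the featureless level outside the
    basins, 20 kcal/mol above the product minimum.
    """

    targets: tuple = (
        StationaryTarget("R", (3.83, 1.68), 5.7),
        StationaryTarget("TS", (3.05, 2.40), 12.8),
        StationaryTarget("P", (2.20, 4.10), 0.0),
    )
    tolerance: float = 0.1
    location_tolerance: float = 0.1
    saddle_location_tolerance: float = 0.15
    plateau: float = 20.0
    domain: tuple = ((1.4, 5.2), (0.8, 5.6))
    seed: int = 0

    def target(self, label: str) -> StationaryTarget:
        for t in self.targets:
            if t.label == label:
                return t
        raise KeyError(label)

    def __post_init__(self):
        labels = [t.label for t in self.targets]
        if labels.count("TS") != 1:
            raise ValueError("spec must contain exactly one TS target")
        ts = self.target("TS")
        for t in self.targets:
            if t.label != "TS" and t.free_energy >= ts.free_energy:
                raise ValueError("TS free energy must exceed both basin values")


def _initial_wells(spec: ReferenceSurfaceSpec):
    """Two basin wells plus two channel segments bridging them via the saddle."""
    r = np.array(spec.target("R").location)
    ts = np.array(spec.target("TS").location)
    p = np.array(spec.target("P").location)

    def seg(a, b):
        mid = 0.5 * (a + b)
        vec = b - a
        return mid, np.linalg.norm(vec), np.arctan2(vec[1], vec[0])

    mid1, len1, ang1 = seg(r, ts)
    mid2, len2, ang2 = seg(ts, p)
    return [
        # reactant basin: narrow channel elongated along CV1
        GaussianWell(tuple(r), 10.0, 0.45, 0.15, 0.0),
        # product basin: global minimum elongated along CV2
        GaussianWell(tuple(p), 16.0, 0.60, 0.20, np.pi / 2),
        # channel segments carving the path through the saddle
        GaussianWell(tuple(mid1), 6.0, 0.7 * len1, 0.22, ang1),
        GaussianWell(tuple(mid2), 8.0, 0.7 * len2, 0.22, ang2),
    ]


def _pack(wells):
    return np.concatenate([[w.center[0], w.center[1], w.depth, w.s1, w.s2, w.theta]
                           for w in wells])


def _unpack(vec, domain):
    wells = []
    for i in range(0, len(vec), 6):
        cx, cy, depth, s1, s2, theta = vec[i:i + 6]
        wells.append(GaussianWell((cx, cy), abs(depth), abs(s1) + 1e-3,
                                  abs(s2) + 1e-3, theta))
    return GaussianMixturePotential(wells, 20.0, domain)


def _locate_stationary(mix: GaussianMixturePotential, spec: ReferenceSurfaceSpec):
    """Locate the two minima and the saddle from the target starting points."""
    out = {}
    for t in spec.targets:
        x0 = np.array(t.location)
        if t.label == "TS":
            sol = optimize.root(mix.gradient, x0, jac=mix.hessian, tol=1e-12)
            loc = sol.x
            ok = sol.success
        else:
            res = optimize.minimize(mix.energy, x0, jac=mix.gradient,
                                    method="BFGS", options={"gtol": 1e-10})
            loc = res.x
            ok = res.success or np.linalg.norm(mix.gradient(loc)) < 1e-6
        eig = np.linalg.eigvalsh(mix.hessian(loc))
        out[t.label] = (loc, float(mix.energy(loc)), eig, ok)
    return out


def _calibration_residuals(vec, spec: ReferenceSurfaceSpec, p0):
    mix = _unpack(vec, spec.domain)
    st = _locate_stationary(mix, spec)
    res = []
    f_p = st["P"][1]
    for t in spec.targets:
        loc, f, eig, ok = st[t.label]
        n_here = 3 if t.label == "P" else 4
        if not ok:
            res.extend([10.0] * n_here)
            continue
        res.extend(((loc - np.array(t.location)) / 0.02).tolist())
        if t.label != "P":
            res.append(((f - f_p) - t.free_energy) / 0.02)
        # wrong Hessian signature is a hard failure
        want_neg = 1 if t.label == "TS" else 0
        res.append(0.0 if int(np.sum(eig < 0)) == want_neg else 25.0)
    # monotonicity of the energy along the piecewise R->TS->P line:
    # penalize dips on the uphill leg and bumps above the saddle level
    r = np.array(spec.target("R").location)
    ts = np.array(spec.target("TS").location)
    p = np.array(spec.target("P").location)
    for a, b in ((r, ts), (ts, p)):
        line = a + np.linspace(0, 1, 25)[:, None] * (b - a)
        e = mix.energy(line)
        over = np.max(e) - (spec.target("TS").free_energy + f_p)
        res.append(5.0 * max(over, 0.0))
    # weak regularization keeps the fit near the designed well layout
    res.extend((0.02 * (vec - p0)).tolist())
    return np.array(res)


_SURFACE_CACHE: dict = {}


def reference_mechanism_surface(spec: ReferenceSurfaceSpec | None = None) -> ModelPotential:
    """Calibrated 2D reference surface for the first reaction step.

    A sum of anisotropic Gaussian wells on a 20 kcal/mol plateau is fitted
    (deterministic seeded least squares) so that its two minima and its
    index-1 saddle reproduce the target locations and relative free
    energies within the spec tolerances.  Raises
    :class:`CalibrationError` with the residuals if the fit fails.
    """
    spec = spec or ReferenceSurfaceSpec()
    key = repr(spec)
    if key in _SURFACE_CACHE:
        return _SURFACE_CACHE[key]
    rng = np.random.default_rng(spec.seed)
    p0 = _pack(_initial_wells(spec))
    best = None
    for attempt in range(3):
        start = p0 if attempt == 0 else p0 * (1 + 0.02 * rng.standard_normal(len(p0)))
        sol = optimize.least_squares(
            _calibration_residuals, start, args=(spec, p0),
            method="lm", max_nfev=4000, xtol=1e-14, ftol=1e-14)
        mix = _unpack(sol.x, spec.domain)
        errs = _verify_targets(mix, spec)
        if best is None or errs["worst"] < best[1]["worst"]:
            best = (mix, errs)
        if errs["ok"]:
            break
    mix, errs = best
    if not errs["ok"]:
        raise CalibrationError(
            f"reference surface calibration failed; residuals: {errs}")
    pot = mix.as_model_potential()
    _SURFACE_CACHE[key] = pot
    return pot


def _verify_targets(mix: GaussianMixturePotential, spec: ReferenceSurfaceSpec) -> dict:
    st = _locate_stationary(mix, spec)
    f_p = st["P"][1]
    report = {}
    worst = 0.0
    ok = True
    for t in spec.targets:
        loc, f, eig, converged = st[t.label]
        loc_err = float(np.linalg.norm(loc - np.array(t.location)))
        e_err = abs((f - f_p) - t.free_energy)
        want_neg = 1 if t.label == "TS" else 0
        sig_ok = int(np.sum(eig < 0)) == want_neg
        loc_tol = (spec.saddle_location_tolerance if t.label == "TS"
                   else spec.location_tolerance)
        this_ok = converged and sig_ok and loc_err <= loc_tol and e_err <= spec.tolerance
        ok = ok and this_ok
        worst = max(worst, loc_err, e_err)
        report[t.label] = {"location_error": loc_err, "energy_error": e_err,
                           "signature_ok": sig_ok}
    report["worst"] = worst
    report["ok"] = ok
    return report


# ---------------------------------------------------------------------------
# Oracle double well


def double_well_1d(barrier: float = 5.0, minima_at: float = 1.0,
                   domain_half_width: float | None = None) -> ModelPotential:
    """Symmetric quartic double well U(x) = barrier·((x/a)²−1)².

    Minima at ±a with U = 0 and a barrier of exactly ``barrier`` at x = 0.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    a = float(minima_at)
    half = domain_half_width if domain_half_width is not None else 2.0 * a

    def _x(x):
        x = np.asarray(x, dtype=float)
        return x[..., 0] if (x.ndim and x.shape[-1] == 1) else x

    def energy(x):
        xi = _x(x)
        return barrier * ((xi / a) ** 2 - 1.0) ** 2

    def gradient(x):
        xi = _x(x)
        g = 4.0 * barrier * xi / a**2 * ((xi / a) ** 2 - 1.0)
        return np.expand_dims(g, -1)

    return ModelPotential(dimension=1, energy=energy, gradient=gradient,
                          domain=((-half, half),))


# ---------------------------------------------------------------------------
# Planted pose ensembles


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Layout of the planted consensus-clustering fixture.

    The total of 500 poses and the 95-member top cluster mirror the pooled
    docking study; the remaining cluster sizes are fixture choices.
    """

    cluster_sizes: tuple = (95, 80, 70, 60, 50, 40, 35, 30, 25, 15)
    sigma: float = 0.5
    min_separation: float = 10.0
    seed: int = 0
    n_receptor_atoms: int = 20
    n_ligand_atoms: int = 15

    def __post_init__(self):
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.sigma > 0 and self.min_separation <= 6 * self.sigma:
            raise ValueError("separation must exceed 6x the displacement sigma")


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _place_cluster_centers(rng, n: int, min_sep: float, box: float = 30.0) -> np.ndarray:
    for _ in range(3):
        centers = []
        for _ in range(5000):
            cand = rng.uniform(-box, box, size=3)
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
            if len(centers) == n:
                return np.array(centers)
    raise RuntimeError(
        f"could not place {n} cluster centers with separation >= {min_sep} Å "
        f"in a {2*box} Å box after 3 attempts")


def _pose_structure(receptor: np.ndarray, ligand: np.ndarray) -> Structure:
    n_rec, n_lig = len(receptor), len(ligand)
    return Structure(
        serial=np.arange(1, n_rec + n_lig + 1),
        name=np.array(["CA"] * (n_rec + n_lig)),
        res_name=np.array(["GLY"] * (n_rec + n_lig)),
        chain=np.array(["A"] * n_rec + ["B"] * n_lig),
        res_id=np.concatenate([np.arange(1, n_rec + 1), np.arange(1, n_lig + 1)]),
        coord=np.vstack([receptor, ligand]),
        element=np.array(["C"] * (n_rec + n_lig)),
    )


def planted_pose_ensemble(spec: PlantedEnsembleSpec | None = None):
    """Pose ensemble with planted clusters; returns ``(ensemble, labels)``.

    A fixed receptor point cloud is shared by all poses; each cluster is a
    rigid placement (random rotation + well-separated translation) of a
    ligand cloud, and members perturb that placement by i.i.d. Gaussian
    atomic displacements of ``spec.sigma``.
    """
    spec = spec or PlantedEnsembleSpec()
    rng = np.random.default_rng(spec.seed)
    receptor = 3.0 * rng.standard_normal((spec.n_receptor_atoms, 3))
    ligand_template = 2.5 * rng.standard_normal((spec.n_ligand_atoms, 3))
    centers = _place_cluster_centers(rng, len(spec.cluster_sizes), spec.min_separation)
    poses = []
    labels = []
    for lab, (size, center) in enumerate(zip(spec.cluster_sizes, centers)):
        rot = _random_rotation(rng)
        reference = ligand_template @ rot.T + center
        for _ in range(size):
            noise = spec.sigma * rng.standard_normal(reference.shape)
            poses.append(_pose_structure(receptor, reference + noise))
            labels.append(lab)
    n_rec = spec.n_receptor_atoms
    ensemble = PoseEnsemble(
        poses=poses,
        receptor_selection=np.arange(n_rec),
        mobile_selection=np.arange(n_rec, n_rec + spec.n_ligand_atoms),
    )
    return ensemble, np.array(labels)


# ---------------------------------------------------------------------------
# Toy active site


@dataclass(frozen=True)
class ActiveSiteGeometry:
    """Distances (Å) controlling the toy active-site layout.

    The sulfur, phosphorus and tyrosyl oxygen are collinear (in-line
    attack); the Asp proton sits between the tyrosyl oxygen and the
    carboxylate; terminal phosphate oxygens are placed perpendicular to
    the S–P axis.
    """

    d_s_p: float = 3.83        # S(Cys215) – P
    d_p_otyr: float = 1.68     # P – O(Tyr306)
    d_h_otyr: float = 1.9      # H(Asp181) – O(Tyr306)
    d_h_oasp: float = 1.0      # H(Asp181) – OD1(Asp181)
    d_p_op: float = 1.5        # P – terminal phosphate O
    d_od1_od2: float = 2.2     # carboxylate O–O


def toy_active_site(geometry: ActiveSiteGeometry | None = None) -> Structure:
    """Minimal active-site structure with hand-checkable CV geometry.

    Exposes SG (chain A, Cys215), the Asp181 carboxylate (OD1/OD2) with
    its proton HD2, and the pTyr306 phosphosite (P, OH, O1P–O3P on chain
    B) at the configured distances.
    """
    g = geometry or ActiveSiteGeometry()
    p = np.zeros(3)
    s = np.array([g.d_s_p, 0.0, 0.0])
    o_tyr = np.array([-g.d_p_otyr, 0.0, 0.0])
    h = o_tyr + np.array([0.0, g.d_h_otyr, 0.0])
    od1 = h + np.array([0.0, g.d_h_oasp, 0.0])
    od2 = od1 + np.array([g.d_od1_od2, 0.0, 0.0])
    phosphate_dirs = [np.array([0.0, np.cos(a), np.sin(a)])
                      for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                                np.pi / 2 + 4 * np.pi / 3)]
    ops = [p + g.d_p_op * d for d in phosphate_dirs]
    atoms = [
        (1, "SG", "CYS", "A", 215, tuple(s), "S"),
        (2, "OD1", "ASP", "A", 181, tuple(od1), "O"),
        (3, "OD2", "ASP", "A", 181, tuple(od2), "O"),
        (4, "HD2", "ASP", "A", 181, tuple(h), "H"),
        (5, "P", "PTR", "B", 306, tuple(p), "P"),
        (6, "OH", "PTR", "B", 306, tuple(o_tyr), "O"),
        (7, "O1P", "PTR", "B", 306, tuple(ops[0]), "O"),
        (8, "O2P", "PTR", "B", 306, tuple(ops[1]), "O"),
        (9, "O3P", "PTR", "B", 306, tuple(ops[2]), "O"),
    ]
    return Structure.from_atoms(atoms)
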