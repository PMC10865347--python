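"""End-to-end pipeline chaining the toolkit stages.

A pipeline run is declared by a configuration mapping (YAML-friendly):
stage list, per-stage parameter blocks, a global seed and an output
directory.  Stages communicate through files in the output directory and
every product is checksummed into a manifest, so identical configuration
and seed reproduce identical bytes.  Per-stage randomness is derived from
the global seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cvs as cvs_mod
from .engine import MetaDParams, run_wtmetad
from .io_formats import (read_pdb, write_pdb, read_hills, write_hills,
                         read_colvar, write_colvar, write_fes_table, read_fes_table)
from .landscape import (fes_from_hills, fes_from_grid, find_minima, find_saddles,
                        minimum_energy_path)
from .reweight import unbias_weights, reweight_to_new_cvs, block_error, crossing_count
from .synthetic import (reference_mechanism_surface, double_well_1d,
                        planted_pose_ensemble, PlantedEnsembleSpec, toy_active_site)
from .consensus import cluster_ensemble, PoseEnsemble

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "mechanism_demo_config", "consensus_demo_config"]

logger = logging.getLogger(__name__)

_STAGES = ("make_data", "simulate", "fes", "landscape", "reweight",
           "converge", "cluster", "cv")

_STAGE_REQUIRES = {
    "fes": ["hills.dat"],
    "landscape": ["fes.tsv"],
    "reweight": ["hills.dat", "colvar.dat"],
    "converge": ["hills.dat", "colvar.dat"],
}


class PipelineError(ValueError):
    """Configuration or dependency error raised before any stage runs."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    stages: list
    seed: int = 0
    output_dir: str = "pipeline_out"
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        known_top = {"stages", "seed", "output_dir", *_STAGES}
        unknown = set(cfg) - known_top
        if unknown:
            raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
        stages = list(cfg.pop("stages", []))
        for s in stages:
            if s not in _STAGES:
                raise PipelineError(f"unknown stage {s!r}; valid stages: {_STAGES}")
        return cls(
            stages=stages,
            seed=int(cfg.pop("seed", 0)),
            output_dir=str(cfg.pop("output_dir", "pipeline_out")),
            stage_params={k: v for k, v in cfg.items() if k in _STAGES},
        )

    def to_dict(self) -> dict:
        out = {"stages": self.stages, "seed": self.seed, "output_dir": self.output_dir}
        out.update(self.stage_params)
        return out


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _potential(name: str, params: dict):
    if name == "doublewell":
        return double_well_1d(params.get("barrier", 5.0), params.get("minima_at", 1.0))
    if name == "surface":
        return reference_mechanism_surface()
    raise PipelineError(f"unknown potential preset {name!r}")


def _grid_spec(block, default):
    spec = block.get("grid", default)
    return [tuple(row) for row in spec]


# ---------------------------------------------------------------------------
# Stage implementations (each returns a list of produced file names)


def _stage_make_data(cfg, out: Path, seed: int) -> list:
    preset = cfg.get("preset", "surface")
    produced = []
    if preset == "surface":
        pot = reference_mechanism_surface()
        grid = fes_from_grid(pot, _grid_spec(cfg, [(1.4, 5.2, 0.02), (0.8, 5.6, 0.02)]))
        write_fes_table(grid, out / "fes.tsv")
        produced.append("fes.tsv")
    elif preset == "doublewell":
        pot = double_well_1d(cfg.get("barrier", 5.0), cfg.get("minima_at", 1.0))
        grid = fes_from_grid(pot, _grid_spec(cfg, [(-2.0, 2.0, 0.02)]))
        write_fes_table(grid, out / "fes.tsv")
        produced.append("fes.tsv")
    elif preset == "poses":
        spec = PlantedEnsembleSpec(seed=cfg.get("seed", seed),
                                   sigma=cfg.get("sigma", 0.5))
        ensemble, labels = planted_pose_ensemble(spec)
        write_pdb(ensemble.poses, out / "poses.pdb")
        np.savetxt(out / "true_labels.tsv", labels, fmt="%d",
                   header="planted cluster label per pose", comments="#")
        produced += ["poses.pdb", "true_labels.tsv"]
    elif preset == "toysite":
        write_pdb(toy_active_site(), out / "toysite.pdb")
        produced.append("toysite.pdb")
    else:
        raise PipelineError(f"unknown make_data preset {preset!r}")
    return produced


def _stage_simulate(cfg, out: Path, seed: int) -> list:
    params = MetaDParams(seed=cfg.get("seed", seed), **cfg.get("params", {}))
    pot = _potential(cfg.get("potential", "doublewell"), cfg)
    start = cfg.get("start")
    if start is None:
        start = [-1.0] if pot.dimension == 1 else [2.20, 4.10]
    traj, hills = run_wtmetad(pot, params, int(cfg.get("n_steps", 2_000_000)), start)
    write_colvar(traj, out / "colvar.dat")
    write_hills(hills, out / "hills.dat")
    return ["colvar.dat", "hills.dat"]


def _stage_fes(cfg, out: Path, seed: int) -> list:
    hills = read_hills(out / "hills.dat")
    default = [(-1.6, 1.6, 0.02)] if hills.n_cvs == 1 else \
        [(1.4, 5.2, 0.02), (0.8, 5.6, 0.02)]
    grid = fes_from_hills(hills, _grid_spec(cfg, default),
                          time_average=cfg.get("time_average"))
    write_fes_table(grid, out / "fes.tsv")
    return ["fes.tsv"]


def _stage_landscape(cfg, out: Path, seed: int) -> list:
    grid = read_fes_table(out / "fes.tsv")
    minima = find_minima(grid)
    report = {
        "minima": [{"location": m.location.tolist(),
                    "free_energy": round(m.free_energy, 4)} for m in minima],
    }
    if grid.ndim == 2:
        saddles = find_saddles(grid)
        report["saddles"] = [{"location": s.location.tolist(),
                              "free_energy": round(s.free_energy, 4)} for s in saddles]
    if len(minima) >= 2:
        a = max(minima, key=lambda m: m.free_energy)
        b = min(minima, key=lambda m: m.free_energy)
        mep = minimum_energy_path(grid, a, b)
        report["activation_free_energy"] = round(mep.barrier, 4)
        report["reaction_free_energy"] = round(mep.reaction_free_energy, 4)
        np.savetxt(out / "mep.tsv",
                   np.column_stack([mep.points, mep.energies]),
                   header=" ".join(grid.cv_names) + " free_energy", comments="#")
        logger.info("landscape: dG_act=%.3f dRG=%.3f",
                    mep.barrier, mep.reaction_free_energy)
    (out / "landscape.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    produced = ["landscape.json"]
    if len(minima) >= 2:
        produced.append("mep.tsv")
    return produced


def _stage_reweight(cfg, out: Path, seed: int) -> list:
    hills = read_hills(out / "hills.dat")
    traj = read_colvar(out / "colvar.dat")
    temperature = cfg.get("temperature", 298.0)
    weights = unbias_weights(traj, hills, temperature,
                             scheme=cfg.get("scheme", "offset"))
    default = [(-1.6, 1.6, 0.05)] if traj.n_cvs == 1 else \
        [(1.4, 5.2, 0.05), (0.8, 5.6, 0.05)]
    result = reweight_to_new_cvs(weights, traj, _grid_spec(cfg, default), temperature)
    write_fes_table(result.grid, out / "fes_reweighted.tsv")
    np.savetxt(out / "weights.tsv", weights, header="frame weight", comments="#")
    (out / "reweight.json").write_text(json.dumps(
        {"effective_sample_size": round(result.effective_sample_size, 2),
         "n_frames": len(traj)}, indent=1, sort_keys=True))
    return ["fes_reweighted.tsv", "weights.tsv", "reweight.json"]


def _stage_converge(cfg, out: Path, seed: int) -> list:
    hills = read_hills(out / "hills.dat")
    traj = read_colvar(out / "colvar.dat")
    temperature = cfg.get("temperature", 298.0)
    weights = unbias_weights(traj, hills, temperature)
    ns = cfg.get("n_blocks", [10, 20, 50, 100, 200, 500, 1000])
    ns = [n for n in ns if n <= len(traj)]
    analysis = block_error(weights, traj, ns, temperature)
    np.savetxt(out / "block_error.tsv",
               np.column_stack([analysis.n_blocks, analysis.errors]),
               header="n_blocks " + " ".join(analysis.cv_names), comments="#")
    crossings = crossing_count(traj, cfg.get("dividing_value", 0.0),
                               hysteresis=cfg.get("hysteresis", 0.25))
    (out / "converge.json").write_text(json.dumps(
        {"crossings": crossings,
         "final_error": float(analysis.errors[-1].mean())}, indent=1, sort_keys=True))
    return ["block_error.tsv", "converge.json"]


def _stage_cluster(cfg, out: Path, seed: int) -> list:
    poses = read_pdb(out / cfg.get("input", "poses.pdb"))
    n_receptor = int(cfg.get("n_receptor_atoms", 20))
    ensemble = PoseEnsemble(poses=poses,
                            receptor_selection=np.arange(n_receptor),
                            mobile_selection=np.arange(n_receptor, len(poses[0])))
    result = cluster_ensemble(ensemble)
    np.savetxt(out / "penalty.tsv", result.penalty_curve,
               header="k penalty", comments="#")
    np.savetxt(out / "assignments.tsv", result.labels(), fmt="%d",
               header=f"cluster label per pose at k={result.chosen_k}", comments="#")
    write_pdb(poses[result.centroid_member], out / "consensus.pdb")
    (out / "cluster.json").write_text(json.dumps(
        {"k": result.chosen_k,
         "largest_cluster_size": int(result.cluster_sizes[0]),
         "consensus_member": result.centroid_member}, indent=1, sort_keys=True))
    return ["penalty.tsv", "assignments.tsv", "consensus.pdb", "cluster.json"]


def _stage_cv(cfg, out: Path, seed: int) -> list:
    structures = read_pdb(out / cfg.get("input", "toysite.pdb"))
    if not isinstance(structures, list):
        structures = [structures]
    if "definitions" in cfg:
        defs = cvs_mod.load_cv_definitions(out / cfg["definitions"])
    else:
        defs = default_bias_cvs()
    traj = cvs_mod.evaluate_cvs(structures, defs)
    write_colvar(traj, out / "cv_values.dat")
    return ["cv_values.dat"]


def default_bias_cvs():
    """The biased CVs of the phosphoryl-transfer step: d(S–P) and d(O–P)."""
    from .cvs import CVDefinition, AtomSelector
    s = AtomSelector("A", 215, "SG")
    p = AtomSelector("B", 306, "P")
    o = AtomSelector("B", 306, "OH")
    return [CVDefinition("d_S_P", "distance", atoms=(s, p)),
            CVDefinition("d_O_P", "distance", atoms=(o, p))]


_STAGE_FUNCS = {
    "make_data": _stage_make_data,
    "simulate": _stage_simulate,
    "fes": _stage_fes,
    "landscape": _stage_landscape,
    "reweight": _stage_reweight,
    "converge": _stage_converge,
    "cluster": _stage_cluster,
    "cv": _stage_cv,
}


def run_pipeline(config, output_dir: str | None = None) -> dict:
    """Run the configured stages in order; returns the output manifest.

    The manifest maps produced file names to SHA-256 checksums; identical
    configuration and seed yield identical checksums.  Missing stage
    dependencies (e.g. ``landscape`` without a prior FES) are detected
    before any stage runs.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # dependency check up front
    available = {p.name for p in out.iterdir()}
    for stage in config.stages:
        needed = _STAGE_REQUIRES.get(stage, [])
        missing = [f for f in needed if f not in available]
        if missing:
            provider = {"hills.dat": "simulate", "colvar.dat": "simulate",
                        "fes.tsv": "fes or make_data"}
            hints = sorted({provider.get(f, "?") for f in missing})
            raise PipelineError(
                f"stage {stage!r} requires {missing} — run {hints} first")
        if stage == "simulate":
            available |= {"hills.dat", "colvar.dat"}
        if stage == "fes" or (stage == "make_data"
                              and config.stage_params.get(stage, {}).get(
                                  "preset", "surface") in ("surface", "doublewell")):
            available.add("fes.tsv")
        if stage == "make_data" and config.stage_params.get(stage, {}).get(
                "preset") == "poses":
            available.add("poses.pdb")

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest = {"config.yaml": _sha256(out / "config.yaml")}
    for stage in config.stages:
        params = config.stage_params.get(stage, {})
        seed = _stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d): %s", stage, seed, params)
        produced = _STAGE_FUNCS[stage](params, out, seed)
        for name in produced:
            manifest[name] = _sha256(out / name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def mechanism_demo_config(output_dir: str = "mechanism_demo", seed: int = 0) -> dict:
    """Reference-surface demo: tabulated FES, a short biased run, landscape report."""
    return {
        "stages": ["make_data", "simulate", "landscape"],
        "seed": seed,
        "output_dir": output_dir,
        "make_data": {"preset": "surface"},
        "simulate": {"potential": "surface", "n_steps": 200_000,
                     "start": [2.20, 4.10]},
    }


def consensus_demo_config(output_dir: str = "consensus_demo", seed: int = 0) -> dict:
    """Planted-ensemble demo: pose generation plus consensus clustering."""
    return {
        "stages": ["make_data", "cluster"],
        "seed": seed,
        "output_dir": output_dir,
        "make_data": {"preset": "poses"},
    }
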