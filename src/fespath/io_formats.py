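"""File formats: PDB structures, hill files, CV time series, FES tables.

PDB reading/writing is delegated to :mod:`biotite`; the other formats are
plain whitespace-delimited tables with ``#``-prefixed comment lines, in the
dialects produced by the standard metadynamics plugin (HILLS / COLVAR).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "HillSeries",
    "CVTrajectory",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
    "write_fes_table",
    "read_fes_table",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into coordinates."""


# ---------------------------------------------------------------------------
# Structures


@dataclass
class Structure:
    """Atomic coordinates with addressing metadata.

    Atoms are stored in file order as parallel arrays; an atom is addressed
    by its ``(chain, residue number, atom name)`` triple.
    """

    serial: np.ndarray
    name: np.ndarray
    res_name: np.ndarray
    chain: np.ndarray
    res_id: np.ndarray
    coord: np.ndarray
    element: np.ndarray
    model_id: int = 1

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ValueError("coord must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atom positions must be finite")
        for attr in ("serial", "name", "res_name", "chain", "res_id", "element"):
            setattr(self, attr, np.asarray(getattr(self, attr)))

    @classmethod
    def from_atoms(cls, atoms: Sequence[tuple], model_id: int = 1) -> "Structure":
        """Build from ``(serial, name, res_name, chain, res_id, (x, y, z), element)`` tuples."""
        serial, name, res_name, chain, res_id, coord, element = zip(*atoms)
        return cls(
            serial=np.array(serial, dtype=int),
            name=np.array(name),
            res_name=np.array(res_name),
            chain=np.array(chain),
            res_id=np.array(res_id, dtype=int),
            coord=np.array(coord, dtype=float),
            element=np.array(element),
            model_id=model_id,
        )

    def __len__(self) -> int:
        return len(self.coord)

    def select(self, chain=None, res_id=None, name=None, res_name=None) -> np.ndarray:
        """Indices of atoms matching every given criterion (None = wildcard).

        Each criterion may be a scalar or a collection of allowed values.
        """
        mask = np.ones(len(self), dtype=bool)
        for values, attr in (
            (chain, self.chain),
            (res_id, self.res_id),
            (name, self.name),
            (res_name, self.res_name),
        ):
            if values is None:
                continue
            if np.isscalar(values) or isinstance(values, str):
                values = [values]
            mask &= np.isin(attr, np.asarray(list(values)))
        return np.nonzero(mask)[0]

    def atom_index(self, chain, res_id, name, res_name=None) -> int:
        """Index of the unique atom at ``(chain, res_id, name)``; raises otherwise."""
        idx = self.select(chain=chain, res_id=res_id, name=name, res_name=res_name)
        if len(idx) == 0:
            raise KeyError(f"no atom matches (chain={chain!r}, res_id={res_id}, name={name!r})")
        if len(idx) > 1:
            matches = [
                f"{self.chain[i]}/{self.res_name[i]}{self.res_id[i]}/{self.name[i]}"
                for i in idx
            ]
            raise KeyError(
                f"selection (chain={chain!r}, res_id={res_id}, name={name!r}) is "
                f"ambiguous: {matches}"
            )
        return int(idx[0])

    def position(self, chain, res_id, name) -> np.ndarray:
        return self.coord[self.atom_index(chain, res_id, name)]


def _structure_from_atom_array(arr, serial, model_id: int) -> Structure:
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(arr.atom_name),
        res_name=np.asarray(arr.res_name),
        chain=np.asarray(arr.chain_id),
        res_id=np.asarray(arr.res_id, dtype=int),
        coord=np.asarray(arr.coord, dtype=float),
        element=np.asarray(arr.element),
        model_id=model_id,
    )


def _locate_bad_coordinate_line(path) -> str:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return f"malformed coordinate field at line {lineno}: {line.rstrip()!r}"
    return "unparseable coordinate record"


def read_pdb(path):
    """Read a PDB file.

    Returns a single :class:`Structure` for a one-model file and a list of
    :class:`Structure` (one per MODEL record) for multi-model files.  Atom
    order, serial numbers and non-standard residue names are preserved.
    """
    path = Path(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    try:
        pdb_file = PDBFile.read(io.StringIO(text))
        n_models = pdb_file.get_model_count()
        structures = []
        for model in range(1, n_models + 1):
            arr = pdb_file.get_structure(model=model, extra_fields=["atom_id"])
            structures.append(_structure_from_atom_array(arr, arr.atom_id, model))
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(f"{path}: {_locate_bad_coordinate_line(path)}") from exc
    return structures[0] if n_models == 1 else structures


def _atom_array_from_structure(structure: Structure):
    arr = _struc.AtomArray(len(structure))
    arr.coord = structure.coord
    arr.chain_id = structure.chain
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name
    arr.atom_name = structure.name
    arr.element = structure.element
    arr.hetero = ~np.isin(
        structure.res_name,
        _struc.info.amino_acid_names() + _struc.info.nucleotide_names(),
    )
    arr.add_annotation("atom_id", int)
    arr.atom_id = structure.serial
    return arr


def write_pdb(structures, path) -> None:
    """Write one :class:`Structure` or a list of them (multi-model) as PDB."""
    if isinstance(structures, Structure):
        structures = [structures]
    arrays = [_atom_array_from_structure(s) for s in structures]
    pdb_file = PDBFile()
    if len(arrays) == 1:
        pdb_file.set_structure(arrays[0])
    else:
        stack = _struc.stack(arrays)
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Metadynamics tables


@dataclass
class HillSeries:
    """Time-ordered Gaussian bias kernels deposited by metadynamics.

    ``centers`` and ``widths`` have shape ``(n_hills, n_cvs)``; times are in
    ps, heights in kcal/mol.  The bias factor γ of the well-tempered scheme
    is carried along for free-energy reconstruction.
    """

    times: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    heights: np.ndarray
    bias_factor: float = 34.77
    cv_names: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        centers = np.asarray(self.centers, dtype=float)
        widths = np.asarray(self.widths, dtype=float)
        if len(self.times) == 0:
            n = centers.shape[-1] if centers.ndim >= 2 else (len(self.cv_names) or 1)
            centers = centers.reshape(0, n)
            widths = widths.reshape(0, n)
        else:
            centers = centers.reshape(len(self.times), -1)
            widths = widths.reshape(len(self.times), -1)
        self.centers = centers
        self.widths = widths
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        if len(self.times) > 0:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("hill times must be strictly increasing")
            if np.any(self.heights <= 0):
                raise ValueError("hill heights must be positive")
            if np.any(self.widths <= 0):
                raise ValueError("hill widths must be positive")
        if not self.cv_names:
            self.cv_names = [f"cv{i + 1}" for i in range(self.n_cvs)]

    @property
    def n_cvs(self) -> int:
        return self.centers.shape[1] if len(self.times) else len(self.cv_names) or 1

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls, n_cvs: int = 1, bias_factor: float = 34.77, cv_names=None) -> "HillSeries":
        return cls(
            times=np.empty(0),
            centers=np.empty((0, n_cvs)),
            widths=np.empty((0, n_cvs)),
            heights=np.empty(0),
            bias_factor=bias_factor,
            cv_names=list(cv_names) if cv_names else [f"cv{i+1}" for i in range(n_cvs)],
        )

    def upto(self, time: float) -> "HillSeries":
        """Sub-series of hills deposited at or before ``time``."""
        mask = self.times <= time
        return HillSeries(
            self.times[mask], self.centers[mask], self.widths[mask],
            self.heights[mask], self.bias_factor, list(self.cv_names),
        )


@dataclass
class CVTrajectory:
    """Sampled collective-variable values along a trajectory."""

    times: np.ndarray
    values: np.ndarray
    cv_names: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.asarray(self.values, dtype=float).reshape(len(self.times), -1)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not self.cv_names:
            self.cv_names = [f"cv{i + 1}" for i in range(self.values.shape[1])]

    @property
    def n_cvs(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.times)


def _read_table(path):
    """Whitespace table with '#' comments; returns (field names or None, data)."""
    fields = None
    rows = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                tokens = stripped.lstrip("#!").split()
                if tokens and tokens[0] == "FIELDS":
                    fields = tokens[1:]
                continue
            rows.append([float(tok) for tok in stripped.split()])
    if rows:
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}: inconsistent column counts {sorted(widths)}")
    data = np.array(rows, dtype=float) if rows else np.empty((0, 0))
    return fields, data


def write_hills(series: HillSeries, path) -> None:
    """Write a HILLS-style table: time, centers, sigmas, height, bias factor."""
    names = series.cv_names
    header = (
        "! FIELDS time "
        + " ".join(names)
        + " "
        + " ".join(f"sigma_{n}" for n in names)
        + " height biasf"
    )
    if len(series):
        biasf = np.full((len(series), 1), series.bias_factor)
        data = np.column_stack(
            [series.times, series.centers, series.widths, series.heights, biasf]
        )
    else:
        data = np.empty((0, 0))
    np.savetxt(path, data, header=header, comments="#", fmt="%.10g")


def read_hills(path, n_cvs: int | None = None) -> HillSeries:
    """Read a HILLS-style table (see :func:`write_hills` for the schema)."""
    fields, data = _read_table(path)
    if data.size == 0:
        if fields:
            n = (len(fields) - 3) // 2
            names = fields[1 : 1 + n]
            return HillSeries.empty(n_cvs=max(n, 1), cv_names=names if n else None)
        return HillSeries.empty(n_cvs=n_cvs or 1)
    ncols = data.shape[1]
    if n_cvs is None:
        n_cvs = (ncols - 3) // 2
    if ncols != 1 + 2 * n_cvs + 2 or n_cvs < 1:
        raise ValueError(
            f"{path}: expected columns 'time, {n_cvs or 'd'}x center, "
            f"{n_cvs or 'd'}x sigma, height, biasf', found {ncols} columns"
        )
    names = fields[1 : 1 + n_cvs] if fields else None
    return HillSeries(
        times=data[:, 0],
        centers=data[:, 1 : 1 + n_cvs],
        widths=data[:, 1 + n_cvs : 1 + 2 * n_cvs],
        heights=data[:, 1 + 2 * n_cvs],
        bias_factor=float(data[0, -1]),
        cv_names=names or [],
    )


def write_colvar(traj: CVTrajectory, path) -> None:
    """Write a COLVAR-style table: time followed by one column per CV."""
    header = "! FIELDS time " + " ".join(traj.cv_names)
    data = np.column_stack([traj.times, traj.values])
    np.savetxt(path, data, header=header, comments="#", fmt="%.10g")


def read_colvar(path) -> CVTrajectory:
    """Read a COLVAR-style table (see :func:`write_colvar`)."""
    fields, data = _read_table(path)
    if data.size == 0:
        raise ValueError(f"{path}: no data rows (expected 'time cv...' columns)")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected columns 'time cv1 [cv2 ...]'")
    names = fields[1:] if fields else []
    return CVTrajectory(times=data[:, 0], values=data[:, 1:], cv_names=names)


# ---------------------------------------------------------------------------
# FES grid tables


def write_fes_table(grid, path) -> None:
    """Write an FES grid as a table: CV coordinates then free energy per node.

    Row order is C order, i.e. the last CV axis varies fastest.
    """
    if grid.values is None or grid.values.size == 0:
        raise ValueError("cannot write an unpopulated FES grid")
    meshes = np.meshgrid(*grid.axes, indexing="ij")
    cols = [m.reshape(-1) for m in meshes] + [grid.values.reshape(-1)]
    names = list(grid.cv_names) + ["free_energy"]
    header = "! FIELDS " + " ".join(names)
    np.savetxt(path, np.column_stack(cols), header=header, comments="#", fmt="%.10g")


def read_fes_table(path):
    """Read a table written by :func:`write_fes_table` back into an FESGrid."""
    from .landscape import FESGrid

    fields, data = _read_table(path)
    if data.size == 0:
        raise ValueError(f"{path}: empty FES table")
    ndim = data.shape[1] - 1
    axes = [np.unique(data[:, d]) for d in range(ndim)]
    shape = tuple(len(ax) for ax in axes)
    if np.prod(shape) != data.shape[0]:
        raise ValueError(f"{path}: rows do not form a complete regular grid")
    values = data[:, -1].reshape(shape)
    names = fields[:-1] if fields else None
    return FESGrid(axes=axes, values=values, cv_names=names)
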