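"""Collective variables evaluated on structures.

Supports the CV families used to resolve a phosphoryl-transfer reaction:
plain interatomic distances (e.g. the S–P attack distance and the O–P
leaving-group distance), signed antisymmetric distance combinations, and
linear combinations of coordination numbers computed under a switching
function (used to track proton transfer between a donor carboxylate and
acceptor oxygens).

Atom selectors are ``(chain, residue number, atom name)`` triples, with an
optional residue-name guard, matching how active-site residues are named
(e.g. SG of Cys215, P of pTyr306).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .io_formats import Structure, CVTrajectory

__all__ = [
    "SwitchingFunction",
    "AtomSelector",
    "CVDefinition",
    "CoordinationTerm",
    "distance",
    "distance_difference",
    "switching_value",
    "coordination_number",
    "evaluate_cvs",
    "load_cv_definitions",
]


@dataclass(frozen=True)
class SwitchingFunction:
    """Smooth distance-to-[0, 1] map used for coordination counting.

    ``exponential_decay``: 1 for d ≤ d0, exp(−(d−d0)/r0) beyond — the decay
    form with d0 = 1.0 Å and r0 = 0.5 Å used for proton coordination
    numbers.  ``rational``: the standard (1−x^n)/(1−x^m) form with
    x = (d−d0)/r0.
    """

    kind: str = "exponential_decay"
    d0: float = 1.0
    r0: float = 0.5
    n: int = 6
    m: int = 12

    def __post_init__(self):
        if self.kind not in ("exponential_decay", "rational"):
            raise ValueError(f"unknown switching kind {self.kind!r}")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")

    def __call__(self, d):
        return switching_value(self, d)


def switching_value(sf: SwitchingFunction, d):
    """Evaluate a switching function at distance(s) ``d`` (Å)."""
    d = np.asarray(d, dtype=float)
    x = (d - sf.d0) / sf.r0
    if sf.kind == "exponential_decay":
        out = np.where(x <= 0.0, 1.0, np.exp(-np.clip(x, 0.0, None)))
    else:
        x = np.clip(x, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (1.0 - x**sf.n) / (1.0 - x**sf.m)
        # x -> 1 limit of the rational form is n/m
        out = np.where(np.isclose(x, 1.0, atol=1e-12), sf.n / sf.m, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AtomSelector:
    """Addresses atoms by chain, residue number and atom name."""

    chain: str
    res_id: int
    name: str
    res_name: str | None = None

    def resolve_one(self, structure: Structure) -> int:
        return structure.atom_index(self.chain, self.res_id, self.name, self.res_name)

    def resolve(self, structure: Structure) -> np.ndarray:
        idx = structure.select(
            chain=self.chain, res_id=self.res_id, name=self.name, res_name=self.res_name
        )
        if len(idx) == 0:
            raise KeyError(f"selector {self} matches no atom")
        return idx


def _as_selector(sel) -> AtomSelector:
    if isinstance(sel, AtomSelector):
        return sel
    if isinstance(sel, dict):
        return AtomSelector(**sel)
    return AtomSelector(*sel)


def distance(structure: Structure, a, b) -> float:
    """Euclidean distance (Å) between two uniquely addressed atoms."""
    ia = _as_selector(a).resolve_one(structure)
    ib = _as_selector(b).resolve_one(structure)
    return float(np.linalg.norm(structure.coord[ia] - structure.coord[ib]))


def distance_difference(structure: Structure, pair1, pair2) -> float:
    """Signed difference d(pair1) − d(pair2), the antisymmetric distance CV."""
    a1, b1 = pair1
    a2, b2 = pair2
    return distance(structure, a1, b1) - distance(structure, a2, b2)


def coordination_number(structure: Structure, center, partners, sf: SwitchingFunction) -> float:
    """Smooth count of ``partners`` around ``center`` under ``sf``.

    Each partner contributes ``sf(d(center, partner))``; the value lies in
    (0, n_partners].
    """
    ic = _as_selector(center).resolve_one(structure)
    partner_idx: list[int] = []
    partners = list(partners)
    if not partners:
        raise ValueError("coordination_number requires at least one partner")
    for p in partners:
        partner_idx.extend(_as_selector(p).resolve(structure).tolist())
    d = np.linalg.norm(structure.coord[partner_idx] - structure.coord[ic], axis=1)
    return float(np.sum(switching_value(sf, d)))


@dataclass(frozen=True)
class CoordinationTerm:
    coefficient: float
    center: AtomSelector
    partners: tuple
    switching: SwitchingFunction = field(default_factory=SwitchingFunction)


@dataclass(frozen=True)
class CVDefinition:
    """A named collective variable: distance, distance difference, or a
    signed linear combination of coordination numbers."""

    name: str
    kind: str
    atoms: tuple = ()         # distance: (a, b); distance_difference: (pair1, pair2)
    terms: tuple = ()         # coordination_combination: CoordinationTerm, ...
    def __post_init__(self):
        if self.kind not in ("distance", "distance_difference", "coordination_combination"):
            raise ValueError(f"unknown CV kind {self.kind!r}")

    def evaluate(self, structure: Structure) -> float:
        if self.kind == "distance":
            return distance(structure, *self.atoms)
        if self.kind == "distance_difference":
            return distance_difference(structure, *self.atoms)
        total = 0.0
        for term in self.terms:
            total += term.coefficient * coordination_number(
                structure, term.center, term.partners, term.switching
            )
        return total


def evaluate_cvs(structures, defs: Sequence[CVDefinition], times=None) -> CVTrajectory:
    """Evaluate CV definitions frame by frame into a trajectory.

    ``times`` defaults to the frame index; column order follows ``defs``.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    values = np.empty((len(structures), len(defs)))
    for i, frame in enumerate(structures):
        for j, cv in enumerate(defs):
            try:
                values[i, j] = cv.evaluate(frame)
            except KeyError as exc:
                raise KeyError(f"frame {i}, CV {cv.name!r}: {exc}") from exc
    if times is None:
        times = np.arange(len(structures), dtype=float)
    return CVTrajectory(times=times, values=values, cv_names=[d.name for d in defs])


# ---------------------------------------------------------------------------
# Configuration loading


def _selector_from_config(cfg) -> AtomSelector:
    if isinstance(cfg, dict):
        return AtomSelector(**cfg)
    return AtomSelector(*cfg)


def _switching_from_config(cfg) -> SwitchingFunction:
    return SwitchingFunction(**cfg) if cfg else SwitchingFunction()


def load_cv_definitions(path) -> list[CVDefinition]:
    """Load CV definitions from a YAML file.

    Schema: a top-level ``cvs`` list; each entry has ``name``, ``kind`` and,
    depending on the kind, ``atoms`` (two selectors), ``pairs`` (two selector
    pairs) or ``terms`` (each with ``coefficient``, ``center``, ``partners``
    and an optional ``switching`` block).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    defs = []
    for entry in cfg["cvs"]:
        kind = entry["kind"]
        if kind == "distance":
            atoms = tuple(_selector_from_config(a) for a in entry["atoms"])
        elif kind == "distance_difference":
            atoms = tuple(
                tuple(_selector_from_config(a) for a in pair) for pair in entry["pairs"]
            )
        else:
            atoms = ()
        terms = tuple(
            CoordinationTerm(
                coefficient=float(t.get("coefficient", 1.0)),
                center=_selector_from_config(t["center"]),
                partners=tuple(_selector_from_config(p) for p in t["partners"]),
                switching=_switching_from_config(t.get("switching")),
            )
            for t in entry.get("terms", [])
        )
        defs.append(CVDefinition(name=entry["name"], kind=kind, atoms=atoms, terms=terms))
    return defs
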