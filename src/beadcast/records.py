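"""Core in-memory records for structures, topologies and bead maps.

All coordinates are stored in nanometres (GROMACS convention).  File readers
convert at the boundary (PDB uses Angstrom; the conversion factor is exactly
0.1).  Serials and indices mirror the 1-based conventions of the on-disk
formats; numeric kernels work on 0-based arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: Boltzmann constant in kJ mol^-1 K^-1 (internal unit system: nm, ps, kJ/mol).
KB = 0.008314462618

#: PDB lengths are Angstrom; internal unit is nm.
PDB_TO_NM = 0.1

_ION_ELEMENTS = {"NA": "Na", "CL": "Cl", "K": "K", "MG": "Mg", "ZN": "Zn", "CA": "Ca"}


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk files."""


def guess_element(name: str, residue_name: str = "") -> str:
    """Infer an element symbol from an atom name (and residue context).

    Monatomic-ion names (NA, CL, ...) are only treated as two-letter elements
    when the residue is the ion itself; otherwise the leading letter wins
    (so NA in a nucleotide would be nitrogen, CA in a protein is carbon).
    """
    bare = name.strip().upper()
    res = residue_name.strip().upper().rstrip("+-")
    if bare in _ION_ELEMENTS and res in (bare, bare + "+", bare + "-", ""):
        if res == bare:
            return _ION_ELEMENTS[bare]
    stripped = bare.lstrip("0123456789")
    if not stripped:
        return ""
    return stripped[0]


@dataclass
class AtomRecord:
    """One atom (or CG bead) of a structure file."""

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain: str = ""
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    element: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not self.element:
            self.element = guess_element(self.name, self.residue_name)


@dataclass
class StructureRecord:
    """An ordered set of atoms plus an optional orthorhombic box (nm)."""

    atoms: list[AtomRecord]
    box: np.ndarray | None = None
    title: str = ""

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must be 3 lengths (orthorhombic)")
            if not (self.box > 0).all():
                raise ValueError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in nm (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, coords: np.ndarray) -> "StructureRecord":
        """New record with identical metadata but replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureRecord(atoms=atoms, box=None if self.box is None else self.box.copy(),
                               title=self.title)

    def validate(self) -> None:
        if not all(np.isfinite(a.position).all() for a in self.atoms):
            raise ValueError("non-finite coordinates")


@dataclass
class TopologyCounts:
    """Ordered (molecule name, count) entries of a `[ molecules ]` section."""

    entries: list[tuple[str, int]]

    def __post_init__(self):
        for name, count in self.entries:
            if count < 1:
                raise FormatError(f"molecule count for {name!r} must be >= 1, got {count}")

    def total_molecules(self) -> int:
        return sum(c for _, c in self.entries)


@dataclass
class BondedTerms:
    """Harmonic bonds and angles of one molecule template (1-based indices).

    ``b0``/``kb`` (nm, kJ mol^-1 nm^-2) and ``theta0``/``ktheta`` (deg,
    kJ mol^-1 rad^-2) may be ``None`` when the itp omits parameters; the
    force-field builder then measures equilibria from the template geometry.
    """

    bonds: list[tuple[int, int, float | None, float | None]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float | None, float | None]] = field(default_factory=list)

    def exclusion_pairs(self) -> frozenset[tuple[int, int]]:
        """All 1-2 and 1-3 pairs reachable through the bond graph (1-based)."""
        adj: dict[int, set[int]] = {}
        pairs: set[tuple[int, int]] = set()
        for i, j, *_ in self.bonds:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
            pairs.add((min(i, j), max(i, j)))
        for j, nbrs in adj.items():
            for a in nbrs:
                for b in nbrs:
                    if a < b:
                        pairs.add((a, b))
        return frozenset(pairs)

    def validate(self, n_atoms: int) -> None:
        for i, j, b0, _ in self.bonds:
            if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
                raise FormatError(f"bond ({i},{j}) exceeds atom count {n_atoms}")
            if b0 is not None and b0 <= 0:
                raise FormatError(f"bond ({i},{j}) has non-positive b0 {b0}")
        for i, j, k, t0, _ in self.angles:
            for idx in (i, j, k):
                if not (1 <= idx <= n_atoms):
                    raise FormatError(f"angle ({i},{j},{k}) exceeds atom count {n_atoms}")
            if t0 is not None and not (0 < t0 <= 180):
                raise FormatError(f"angle ({i},{j},{k}) has theta0 {t0} outside (0, 180]")


@dataclass
class ResidueMap:
    """Per-residue ordered bead->mapped-atom-serial correspondences."""

    entries: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> list[tuple[int, int]]:
        return self.entries[name]

    def residue_names(self) -> Iterable[str]:
        return self.entries.keys()

    def add(self, name: str, pairs: list[tuple[int, int]]) -> None:
        if name in self.entries:
            raise FormatError(f"residue {name!r} redefined in residue map")
        ordinals = [b for b, _ in pairs]
        if ordinals != list(range(1, len(pairs) + 1)):
            raise FormatError(f"residue {name!r}: bead ordinals must be contiguous from 1")
        serials = [a for _, a in pairs]
        if len(set(serials)) != len(serials):
            raise FormatError(f"residue {name!r}: mapped atom serials must be unique")
        self.entries[name] = list(pairs)
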