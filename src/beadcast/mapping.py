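"""Bead/atom correspondence: molecule templates, residue maps, partitioning.

Two kinds of map coexist.  Small molecules are keyed by template atom
*serial* (what a residues.map file can promise); amino acids are keyed by
atom *name*, because protein templates vary in serial layout.  A protein
instance's per-residue maps are concatenated in residue order with atom
indices offset into the whole-molecule template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .records import AtomRecord, BondedTerms, FormatError, ResidueMap, StructureRecord, TopologyCounts

__all__ = [
    "MoleculeTemplate",
    "BeadAtomMap",
    "AminoAcidMap",
    "MoleculeInstance",
    "PartitionResult",
    "MappingError",
    "partition_cg_system",
    "build_molecule_map",
    "load_template",
    "DEFAULT_WATER_NAMES",
    "DEFAULT_ION_NAMES",
]

#: CG solvent bead names routed to the resolvation stage rather than to
#: templates.  WF (anti-freeze) back-maps identically to W: it is a CG
#: artifact with no atomistic counterpart distinction.
DEFAULT_WATER_NAMES = frozenset({"W", "WF"})
DEFAULT_ION_NAMES = frozenset({"NA+", "NA", "CL-", "CL", "ION"})


class MappingError(ValueError):
    """Inconsistency between structure, topology, maps and templates."""


@dataclass
class MoleculeTemplate:
    """Energy-minimized atomistic reference for one molecule type.

    ``chiral_centers`` holds (center, a, b, c) atom-serial quadruples; the
    reference handedness is the sign of the signed volume
    (b-center) . ((a-center) x (c-center)) evaluated on this geometry.
    """

    name: str
    atoms: list[AtomRecord]
    bonded: BondedTerms
    chiral_centers: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise MappingError(f"template {self.name!r} has no atoms")
        self.bonded.validate(len(self.atoms))
        if len(self.atoms) > 1:
            if pdist(self.positions()).min() < 0.05:
                raise MappingError(
                    f"template {self.name!r}: atoms closer than 0.05 nm in reference geometry"
                )
        for quad in self.chiral_centers:
            for serial in quad:
                self.index_of_serial(serial)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def index_of_serial(self, serial: int) -> int:
        for i, a in enumerate(self.atoms):
            if a.serial == serial:
                return i
        raise MappingError(f"template {self.name!r}: no atom with serial {serial}")

    def residue_spans(self) -> list[tuple[str, int, int]]:
        """Consecutive (resname, start, stop) atom spans, template order."""
        spans: list[tuple[str, int, int]] = []
        prev = None
        start = 0
        for i, a in enumerate(self.atoms):
            key = (a.residue_seq, a.residue_name, a.chain)
            if key != prev:
                if prev is not None:
                    spans.append((prev[1], start, i))
                prev, start = key, i
        spans.append((prev[1], start, len(self.atoms)))
        return spans

    def chiral_signs(self) -> list[float]:
        """Reference signed-volume sign of each declared center."""
        pos = self.positions()
        signs = []
        for center, a, b, c in self.chiral_centers:
            signs.append(float(np.sign(signed_volume(pos, self.index_of_serial(center),
                                                     self.index_of_serial(a),
                                                     self.index_of_serial(b),
                                                     self.index_of_serial(c)))))
        return signs


def signed_volume(pos: np.ndarray, center: int, a: int, b: int, c: int) -> float:
    """Triple product (b-center) . ((a-center) x (c-center)), nm^3."""
    va = pos[a] - pos[center]
    vb = pos[b] - pos[center]
    vc = pos[c] - pos[center]
    return float(np.dot(vb, np.cross(va, vc)))


@dataclass
class BeadAtomMap:
    """Ordered (bead_index, atom_index) pairs, 0-based within one molecule."""

    pairs: list[tuple[int, int]]

    def __post_init__(self):
        atoms = [a for _, a in self.pairs]
        if len(set(atoms)) != len(atoms):
            raise MappingError("bead->atom map is not injective on atoms")

    @property
    def n_beads(self) -> int:
        return len(self.pairs)

    def bead_indices(self) -> np.ndarray:
        return np.array([b for b, _ in self.pairs], dtype=int)

    def atom_indices(self) -> np.ndarray:
        return np.array([a for _, a in self.pairs], dtype=int)


# Default per-amino-acid bead -> atom-name map (Martini-style bead layout:
# one backbone bead on CA, side-chain beads on representative heavy atoms).
_DEFAULT_AMINO: dict[str, list[str]] = {
    "GLY": ["CA"],
    "ALA": ["CA"],
    "CYS": ["CA", "SG"],
    "VAL": ["CA", "CB"],
    "LEU": ["CA", "CG"],
    "ILE": ["CA", "CG1"],
    "PRO": ["CA", "CG"],
    "MET": ["CA", "SD"],
    "SER": ["CA", "OG"],
    "THR": ["CA", "OG1"],
    "ASN": ["CA", "CG"],
    "GLN": ["CA", "CD"],
    "ASP": ["CA", "CG"],
    "GLU": ["CA", "CD"],
    "LYS": ["CA", "CG", "NZ"],
    "ARG": ["CA", "CG", "CZ"],
    "HIS": ["CA", "CG", "ND1", "NE2"],
    "PHE": ["CA", "CG", "CE1", "CE2"],
    "TYR": ["CA", "CG", "CE1", "CE2"],
    "TRP": ["CA", "CG", "NE1", "CZ2"],
}


class AminoAcidMap:
    """Per-residue bead -> atom-name map for proteins, user-extensible."""

    def __init__(self, entries: dict[str, list[tuple[int, str]]] | None = None):
        self.entries: dict[str, list[tuple[int, str]]] = dict(entries or {})

    @classmethod
    def default(cls) -> "AminoAcidMap":
        return cls({res: [(i + 1, nm) for i, nm in enumerate(names)]
                    for res, names in _DEFAULT_AMINO.items()})

    def __contains__(self, resname: str) -> bool:
        return resname in self.entries

    def __getitem__(self, resname: str) -> list[tuple[int, str]]:
        return self.entries[resname]

    def add_residue(self, resname: str, pairs: list[tuple[int, str]], override: bool = False) -> None:
        """Register a residue.  Redefining a known residue requires ``override``."""
        if resname in self.entries and not override:
            raise MappingError(
                f"residue {resname!r} already mapped; pass override=True to replace it"
            )
        ordinals = [b for b, _ in pairs]
        if ordinals != list(range(1, len(pairs) + 1)):
            raise MappingError(f"residue {resname!r}: bead ordinals must be contiguous from 1")
        self.entries[resname] = list(pairs)

    @classmethod
    def from_file(cls, path, extend_default: bool = True) -> "AminoAcidMap":
        """Load the amino-map dialect (``[ RES ]`` then ``bead  ATOMNAME`` lines)."""
        amap = cls.default() if extend_default else cls()
        current = None
        pending: list[tuple[int, str]] = []

        def flush():
            if current is not None:
                amap.add_residue(current, pending, override=True)

        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split(";", 1)[0].strip()
                if not line:
                    continue
                if line.startswith("["):
                    flush()
                    current = line.strip("[] \t")
                    pending = []
                    continue
                parts = line.split()
                if current is None or len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'bead ATOMNAME' inside a residue block")
                pending.append((int(parts[0]), parts[1]))
        flush()
        return amap


@dataclass
class MoleculeInstance:
    """One molecule of the CG system: a contiguous bead span plus provenance."""

    molecule_name: str
    bead_slice: tuple[int, int]  # [start, stop) into the CG atom list
    is_protein: bool = False
    residue_breakdown: list[tuple[str, int, int]] | None = None  # (resname, start, stop) bead spans

    @property
    def n_beads(self) -> int:
        return self.bead_slice[1] - self.bead_slice[0]


@dataclass
class PartitionResult:
    instances: list[MoleculeInstance]
    water_bead_indices: list[int]
    ion_beads: list[tuple[str, int]]  # (species name, bead index)


def partition_cg_system(
    cg: StructureRecord,
    top: TopologyCounts,
    maps: ResidueMap,
    amino: AminoAcidMap | None = None,
    water_names: frozenset[str] = DEFAULT_WATER_NAMES,
    ion_names: frozenset[str] = DEFAULT_ION_NAMES,
) -> PartitionResult:
    """Partition the CG bead list into molecule instances and solvent beads.

    Entries are consumed in topology order.  A topology name resolves, in
    order, as: water bead, ion bead, small molecule (present in the residue
    map, bead count = map length), or protein (a run of residues resolvable
    in the amino-acid map, delimited by chain boundaries).
    """
    amino = amino or AminoAcidMap.default()
    atoms = cg.atoms
    n = len(atoms)
    idx = 0
    instances: list[MoleculeInstance] = []
    waters: list[int] = []
    ions: list[tuple[str, int]] = []

    for name, count in top.entries:
        if name in water_names:
            if idx + count > n:
                raise MappingError(
                    f"molecule block {name!r}: topology claims {count} beads but only "
                    f"{n - idx} remain in the structure"
                )
            waters.extend(range(idx, idx + count))
            idx += count
        elif name in ion_names:
            if idx + count > n:
                raise MappingError(
                    f"molecule block {name!r}: topology claims {count} beads but only "
                    f"{n - idx} remain in the structure"
                )
            ions.extend((name, i) for i in range(idx, idx + count))
            idx += count
        elif name in maps:
            bpm = len(maps[name])
            for m in range(count):
                if idx + bpm > n:
                    raise MappingError(
                        f"molecule block {name!r}: instance {m + 1}/{count} needs {bpm} beads "
                        f"but only {n - idx} remain"
                    )
                first = atoms[idx]
                if first.residue_name != name:
                    raise MappingError(
                        f"molecule block {name!r}: bead {idx + 1} has residue "
                        f"{first.residue_name!r}; structure and topology disagree"
                    )
                instances.append(MoleculeInstance(name, (idx, idx + bpm)))
                idx += bpm
        else:
            # protein path: consume `count` chain-delimited residue runs
            for m in range(count):
                start = idx
                if idx >= n:
                    raise MappingError(f"molecule block {name!r}: no beads left for instance {m + 1}")
                chain0 = atoms[idx].chain
                breakdown: list[tuple[str, int, int]] = []
                while idx < n and atoms[idx].chain == chain0 and atoms[idx].residue_name in amino:
                    resname = atoms[idx].residue_name
                    resseq = atoms[idx].residue_seq
                    rstart = idx
                    while idx < n and atoms[idx].residue_seq == resseq \
                            and atoms[idx].residue_name == resname and atoms[idx].chain == chain0:
                        idx += 1
                    expected = len(amino[resname])
                    if idx - rstart != expected:
                        raise MappingError(
                            f"protein {name!r}: residue {resname} {resseq} has {idx - rstart} "
                            f"beads, amino map expects {expected}"
                        )
                    breakdown.append((resname, rstart - start, idx - start))
                if not breakdown:
                    raise MappingError(
                        f"molecule {name!r} is not in the residue map and residue "
                        f"{atoms[idx].residue_name!r} is not in the amino-acid map"
                    )
                instances.append(
                    MoleculeInstance(name, (start, idx), is_protein=True, residue_breakdown=breakdown)
                )

    if idx != n:
        raise MappingError(
            f"topology accounts for {idx} beads but the structure has {n}; "
            f"first unclaimed bead: {atoms[idx].residue_name!r} serial {atoms[idx].serial}"
        )
    return PartitionResult(instances=instances, water_bead_indices=waters, ion_beads=ions)


def build_molecule_map(
    instance: MoleculeInstance,
    maps: ResidueMap,
    amino: AminoAcidMap | None,
    template: MoleculeTemplate,
) -> BeadAtomMap:
    """Bead->atom map (0-based) for one molecule instance against its template."""
    if not instance.is_protein:
        if instance.molecule_name not in maps:
            raise MappingError(f"no residue-map entry for {instance.molecule_name!r}")
        entry = maps[instance.molecule_name]
        if len(entry) != instance.n_beads:
            raise MappingError(
                f"{instance.molecule_name!r}: map has {len(entry)} beads, instance has "
                f"{instance.n_beads}"
            )
        pairs = [(bead - 1, template.index_of_serial(serial)) for bead, serial in entry]
        return BeadAtomMap(pairs=pairs)

    amino = amino or AminoAcidMap.default()
    spans = template.residue_spans()
    if len(spans) != len(instance.residue_breakdown or []):
        raise MappingError(
            f"protein {instance.molecule_name!r}: template has {len(spans)} residues, "
            f"CG instance has {len(instance.residue_breakdown or [])}"
        )
    pairs: list[tuple[int, int]] = []
    for (resname, bstart, _bstop), (tname, astart, astop) in zip(instance.residue_breakdown, spans):
        if resname != tname:
            raise MappingError(
                f"protein {instance.molecule_name!r}: CG residue {resname} does not match "
                f"template residue {tname}"
            )
        name_to_local = {template.atoms[i].name: i for i in range(astart, astop)}
        for bead_ord, atom_name in amino[resname]:
            if atom_name not in name_to_local:
                raise MappingError(
                    f"protein {instance.molecule_name!r}: residue {resname} has no atom "
                    f"named {atom_name!r} in the template"
                )
            pairs.append((bstart + bead_ord - 1, name_to_local[atom_name]))
    return BeadAtomMap(pairs=pairs)


def load_template(template_dir, name: str) -> MoleculeTemplate:
    """Load ``<name>.pdb`` + ``<name>.itp`` (+ optional ``<name>.chiral``).

    The chiral sidecar lists one ``center a b c`` serial quadruple per line;
    ``;`` starts a comment.
    """
    from .io_formats import parse_bonded_itp, read_structure

    tdir = Path(template_dir)
    pdb = tdir / f"{name}.pdb"
    itp = tdir / f"{name}.itp"
    missing = [str(p) for p in (pdb, itp) if not p.exists()]
    if missing:
        raise MappingError(
            f"template files for molecule {name!r} not found: {', '.join(missing)} "
            f"(each molecule type needs an energy-minimized PDB and a bonded-term itp)"
        )
    struct = read_structure(pdb, "pdb")
    bonded = parse_bonded_itp(itp)
    centers: list[tuple[int, int, int, int]] = []
    sidecar = tdir / f"{name}.chiral"
    if sidecar.exists():
        with open(sidecar) as fh:
            for raw in fh:
                line = raw.split(";", 1)[0].strip()
                if not line:
                    continue
                vals = tuple(int(v) for v in line.split())
                if len(vals) != 4:
                    raise FormatError(f"{sidecar}: expected 4 serials per line, got {line!r}")
                centers.append(vals)
    return MoleculeTemplate(name=name, atoms=struct.atoms, bonded=bonded, chiral_centers=centers)
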