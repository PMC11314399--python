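"""System assembly, system-level restrained relaxation, and structure audits.

Molecules are merged in topology order, then all waters (bead waters plus
ion hydration shells), then ions.  The box is copied unchanged from the CG
input and every molecule is wrapped into the primary cell by its centroid,
so molecules stay whole.  The audits check what back-mapping can silently
break: stereocenter handedness (signed tetrahedral volume against the
template's) and interatomic clashes (cell-list neighbor search under PBC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mapping import MoleculeInstance, MoleculeTemplate, signed_volume
from .records import AtomRecord, StructureRecord
from .relax import MiniForceField, RelaxParams, RestraintSet, minimize, stochastic_relax
from .solvate import O_H, HOH_ANGLE, SolventAtoms

__all__ = [
    "AASystem",
    "MoleculeEntry",
    "ChiralityReport",
    "assemble",
    "system_relax",
    "check_chirality",
    "check_clashes",
    "water_bonded_terms",
]


@dataclass
class MoleculeEntry:
    """One back-mapped molecule ready for assembly."""

    name: str
    instance: MoleculeInstance
    template: MoleculeTemplate
    coords: np.ndarray
    mapped_atom_indices: np.ndarray  # local, 0-based
    bead_references: np.ndarray  # nm, one per mapped atom


@dataclass
class Provenance:
    name: str
    kind: str  # molecule | water | ion
    span: tuple[int, int]
    source_index: int
    template: MoleculeTemplate | None = None


@dataclass
class AASystem:
    """Assembled atomistic system with per-molecule provenance."""

    structure: StructureRecord
    provenance: list[Provenance]
    molecule_of: np.ndarray  # per-atom molecule id
    restraints: RestraintSet | None = None
    audit: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def entries_of_kind(self, kind: str) -> list[Provenance]:
        return [p for p in self.provenance if p.kind == kind]


def _wrap_molecule(coords: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return coords
    centroid = coords.mean(axis=0)
    shift = np.floor(centroid / box) * box
    return coords - shift


def assemble(
    molecules: list[MoleculeEntry],
    waters: SolventAtoms,
    ions: SolventAtoms,
    box: np.ndarray | None,
    title: str = "back-mapped atomistic system",
) -> AASystem:
    """Merge molecules + solvent into one structure (topology order, solvent last)."""
    atoms: list[AtomRecord] = []
    provenance: list[Provenance] = []
    mol_ids: list[int] = []
    resid = 0
    mol_id = 0

    for mi, entry in enumerate(molecules):
        coords = _wrap_molecule(np.asarray(entry.coords, dtype=float), box)
        start = len(atoms)
        spans = entry.template.residue_spans()
        for resname, astart, astop in spans:
            resid += 1
            for li in range(astart, astop):
                ta = entry.template.atoms[li]
                atoms.append(
                    AtomRecord(
                        serial=len(atoms) + 1,
                        name=ta.name,
                        residue_name=resname,
                        residue_seq=resid,
                        chain=ta.chain,
                        position=coords[li],
                        element=ta.element,
                    )
                )
                mol_ids.append(mol_id)
        provenance.append(Provenance(entry.name, "molecule", (start, len(atoms)), mi, entry.template))
        mol_id += 1

    for group, kind in ((waters, "water"), (ions, "ion")):
        offset = 0
        for si, size in enumerate(group.mol_sizes):
            resid += 1
            start = len(atoms)
            block = _wrap_molecule(group.positions[offset:offset + size], box)
            for a in range(size):
                atoms.append(
                    AtomRecord(
                        serial=len(atoms) + 1,
                        name=group.names[offset + a],
                        residue_name=group.resnames[offset + a],
                        residue_seq=resid,
                        position=block[a],
                    )
                )
                mol_ids.append(mol_id)
            provenance.append(Provenance(group.resnames[offset], kind, (start, len(atoms)), si))
            mol_id += 1
            offset += size

    structure = StructureRecord(atoms=atoms, box=None if box is None else np.asarray(box, float).copy(),
                                title=title)
    return AASystem(structure=structure, provenance=provenance,
                    molecule_of=np.array(mol_ids, dtype=int))


def water_bonded_terms(n_waters: int) -> MiniForceField:
    """Stiff internal geometry for placed 3-site waters (per-water O-H bonds
    and the H-O-H angle), as a mergeable force-field fragment."""
    bi, ai = [], []
    for w in range(n_waters):
        o, h1, h2 = 3 * w, 3 * w + 1, 3 * w + 2
        bi.append((o, h1))
        bi.append((o, h2))
        ai.append((h1, o, h2))
    n = 3 * n_waters
    keys = []
    for w in range(n_waters):
        o, h1, h2 = 3 * w, 3 * w + 1, 3 * w + 2
        keys.extend([o * n + h1, o * n + h2, h1 * n + h2])
    return MiniForceField(
        n_atoms=n,
        bond_idx=np.array(bi, dtype=int).reshape(-1, 2),
        bond_b0=np.full(2 * n_waters, O_H),
        bond_kb=np.full(2 * n_waters, 20000.0),
        angle_idx=np.array(ai, dtype=int).reshape(-1, 3),
        angle_t0=np.full(n_waters, HOH_ANGLE),
        # scaffolding constant: holds the H-O-H angle through the short
        # relax without dominating the integrator's stability budget
        angle_kt=np.full(n_waters, 150.0),
        excluded_keys=np.array(keys, dtype=np.int64),
    )


def build_system_forcefield(sys: AASystem) -> MiniForceField:
    """Merge per-molecule bonded terms + water geometry over the whole system."""
    n_total = sys.n_atoms
    parts: list[tuple[MiniForceField, int]] = []
    water_spans = [p.span for p in sys.provenance if p.kind == "water"]
    for p in sys.provenance:
        if p.kind == "molecule" and p.template is not None:
            parts.append((MiniForceField.from_template(p.template), p.span[0]))
    if water_spans:
        # waters are contiguous blocks of 3 atoms; one fragment per contiguous run
        start = water_spans[0][0]
        count = len(water_spans)
        parts.append((water_bonded_terms(count), start))
    return MiniForceField.merge(parts, n_total)


@dataclass
class SystemRelaxParams(RelaxParams):
    """Step-5 defaults: shorter, stiffer-integrator settings for the full system."""

    em_max_steps: int = 300
    sd_dt: float = 0.0005
    sd_gamma: float = 50.0
    sd_steps: int = 100
    solvent_restraint_k: float = 1000.0


def build_system_restraints(
    sys: AASystem,
    params: SystemRelaxParams,
    mapped: list[tuple[np.ndarray, np.ndarray]],
) -> RestraintSet:
    """Mapped atoms tether to bead references; solvent oxygens and ions
    tether (more weakly) to their placed positions so the Martini solvent
    distribution survives while clashes can still resolve."""
    idx_parts, ref_parts, k_parts = [], [], []
    for indices, refs in mapped:
        idx_parts.append(np.asarray(indices, dtype=int))
        ref_parts.append(np.asarray(refs, dtype=float))
        k_parts.append(np.full(len(indices), params.restraint_k))
    pos = sys.structure.positions()
    for p in sys.provenance:
        if p.kind == "water":
            o = p.span[0]  # oxygen is the first site of each water
            idx_parts.append(np.array([o]))
            ref_parts.append(pos[o:o + 1])
            k_parts.append(np.array([params.solvent_restraint_k]))
        elif p.kind == "ion":
            i = p.span[0]
            idx_parts.append(np.array([i]))
            ref_parts.append(pos[i:i + 1])
            k_parts.append(np.array([params.solvent_restraint_k]))
    return RestraintSet(
        atom_indices=np.concatenate(idx_parts),
        references=np.concatenate(ref_parts),
        k=np.concatenate(k_parts),
    )


def system_relax(
    sys: AASystem,
    restraints: RestraintSet,
    params: SystemRelaxParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[AASystem, dict]:
    """Constant-volume restrained relaxation of the assembled system.

    Runs minimize -> short stochastic dynamics -> minimize with the capped
    repulsion active across molecules under periodic minimum-image
    distances.  The box is never altered (pressure coupling belongs to the
    production engine, after export).
    """
    params = params or SystemRelaxParams()
    ff = build_system_forcefield(sys)
    box = sys.structure.box
    x = sys.structure.positions()
    x, rep1 = minimize(x, ff, restraints, params, pairs_scope="all", box=box)
    if params.sd_steps > 0:
        x = stochastic_relax(x, ff, restraints, params, seed=seed, pairs_scope="all", box=box)
        x, rep2 = minimize(x, ff, restraints, params, pairs_scope="all", box=box)
    else:
        rep2 = rep1
    relaxed = AASystem(
        structure=sys.structure.with_positions(x),
        provenance=sys.provenance,
        molecule_of=sys.molecule_of,
        restraints=restraints,
        audit=dict(sys.audit),
    )
    # keep the box bit-identical to the input
    relaxed.structure.box = None if box is None else box.copy()
    report = {"em1": rep1.as_dict(), "em2": rep2.as_dict(),
              "mapped_rmsd": restraints.mapped_rmsd(x)}
    return relaxed, report


@dataclass
class ChiralityEntry:
    molecule_index: int
    molecule_name: str
    center_serials: tuple[int, int, int, int]
    template_sign: float
    observed_sign: float

    @property
    def ok(self) -> bool:
        return self.template_sign == self.observed_sign


@dataclass
class ChiralityReport:
    entries: list[ChiralityEntry]

    @property
    def n_checked(self) -> int:
        return len(self.entries)

    @property
    def n_flipped(self) -> int:
        return sum(1 for e in self.entries if not e.ok)

    @property
    def all_ok(self) -> bool:
        return self.n_flipped == 0

    def as_dict(self) -> dict:
        return {
            "n_checked": self.n_checked,
            "n_flipped": self.n_flipped,
            "failures": [
                {
                    "molecule_index": e.molecule_index,
                    "molecule_name": e.molecule_name,
                    "center_serials": list(e.center_serials),
                }
                for e in self.entries
                if not e.ok
            ],
        }


def check_chirality(sys: AASystem) -> ChiralityReport:
    """Audit every declared stereocenter against its template handedness.

    The observed sign is the sign of the triple product
    (b-center) . ((a-center) x (c-center)); a mirror image flips it.
    """
    pos = sys.structure.positions()
    entries: list[ChiralityEntry] = []
    for mi, p in enumerate(sys.provenance):
        if p.kind != "molecule" or p.template is None or not p.template.chiral_centers:
            continue
        tmpl = p.template
        ref_signs = tmpl.chiral_signs()
        start = p.span[0]
        for quad, ref in zip(tmpl.chiral_centers, ref_signs):
            try:
                li = [tmpl.index_of_serial(s) for s in quad]
            except Exception as exc:
                raise ValueError(f"molecule {p.name!r}: chiral center atoms missing: {exc}")
            obs = float(np.sign(signed_volume(pos, start + li[0], start + li[1],
                                              start + li[2], start + li[3])))
            entries.append(ChiralityEntry(mi, p.name, quad, ref, obs))
    return ChiralityReport(entries=entries)


def check_clashes(sys: AASystem, cutoff: float = 0.08) -> list[tuple[int, int, float]]:
    """Inter-molecular heavy-atom pairs closer than ``cutoff`` (nm).

    Uses a periodic cell-list (KD-tree) neighbor search; hydrogens are
    excluded, as are pairs within one molecule (bonded geometry is the
    relaxation engine's business, not a packing clash).
    """
    pos = sys.structure.positions()
    heavy = np.array([a.element.upper() != "H" for a in sys.structure.atoms], dtype=bool)
    hidx = np.flatnonzero(heavy)
    if len(hidx) < 2:
        return []
    pts = pos[hidx]
    box = sys.structure.box
    if box is not None:
        pts = np.mod(pts, box)
        pts = np.where(pts >= box, 0.0, pts)
        tree = cKDTree(pts, boxsize=box)
    else:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: list[tuple[int, int, float]] = []
    for a, b in pairs:
        gi, gj = int(hidx[a]), int(hidx[b])
        if sys.molecule_of[gi] == sys.molecule_of[gj]:
            continue
        d = pos[gi] - pos[gj]
        if box is not None:
            d = d - box * np.round(d / box)
        r = float(np.linalg.norm(d))
        if r < cutoff:
            out.append((gi, gj, r))
    return sorted(out)
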