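"""Synthetic systems with known ground truth, plus brute-force test oracles.

Everything a pipeline run needs — CG structures, topologies, residue maps,
atomistic templates with bonded terms and a declared stereocenter — is
generated here at toy scale (3-bead amphiphiles of ~10 atoms instead of a
134-atom phospholipid), so every stage is testable without downloads.  The
file writers emit the same formats the tool consumes, dogfooding the
parsers.  All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import write_structure
from .mapping import MoleculeTemplate
from .records import AtomRecord, BondedTerms, ResidueMap, StructureRecord, TopologyCounts

__all__ = [
    "toy_amphiphile_template",
    "toy_residue_map",
    "toy_peptide_template",
    "benzyl_alcohol_residue_map",
    "write_template_files",
    "write_bonded_itp",
    "gen_bilayer",
    "gen_micelle",
    "oracle_best_rotation",
    "oracle_all_pairs_clashes",
]

_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)

TOY_NAME = "TOA"


def toy_amphiphile_template(n_tail: int = 6, name: str = TOY_NAME) -> MoleculeTemplate:
    """A 3-bead toy amphiphile: polar head with one stereocenter + alkyl tail.

    Atoms: C1 (stereocenter) with substituents O1, N1, C2 plus the tail
    C3..C(2+n_tail) in an all-anti zigzag (bond 0.153 nm, angle 111 deg).
    The declared chiral center is (C1; O1, N1, C3) with signed volume
    ~ +0.0025 nm^3, comfortably above the 0.001 nm^3 degeneracy floor.
    """
    if n_tail < 2:
        raise ValueError("need at least 2 tail atoms")
    l = 0.153
    pos = {
        "C1": np.zeros(3),
        "O1": 0.143 * _TETRA[0],
        "N1": 0.147 * _TETRA[1],
        "C2": 0.153 * _TETRA[2],
        "C3": 0.153 * _TETRA[3],
    }
    theta = math.radians(111.0)
    dz = l * math.sqrt((1 - math.cos(theta)) / 2.0)
    h = l * math.sqrt((1 + math.cos(theta)) / 2.0)
    axis = _TETRA[3]
    ref = np.array([1.0, 0.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    for k in range(1, n_tail):
        pos[f"C{3 + k}"] = pos["C3"] + axis * (k * dz) + perp * ((k % 2) * h)

    order = ["C1", "O1", "N1", "C2"] + [f"C{3 + k}" for k in range(n_tail)]
    atoms = [
        AtomRecord(serial=i + 1, name=nm, residue_name=name, residue_seq=1, position=pos[nm])
        for i, nm in enumerate(order)
    ]
    serial = {nm: i + 1 for i, nm in enumerate(order)}
    bonds = [(serial["C1"], serial["O1"]), (serial["C1"], serial["N1"]),
             (serial["C1"], serial["C2"]), (serial["C1"], serial["C3"])]
    for k in range(1, n_tail):
        bonds.append((serial[f"C{2 + k}"], serial[f"C{3 + k}"]))
    # measured equilibria, stiff defaults
    parr = np.array([a.position for a in atoms])
    bond_terms = [(i, j, float(np.linalg.norm(parr[i - 1] - parr[j - 1])), 5000.0)
                  for i, j in bonds]
    terms = BondedTerms(bonds=bond_terms, angles=_angles_from_bonds(bonds, parr))
    chiral = [(serial["C1"], serial["O1"], serial["N1"], serial["C3"])]
    return MoleculeTemplate(name=name, atoms=atoms, bonded=terms, chiral_centers=chiral)


def _angles_from_bonds(bonds, pos, ktheta: float = 500.0):
    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    angles = []
    for j, nbrs in sorted(adj.items()):
        nb = sorted(nbrs)
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, k = nb[x], nb[y]
                u = pos[i - 1] - pos[j - 1]
                v = pos[k - 1] - pos[j - 1]
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                angles.append((i, j, k, math.degrees(math.acos(np.clip(c, -1, 1))), ktheta))
    return angles


def toy_residue_map(template: MoleculeTemplate | None = None) -> ResidueMap:
    """Bead->serial map for the toy amphiphile: head O1, mid-tail, tail end."""
    template = template or toy_amphiphile_template()
    serial = {a.name: a.serial for a in template.atoms}
    n_tail = template.n_atoms - 4
    mid = f"C{3 + n_tail // 2}"
    last = f"C{2 + n_tail}"
    rmap = ResidueMap()
    rmap.add(template.name, [(1, serial["O1"]), (2, serial[mid]), (3, serial[last])])
    return rmap


def benzyl_alcohol_residue_map() -> ResidueMap:
    """Example 3-bead aromatic-alcohol mapping (beads 1,2,3 -> atoms 7,5,2)."""
    rmap = ResidueMap()
    rmap.add("BZA", [(1, 7), (2, 5), (3, 2)])
    return rmap


def toy_peptide_template(sequence: tuple[str, ...] = ("ALA", "CYS", "ALA"),
                         name: str = "TPEP") -> MoleculeTemplate:
    """A tiny all-backbone peptide template (N, CA, C, O per residue, + SG
    for CYS), chain A, for exercising the per-residue protein mapping."""
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    serial = 0
    prev_c = None
    for ri, resname in enumerate(sequence, start=1):
        base = np.array([0.35 * (ri - 1), 0.0, 0.0])
        local = {
            "N": base + np.array([0.00, 0.00, 0.00]),
            "CA": base + np.array([0.145, 0.05, 0.00]),
            "C": base + np.array([0.25, -0.05, 0.05]),
            "O": base + np.array([0.27, -0.17, 0.08]),
        }
        if resname == "CYS":
            local["SG"] = base + np.array([0.16, 0.18, 0.12])
        ids = {}
        for nm, p in local.items():
            serial += 1
            ids[nm] = serial
            atoms.append(AtomRecord(serial=serial, name=nm, residue_name=resname,
                                    residue_seq=ri, chain="A", position=p))
        bonds += [(ids["N"], ids["CA"]), (ids["CA"], ids["C"]), (ids["C"], ids["O"])]
        if "SG" in ids:
            bonds.append((ids["CA"], ids["SG"]))
        if prev_c is not None:
            bonds.append((prev_c, ids["N"]))
        prev_c = ids["C"]
    parr = np.array([a.position for a in atoms])
    bond_terms = [(i, j, float(np.linalg.norm(parr[i - 1] - parr[j - 1])), 5000.0)
                  for i, j in bonds]
    terms = BondedTerms(bonds=bond_terms, angles=_angles_from_bonds(bonds, parr))
    return MoleculeTemplate(name=name, atoms=atoms, bonded=terms)


def write_bonded_itp(template: MoleculeTemplate, path) -> None:
    """Write the template's bonded terms in itp [ bonds ]/[ angles ] form."""
    with open(path, "w") as fh:
        fh.write(f"; bonded terms for {template.name}\n[ bonds ]\n;  i   j  funct  b0(nm)  kb\n")
        for i, j, b0, kb in template.bonded.bonds:
            fh.write(f"{i:4d} {j:4d}   1  {b0:8.5f}  {kb:10.1f}\n")
        if template.bonded.angles:
            fh.write("\n[ angles ]\n;  i   j   k  funct  theta0(deg)  ktheta\n")
            for i, j, k, t0, kt in template.bonded.angles:
                fh.write(f"{i:4d} {j:4d} {k:4d}   1  {t0:9.3f}  {kt:10.1f}\n")


def write_template_files(template: MoleculeTemplate, template_dir) -> None:
    """Emit <name>.pdb, <name>.itp and (if stereocenters) <name>.chiral."""
    tdir = Path(template_dir)
    tdir.mkdir(parents=True, exist_ok=True)
    write_structure(StructureRecord(atoms=template.atoms, box=None, title=template.name),
                    tdir / f"{template.name}.pdb", "pdb")
    write_bonded_itp(template, tdir / f"{template.name}.itp")
    if template.chiral_centers:
        with open(tdir / f"{template.name}.chiral", "w") as fh:
            fh.write("; stereocenters: center a b c (atom serials)\n")
            for quad in template.chiral_centers:
                fh.write(" ".join(str(s) for s in quad) + "\n")


def _place_lipid_beads(template: MoleculeTemplate, rmap: ResidueMap,
                       rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Bead positions of one randomly oriented rigid toy lipid, tail along -z,
    head bead at the local origin; jitter emulates CG thermal disorder."""
    serial_to_idx = {a.serial: i for i, a in enumerate(template.atoms)}
    mapped = np.array([template.atoms[serial_to_idx[s]].position
                       for _, s in rmap[template.name]])
    head, tail = mapped[0], mapped[-1]
    axis = tail - head
    axis /= np.linalg.norm(axis)
    # rotate so the head->tail axis is -z, then random azimuthal spin
    R_align = _rotation_onto(axis, np.array([0.0, 0.0, -1.0]))
    phi = rng.uniform(0, 2 * math.pi)
    cz, sz = math.cos(phi), math.sin(phi)
    R_spin = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    beads = (mapped - head) @ (R_spin @ R_align).T
    return beads + rng.normal(0.0, jitter, size=beads.shape)


def _rotation_onto(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    c = float(np.dot(u, v))
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    w = w / s
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def gen_bilayer(
    nx: int,
    ny: int,
    apl: float = 0.64,
    seed: int = 0,
    waters_per_lipid: float = 6.0,
    wf_fraction: float = 0.10,
    ion_fraction: float = 0.01,
    jitter: float = 0.02,
    template: MoleculeTemplate | None = None,
) -> tuple[StructureRecord, TopologyCounts]:
    """A 2*nx*ny-lipid CG bilayer (two leaflet lattices with jitter), solvated
    with W beads — a fraction relabeled WF anti-freeze — plus NA+/CL- beads.

    The box follows the requested area per lipid; all beads lie inside it.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx, ny must be >= 1")
    rng = np.random.default_rng(seed)
    template = template or toy_amphiphile_template()
    rmap = toy_residue_map(template)
    a = math.sqrt(apl)
    lx, ly = nx * a, ny * a
    lz = 6.0
    zc = lz / 2.0
    head_off = 1.1  # head-bead |z - center|

    beads: list[AtomRecord] = []
    serial = 0
    resseq = 0

    def add_bead(name, resname, p):
        nonlocal serial, resseq
        serial += 1
        p = np.mod(p, [lx, ly, lz])
        beads.append(AtomRecord(serial=serial, name=name, residue_name=resname,
                                residue_seq=resseq, position=p))

    n_lipids = 2 * nx * ny
    for leaflet, zsign in ((0, +1), (1, -1)):
        for ix in range(nx):
            for iy in range(ny):
                local = _place_lipid_beads(template, rmap, rng, jitter)
                if zsign < 0:
                    local = local @ np.diag([1.0, -1.0, -1.0]).T  # proper flip
                origin = np.array([(ix + 0.5) * a, (iy + 0.5) * a, zc + zsign * head_off])
                resseq += 1
                for bi, p in enumerate(local):
                    add_bead(f"B{bi + 1}", template.name, origin + p)

    # solvent lattice in the two slabs above and below the membrane
    n_w_target = int(round(waters_per_lipid * n_lipids))
    spacing = 0.47
    sites = []
    for z0, z1 in ((0.25, zc - head_off - 0.35), (zc + head_off + 0.35, lz - 0.25)):
        zs = np.arange(z0, z1, spacing)
        xs = np.arange(0.25, lx - 0.1, spacing)
        ys = np.arange(0.25, ly - 0.1, spacing)
        for z in zs:
            for x in xs:
                for y in ys:
                    sites.append(np.array([x, y, z]))
    sites = np.array(sites)
    if len(sites) < n_w_target:
        n_w_target = len(sites)
    chosen = sites[rng.permutation(len(sites))[:n_w_target]]
    chosen = chosen + rng.normal(0.0, 0.03, size=chosen.shape)

    n_ion = max(1, int(round(ion_fraction * n_w_target)))
    n_solvent_w = n_w_target - 2 * n_ion
    n_wf = int(round(wf_fraction * n_solvent_w))
    n_w = n_solvent_w - n_wf

    k = 0
    for _ in range(n_w):
        resseq += 1
        add_bead("W", "W", chosen[k]); k += 1
    for _ in range(n_wf):
        resseq += 1
        add_bead("WF", "WF", chosen[k]); k += 1
    for _ in range(n_ion):
        resseq += 1
        add_bead("NA+", "NA+", chosen[k]); k += 1
    for _ in range(n_ion):
        resseq += 1
        add_bead("CL-", "CL-", chosen[k]); k += 1

    entries = [(template.name, n_lipids), ("W", n_w)]
    if n_wf:
        entries.append(("WF", n_wf))
    entries += [("NA+", n_ion), ("CL-", n_ion)]
    structure = StructureRecord(atoms=beads, box=np.array([lx, ly, lz]),
                                title=f"toy CG bilayer {nx}x{ny}")
    return structure, TopologyCounts(entries=entries)


def gen_micelle(
    n_molecules: int,
    radius: float = 1.2,
    seed: int = 0,
    jitter: float = 0.02,
    template: MoleculeTemplate | None = None,
) -> tuple[StructureRecord, TopologyCounts]:
    """A toy CG micelle: head beads on a sphere, tails pointing inward."""
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    rng = np.random.default_rng(seed)
    template = template or toy_amphiphile_template()
    rmap = toy_residue_map(template)
    box_l = 2 * radius + 4.0
    center = np.full(3, box_l / 2.0)

    # Fibonacci sphere for even head placement
    beads: list[AtomRecord] = []
    serial = 0
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for m in range(n_molecules):
        zf = 1.0 - 2.0 * (m + 0.5) / n_molecules
        rf = math.sqrt(max(0.0, 1.0 - zf * zf))
        phi = golden * m
        outward = np.array([rf * math.cos(phi), rf * math.sin(phi), zf])
        local = _place_lipid_beads(template, rmap, rng, jitter)
        R = _rotation_onto(np.array([0.0, 0.0, -1.0]), -outward)  # tail inward
        placed = center + outward * radius + local @ R.T
        for bi, p in enumerate(placed):
            serial += 1
            beads.append(AtomRecord(serial=serial, name=f"B{bi + 1}",
                                    residue_name=template.name, residue_seq=m + 1,
                                    position=np.mod(p, box_l)))
    structure = StructureRecord(atoms=beads, box=np.full(3, box_l),
                                title=f"toy CG micelle n={n_molecules}")
    return structure, TopologyCounts(entries=[(template.name, n_molecules)])


def oracle_best_rotation(
    mobile: np.ndarray,
    target: np.ndarray,
    n_samples: int = 10000,
    seed: int = 0,
) -> float:
    """Min RMSD over uniformly sampled proper rotations (optimal translation
    each): an upper bound on the true optimum, used to verify the analytic fit."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    A = mobile - mobile.mean(axis=0)
    B = target - target.mean(axis=0)
    rng = np.random.default_rng(seed)
    Rs = Rotation.random(n_samples, rng=rng).as_matrix()
    Rs[0] = np.eye(3)  # always include the identity in the sample set
    rotated = np.einsum("rij,nj->rni", Rs, A)
    msd = np.mean(np.sum((rotated - B[None]) ** 2, axis=2), axis=1)
    return float(np.sqrt(msd.min()))


def oracle_all_pairs_clashes(sys, cutoff: float = 0.08) -> list[tuple[int, int, float]]:
    """O(N^2) minimum-image reference for the cell-list clash search."""
    pos = sys.structure.positions()
    box = sys.structure.box
    heavy = np.array([a.element.upper() != "H" for a in sys.structure.atoms], dtype=bool)
    out = []
    n = len(pos)
    for i in range(n):
        if not heavy[i]:
            continue
        for j in range(i + 1, n):
            if not heavy[j] or sys.molecule_of[i] == sys.molecule_of[j]:
                continue
            d = pos[i] - pos[j]
            if box is not None:
                d = d - box * np.round(d / box)
            r = float(np.linalg.norm(d))
            if r < cutoff:
                out.append((i, j, r))
    return sorted(out)
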