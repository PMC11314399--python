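"""Resolvation: CG water and ion beads become atomistic water clusters.

Each Martini W (or WF) bead stands for four real waters; each ion bead is
the 'solvated ion' paradigm, one ion plus its first hydration shell of four
waters.  Clusters are rigid templates — oxygens at tetrahedron vertices,
three-site water geometry (O-H 0.09572 nm, H-O-H 104.52 deg) — given a
seeded uniform random orientation per bead and translated onto the bead.
Shell waters orient by ion charge: oxygen toward a cation, hydrogens toward
an anion.  Inter-cluster overlap is left to the system-level soft-core
relaxation, matching the final restrained-equilibration stage of the
protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "IonSpec",
    "DEFAULT_ION_TABLE",
    "SolventAtoms",
    "water_cluster_template",
    "ion_shell_template",
    "backmap_waters",
    "backmap_ions",
]

O_H = 0.09572  # nm
HOH_ANGLE = math.radians(104.52)
WATER_CLUSTER_RADIUS = 0.31  # nm, O distance from cluster center

_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)


@dataclass(frozen=True)
class IonSpec:
    name: str  # emitted residue/atom name
    charge: int
    shell_radius: float  # nm, ion-O distance


#: bead name -> ion species; cations hold water oxygens closer than anions.
DEFAULT_ION_TABLE: dict[str, IonSpec] = {
    "NA+": IonSpec("NA", +1, 0.23),
    "NA": IonSpec("NA", +1, 0.23),
    "CL-": IonSpec("CL", -1, 0.31),
    "CL": IonSpec("CL", -1, 0.31),
}


def _single_water(oxygen: np.ndarray, outward: np.ndarray) -> np.ndarray:
    """3-site water at ``oxygen`` with its dipole (H-bisector) along ``outward``."""
    z = outward / np.linalg.norm(outward)
    # any perpendicular axis; deterministic choice
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    xax = np.cross(z, ref)
    xax /= np.linalg.norm(xax)
    half = HOH_ANGLE / 2.0
    h1 = oxygen + O_H * (math.cos(half) * z + math.sin(half) * xax)
    h2 = oxygen + O_H * (math.cos(half) * z - math.sin(half) * xax)
    return np.array([oxygen, h1, h2])


def water_cluster_template() -> np.ndarray:
    """(12, 3) sites of 4 waters (O,H1,H2 each), centroid of oxygens at origin.

    Oxygens sit at tetrahedron vertices 0.31 nm from the center with each
    water's hydrogens pointing outward, so the minimum O-O distance is the
    tetrahedron edge (~0.51 nm) and no intra-cluster pair clashes.
    """
    sites = [_single_water(WATER_CLUSTER_RADIUS * d, d) for d in _TETRA]
    return np.concatenate(sites, axis=0)


def ion_shell_template(spec: IonSpec) -> np.ndarray:
    """(13, 3) sites: ion at origin + 4 shell waters at tetrahedron vertices.

    For a cation the water oxygens point toward the ion (dipole outward);
    for an anion the hydrogens point inward (dipole toward the ion).
    """
    sites = [np.zeros((1, 3))]
    for d in _TETRA:
        o = spec.shell_radius * d
        outward = d if spec.charge > 0 else -d
        sites.append(_single_water(o, outward))
    return np.concatenate(sites, axis=0)


@dataclass
class SolventAtoms:
    """Flat arrays of placed solvent sites plus per-molecule grouping."""

    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    names: list[str] = field(default_factory=list)
    resnames: list[str] = field(default_factory=list)
    mol_sizes: list[int] = field(default_factory=list)  # atoms per solvent molecule

    @property
    def n_molecules(self) -> int:
        return len(self.mol_sizes)


def backmap_waters(
    bead_positions: np.ndarray,
    seed: int | np.random.SeedSequence = 0,
    water_resname: str = "SOL",
) -> SolventAtoms:
    """Place 4 three-site waters per CG water bead (random rigid orientation)."""
    beads = np.asarray(bead_positions, dtype=float).reshape(-1, 3)
    if len(beads) and not np.isfinite(beads).all():
        raise ValueError("non-finite bead positions")
    rng = np.random.default_rng(seed)
    template = water_cluster_template()
    out = SolventAtoms()
    chunks = []
    for bead in beads:
        R = Rotation.random(rng=rng).as_matrix()
        chunks.append(template @ R.T + bead)
        for _ in range(4):
            out.names.extend(["OW", "HW1", "HW2"])
            out.resnames.extend([water_resname] * 3)
            out.mol_sizes.append(3)
    out.positions = np.concatenate(chunks, axis=0) if chunks else np.zeros((0, 3))
    return out


def backmap_ions(
    beads: list[tuple[str, np.ndarray]],
    seed: int | np.random.SeedSequence = 0,
    ion_table: dict[str, IonSpec] | None = None,
    water_resname: str = "SOL",
) -> tuple[SolventAtoms, SolventAtoms]:
    """Place 1 ion + 4 shell waters per ion bead.

    Returns (ions, shell_waters) as separate groups so the assembler can
    keep all waters in one block.  Unknown species raise with the list of
    configured ones.
    """
    table = ion_table or DEFAULT_ION_TABLE
    rng = np.random.default_rng(seed)
    ions = SolventAtoms()
    shell = SolventAtoms()
    ion_chunks, shell_chunks = [], []
    for species, pos in beads:
        if species not in table:
            raise KeyError(
                f"unknown ion species {species!r}; configured: {sorted(table)}"
            )
        spec = table[species]
        R = Rotation.random(rng=rng).as_matrix()
        sites = ion_shell_template(spec) @ R.T + np.asarray(pos, dtype=float)
        ion_chunks.append(sites[:1])
        ions.names.append(spec.name)
        ions.resnames.append(spec.name)
        ions.mol_sizes.append(1)
        shell_chunks.append(sites[1:])
        for _ in range(4):
            shell.names.extend(["OW", "HW1", "HW2"])
            shell.resnames.extend([water_resname] * 3)
            shell.mol_sizes.append(3)
    ions.positions = np.concatenate(ion_chunks, axis=0) if ion_chunks else np.zeros((0, 3))
    shell.positions = np.concatenate(shell_chunks, axis=0) if shell_chunks else np.zeros((0, 3))
    return ions, shell
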