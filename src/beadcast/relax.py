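"""Position-restrained relaxation on a minimal internal force field.

The force field carries harmonic bonds and angles (equilibria from the itp
when present, otherwise measured from the template geometry), harmonic
position restraints anchoring mapped atoms to CG bead positions, and a
capped repulsive nonbonded term

    E(r) = eps * (1 - r/rc)^2   for r < rc, else 0

applied to non-excluded pairs.  The cap keeps the energy finite for any
configuration, including exact overlap, so freshly placed solvent can relax
apart — the same property a soft-core potential provides in an MD engine.
Dihedral and improper terms are deliberately absent: chirality is protected
structurally (proper-rotation-only fits plus the chirality audit), not
energetically.

Internal units: nm, ps, kJ/mol, amu; kB = 0.008314 kJ/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .records import KB, BondedTerms

__all__ = [
    "RestraintSet",
    "MiniForceField",
    "MinimizerReport",
    "RelaxParams",
    "energy_forces",
    "minimize",
    "stochastic_relax",
    "relax_molecule",
]

_TREE_THRESHOLD = 200  # above this many atoms, pair generation goes via a KD-tree


@dataclass
class RestraintSet:
    """Harmonic restraints: E = sum 1/2 k |x - x_ref|^2."""

    atom_indices: np.ndarray
    references: np.ndarray
    k: np.ndarray | float = 10000.0

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.references = np.asarray(self.references, dtype=float).reshape(-1, 3)
        if len(self.atom_indices) != len(self.references):
            raise ValueError("restraint indices and references differ in length")
        if len(np.unique(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("restraint atom indices must be unique")
        self.k = np.broadcast_to(np.asarray(self.k, dtype=float), self.atom_indices.shape).copy()
        if not (self.k > 0).all():
            raise ValueError("restraint force constants must be positive")

    def __len__(self) -> int:
        return len(self.atom_indices)

    def mapped_rmsd(self, coords: np.ndarray) -> float:
        """RMSD of the restrained atoms to their reference positions."""
        if len(self) == 0:
            return 0.0
        d = coords[self.atom_indices] - self.references
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


@dataclass
class MiniForceField:
    """Array-of-terms force field for one molecule or an assembled system."""

    n_atoms: int
    bond_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_b0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_kb: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    angle_t0: np.ndarray = field(default_factory=lambda: np.zeros(0))  # radians
    angle_kt: np.ndarray = field(default_factory=lambda: np.zeros(0))
    eps: float = 100.0  # kJ/mol, repulsion cap
    rc: float = 0.25  # nm, repulsion range
    excluded_keys: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    _intra_pairs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.bond_idx = np.asarray(self.bond_idx, dtype=int).reshape(-1, 2)
        self.angle_idx = np.asarray(self.angle_idx, dtype=int).reshape(-1, 3)
        self.excluded_keys = np.sort(np.asarray(self.excluded_keys, dtype=np.int64))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_template(
        cls,
        template,
        kb_default: float = 5000.0,
        kt_default: float = 500.0,
        derive_angles: bool = True,
    ) -> "MiniForceField":
        """Build from a MoleculeTemplate; missing equilibria are measured
        from the reference geometry and missing angles derived from the
        bond graph."""
        pos = template.positions()
        n = template.n_atoms
        bonds = template.bonded.bonds
        angles = list(template.bonded.angles)
        if derive_angles and not angles:
            adj: dict[int, list[int]] = {}
            for i, j, *_ in bonds:
                adj.setdefault(i, []).append(j)
                adj.setdefault(j, []).append(i)
            for j, nbrs in sorted(adj.items()):
                nb = sorted(nbrs)
                for x in range(len(nb)):
                    for y in range(x + 1, len(nb)):
                        angles.append((nb[x], j, nb[y], None, None))

        bi, b0s, kbs = [], [], []
        for i, j, b0, kb in bonds:
            bi.append((i - 1, j - 1))
            b0s.append(b0 if b0 is not None else float(np.linalg.norm(pos[i - 1] - pos[j - 1])))
            kbs.append(kb if kb is not None else kb_default)
        ai, t0s, kts = [], [], []
        for i, j, k, t0, kt in angles:
            ai.append((i - 1, j - 1, k - 1))
            if t0 is None:
                u = pos[i - 1] - pos[j - 1]
                v = pos[k - 1] - pos[j - 1]
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                t0s.append(float(np.arccos(np.clip(c, -1.0, 1.0))))
            else:
                t0s.append(math.radians(t0))
            kts.append(kt if kt is not None else kt_default)

        # exclusions derive from the full bond graph (1-2 and 1-3),
        # independent of whether angles were listed
        terms = BondedTerms(bonds=bonds, angles=[])
        keys = np.array(
            [(i - 1) * n + (j - 1) for i, j in terms.exclusion_pairs()], dtype=np.int64
        )
        return cls(
            n_atoms=n,
            bond_idx=np.array(bi, dtype=int).reshape(-1, 2),
            bond_b0=np.array(b0s),
            bond_kb=np.array(kbs),
            angle_idx=np.array(ai, dtype=int).reshape(-1, 3),
            angle_t0=np.array(t0s),
            angle_kt=np.array(kts),
            excluded_keys=keys,
        )

    @classmethod
    def merge(cls, parts: list[tuple["MiniForceField", int]], n_total: int) -> "MiniForceField":
        """Concatenate per-molecule fields at the given atom offsets."""
        bi, b0, kb, ai, t0, kt, keys = [], [], [], [], [], [], []
        for ff, off in parts:
            if len(ff.bond_idx):
                bi.append(ff.bond_idx + off)
                b0.append(ff.bond_b0)
                kb.append(ff.bond_kb)
            if len(ff.angle_idx):
                ai.append(ff.angle_idx + off)
                t0.append(ff.angle_t0)
                kt.append(ff.angle_kt)
            if len(ff.excluded_keys):
                old_i, old_j = divmod(ff.excluded_keys, ff.n_atoms)
                keys.append((old_i + off) * n_total + (old_j + off))
        cat = lambda xs, empty: np.concatenate(xs) if xs else empty
        return cls(
            n_atoms=n_total,
            bond_idx=cat(bi, np.zeros((0, 2), dtype=int)),
            bond_b0=cat(b0, np.zeros(0)),
            bond_kb=cat(kb, np.zeros(0)),
            angle_idx=cat(ai, np.zeros((0, 3), dtype=int)),
            angle_t0=cat(t0, np.zeros(0)),
            angle_kt=cat(kt, np.zeros(0)),
            excluded_keys=cat(keys, np.zeros(0, dtype=np.int64)),
        )

    # -- pair generation --------------------------------------------------

    def _filter_excluded(self, pi: np.ndarray, pj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if len(self.excluded_keys) == 0 or len(pi) == 0:
            return pi, pj
        lo = np.minimum(pi, pj).astype(np.int64)
        hi = np.maximum(pi, pj).astype(np.int64)
        key = lo * self.n_atoms + hi
        pos = np.searchsorted(self.excluded_keys, key)
        pos = np.clip(pos, 0, len(self.excluded_keys) - 1)
        mask = self.excluded_keys[pos] != key
        return pi[mask], pj[mask]

    def nonbonded_pairs(self, coords: np.ndarray, box: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Non-excluded candidate pairs within the repulsion range."""
        n = self.n_atoms
        if n > _TREE_THRESHOLD or box is not None:
            pts = coords
            if box is not None:
                pts = np.mod(coords, box)
                # guard against fp landing exactly on the upper boundary
                pts = np.where(pts >= box, 0.0, pts)
                tree = cKDTree(pts, boxsize=box)
            else:
                tree = cKDTree(pts)
            pairs = tree.query_pairs(self.rc, output_type="ndarray")
            if len(pairs) == 0:
                return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
            pi, pj = pairs[:, 0], pairs[:, 1]
        else:
            if self._intra_pairs is None:
                iu = np.triu_indices(n, k=1)
                pi, pj = self._filter_excluded(iu[0], iu[1])
                self._intra_pairs = np.stack([pi, pj], axis=1)
            pairs = self._intra_pairs
            return pairs[:, 0], pairs[:, 1]
        return self._filter_excluded(pi, pj)


@dataclass
class MinimizerReport:
    steps_taken: int
    accepted_steps: int
    initial_energy: float
    final_energy: float
    final_max_force: float
    final_mapped_rmsd: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "steps_taken": self.steps_taken,
            "accepted_steps": self.accepted_steps,
            "initial_energy": self.initial_energy,
            "final_energy": self.final_energy,
            "final_max_force": self.final_max_force,
            "final_mapped_rmsd": self.final_mapped_rmsd,
            "converged": self.converged,
        }


@dataclass
class RelaxParams:
    """Tunables of the relaxation stages (defaults sized for stiff bonds)."""

    restraint_k: float = 10000.0  # kJ/mol/nm^2, mapped-atom tether
    em_step0: float = 0.005  # nm, initial max displacement of a descent step
    em_max_steps: int = 2000
    em_f_tol: float = 10.0  # kJ/mol/nm
    sd_dt: float = 0.0005  # ps
    sd_gamma: float = 50.0  # kJ/mol ps nm^-2, friction per unit velocity
    sd_steps: int = 1000
    temperature: float = 313.0  # K


def energy_forces(
    coords: np.ndarray,
    ff: MiniForceField,
    restraints: RestraintSet | None = None,
    pairs_scope: str = "intramolecular",
    box: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Total energy (kJ/mol) and per-atom forces (kJ/mol/nm).

    ``pairs_scope`` selects whether the capped repulsion acts within one
    molecule only (vacuum relaxation of a single molecule) or across the
    whole system ("all"); with a box, distances use the minimum image.
    The gradient is analytic and consistent with the energy.
    """
    x = np.asarray(coords, dtype=float)
    if x.shape != (ff.n_atoms, 3):
        raise ValueError(f"coords shape {x.shape} does not match n_atoms {ff.n_atoms}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite coordinates")
    if pairs_scope not in ("intramolecular", "all"):
        raise ValueError(f"unknown pairs_scope {pairs_scope!r}")

    energy = 0.0
    forces = np.zeros_like(x)

    def min_image(d):
        if box is not None:
            return d - box * np.round(d / box)
        return d

    if len(ff.bond_idx):
        i, j = ff.bond_idx[:, 0], ff.bond_idx[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        safe = np.maximum(r, 1e-12)
        dev = r - ff.bond_b0
        energy += float(np.sum(0.5 * ff.bond_kb * dev * dev))
        fvec = (-ff.bond_kb * dev / safe)[:, None] * d
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)

    if len(ff.angle_idx):
        i, j, k = ff.angle_idx[:, 0], ff.angle_idx[:, 1], ff.angle_idx[:, 2]
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
        nv = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        s = np.maximum(np.sqrt(1.0 - c * c), 1e-8)
        theta = np.arccos(c)
        dev = theta - ff.angle_t0
        energy += float(np.sum(0.5 * ff.angle_kt * dev * dev))
        dEdt = ff.angle_kt * dev
        dth_di = -(vh - c[:, None] * uh) / (nu * s)[:, None]
        dth_dk = -(uh - c[:, None] * vh) / (nv * s)[:, None]
        np.add.at(forces, i, -dEdt[:, None] * dth_di)
        np.add.at(forces, k, -dEdt[:, None] * dth_dk)
        np.add.at(forces, j, dEdt[:, None] * (dth_di + dth_dk))

    pi, pj = ff.nonbonded_pairs(x, box if pairs_scope == "all" else None)
    if len(pi):
        d = min_image(x[pi] - x[pj])
        r = np.linalg.norm(d, axis=1)
        mask = r < ff.rc
        if mask.any():
            pi, pj, d, r = pi[mask], pj[mask], d[mask], r[mask]
            t = 1.0 - r / ff.rc
            energy += float(np.sum(ff.eps * t * t))
            # direction is undefined at exact overlap; use a fixed axis
            dhat = np.where(r[:, None] > 1e-10, d / np.maximum(r, 1e-10)[:, None],
                            np.array([0.0, 0.0, 1.0]))
            fmag = 2.0 * ff.eps * t / ff.rc
            np.add.at(forces, pi, fmag[:, None] * dhat)
            np.add.at(forces, pj, -fmag[:, None] * dhat)

    if restraints is not None and len(restraints):
        d = x[restraints.atom_indices] - restraints.references
        energy += float(np.sum(0.5 * restraints.k * np.sum(d * d, axis=1)))
        forces[restraints.atom_indices] -= restraints.k[:, None] * d

    return energy, forces


def minimize(
    coords: np.ndarray,
    ff: MiniForceField,
    restraints: RestraintSet | None = None,
    params: RelaxParams | None = None,
    pairs_scope: str = "intramolecular",
    box: np.ndarray | None = None,
) -> tuple[np.ndarray, MinimizerReport]:
    """Steepest descent with backtracking step control.

    A trial step displaces the worst atom by at most the current step size
    along the force direction; an energy increase rejects the step and
    shrinks it.  Accepted-step energies are monotone non-increasing by
    construction.  Stops at max |F| < f_tol, step collapse, or max_steps.
    """
    params = params or RelaxParams()
    x = np.array(coords, dtype=float)
    e, f = energy_forces(x, ff, restraints, pairs_scope, box)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at minimizer input")
    e0 = e
    h = params.em_step0
    h_max = 10.0 * params.em_step0
    steps = 0
    accepted = 0
    fmax = float(np.max(np.linalg.norm(f, axis=1))) if len(f) else 0.0
    converged = fmax < params.em_f_tol
    while steps < params.em_max_steps and not converged:
        steps += 1
        dx = f * (h / max(fmax, 1e-30))
        xt = x + dx
        et, ft = energy_forces(xt, ff, restraints, pairs_scope, box)
        if et < e:
            x, e, f = xt, et, ft
            accepted += 1
            h = min(h * 1.2, h_max)
            fmax = float(np.max(np.linalg.norm(f, axis=1)))
            if fmax < params.em_f_tol:
                converged = True
        else:
            h *= 0.2
            if h < 1e-9:
                break
    report = MinimizerReport(
        steps_taken=steps,
        accepted_steps=accepted,
        initial_energy=e0,
        final_energy=e,
        final_max_force=fmax,
        final_mapped_rmsd=restraints.mapped_rmsd(x) if restraints is not None else 0.0,
        converged=converged,
    )
    return x, report


def _stability_limit(coords: np.ndarray, ff: MiniForceField,
                     restraints: RestraintSet | None) -> float:
    """Effective stiffest spatial force constant (kJ/mol/nm^2).

    Bonds count twice (both atoms move); each angle maps to ~4 k_theta / r^2
    about its vertex with r the shorter arm, evaluated on the actual input
    geometry — the dominant stiffness for short bonds.
    """
    k_max = 0.0
    if len(ff.bond_kb):
        k_max = max(k_max, 2.0 * float(ff.bond_kb.max()))
    if len(ff.angle_kt):
        i, j, k = ff.angle_idx[:, 0], ff.angle_idx[:, 1], ff.angle_idx[:, 2]
        ru = np.linalg.norm(coords[i] - coords[j], axis=1)
        rv = np.linalg.norm(coords[k] - coords[j], axis=1)
        arm = np.maximum(np.minimum(ru, rv), 1e-3)
        k_max = max(k_max, float((4.0 * ff.angle_kt / (arm * arm)).max()))
    if restraints is not None and len(restraints):
        k_max = max(k_max, float(restraints.k.max()))
    k_max = max(k_max, 2.0 * ff.eps / (ff.rc * ff.rc))
    return k_max


def stochastic_relax(
    coords: np.ndarray,
    ff: MiniForceField,
    restraints: RestraintSet | None,
    params: RelaxParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    pairs_scope: str = "intramolecular",
    box: np.ndarray | None = None,
    sample_every: int | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Overdamped Langevin (Euler-Maruyama) dynamics under the restraints.

        x <- x + (F/gamma) dt + sqrt(2 kB T dt / gamma) xi

    Identical seed and inputs give a bit-identical trajectory.  At T = 0 the
    noise vanishes and the update reduces to damped minimization.  When
    ``sample_every`` is given, returns (final coords, sampled snapshots).
    """
    params = params or RelaxParams()
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    x = np.array(coords, dtype=float)
    a = _stability_limit(x, ff, restraints) * params.sd_dt / params.sd_gamma
    if a >= 2.0:
        raise ValueError(
            f"unstable integrator settings: k_max*dt/gamma = {a:.2f} >= 2; "
            f"reduce sd_dt or increase sd_gamma"
        )
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * KB * params.temperature * params.sd_dt / params.sd_gamma)
    mobility = params.sd_dt / params.sd_gamma
    samples = []
    for step in range(params.sd_steps):
        e, f = energy_forces(x, ff, restraints, pairs_scope, box)
        if not np.isfinite(e):
            raise ValueError("energy diverged during stochastic dynamics; reduce sd_dt")
        x = x + f * mobility
        if sigma > 0:
            x = x + sigma * rng.standard_normal(x.shape)
        if sample_every is not None and (step + 1) % sample_every == 0:
            samples.append(x.copy())
    if sample_every is not None:
        return x, np.array(samples)
    return x


def relax_molecule(
    instance,
    template,
    bead_map,
    cg,
    params: RelaxParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, dict]:
    """Align the template onto the CG molecule, then run the vacuum
    relaxation pipeline: minimize -> stochastic dynamics -> minimize, with
    intramolecular interactions only and mapped atoms restrained to beads.
    """
    from .superpose import align_template

    params = params or RelaxParams()
    aligned, fit_rmsd = align_template(instance, template, bead_map, cg)
    start, stop = instance.bead_slice
    beads = cg.positions()[start:stop]
    if cg.box is not None:
        ref = beads[0]
        delta = beads - ref
        delta -= cg.box * np.round(delta / cg.box)
        beads = ref + delta
    restraints = RestraintSet(
        atom_indices=bead_map.atom_indices(),
        references=beads[bead_map.bead_indices()],
        k=params.restraint_k,
    )
    ff = MiniForceField.from_template(template)
    x, rep1 = minimize(aligned, ff, restraints, params)
    x = stochastic_relax(x, ff, restraints, params, seed=seed)
    x, rep2 = minimize(x, ff, restraints, params)
    reports = {
        "fit_rmsd": fit_rmsd,
        "em1": rep1.as_dict(),
        "em2": rep2.as_dict(),
        "mapped_rmsd": restraints.mapped_rmsd(x),
    }
    return x, reports
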