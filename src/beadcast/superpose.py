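"""Rigid-body superposition of atomistic templates onto CG bead positions.

The fit minimizes the RMSD between the template's mapped atoms and the CG
beads over proper rotations and translations (Kabsch).  Reflections are
never returned: the determinant of the rotation is sign-corrected to +1,
which is the structural guarantee that template chirality survives the
alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import BeadAtomMap, MoleculeInstance, MoleculeTemplate
from .records import StructureRecord

__all__ = ["RigidTransform", "kabsch_fit", "align_template"]

_DEGENERATE_RTOL = 1e-9


@dataclass
class RigidTransform:
    """A proper rotation plus translation, x -> R x + t (nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is improper (det < 0)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _minimal_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smallest-angle proper rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 degrees about a deterministic perpendicular axis
        axis = np.zeros(3)
        axis[np.argmin(np.abs(u))] = 1.0
        axis -= u * np.dot(axis, u)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    w = w / s
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-RMSD proper rigid fit of ``mobile`` onto ``target`` (both N x 3, nm).

    For degenerate point sets (N <= 2, collinear, or coincident) the optimum
    is non-unique; the tie is broken deterministically by the minimal-angle
    rotation achieving it (identity for a single point).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape != target.shape:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n == 0:
        raise ValueError("cannot fit zero points")
    if not (np.isfinite(mobile).all() and np.isfinite(target).all()):
        raise ValueError("non-finite coordinates")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    A = mobile - mc
    B = target - tc
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)

    scale = max(S[0], 1e-300)
    if S[1] / scale < _DEGENERATE_RTOL or S[0] < 1e-12:
        if S[0] < 1e-12:
            # all points coincide with their centroid on at least one side
            R = np.eye(3)
        else:
            # collinear clouds: align the principal axis with minimal rotation.
            # H ~ s1 * u w^T, optimal R maps u onto w.
            u = U[:, 0]
            w = Vt[0, :]
            R = _minimal_rotation(u, w)
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        if d == 0:
            d = 1.0
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T

    t = tc - R @ mc
    tr = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mobile) - target) ** 2, axis=1))))
    return tr, rmsd


def align_template(
    instance: MoleculeInstance,
    template: MoleculeTemplate,
    bead_map: BeadAtomMap,
    cg: StructureRecord,
) -> tuple[np.ndarray, float]:
    """Place all template atoms by the rigid fit of mapped atoms onto beads.

    Bead positions are made whole under periodic boundaries (minimum image
    relative to the first bead) before fitting, so molecules split across
    the box edge align correctly.  Returns (positioned coordinates, fit
    RMSD in nm); internal template geometry is preserved exactly.
    """
    start, stop = instance.bead_slice
    beads = cg.positions()[start:stop]
    if cg.box is not None:
        ref = beads[0]
        delta = beads - ref
        delta -= cg.box * np.round(delta / cg.box)
        beads = ref + delta
    target = beads[bead_map.bead_indices()]
    mobile = template.positions()[bead_map.atom_indices()]
    tr, rmsd = kabsch_fit(mobile, target)
    return tr.apply(template.positions()), rmsd
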