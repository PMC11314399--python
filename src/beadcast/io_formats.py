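"""Readers and writers for the on-disk artifacts of the back-mapping pipeline.

Structure files (PDB, GRO) are read and written through MDAnalysis; positions
are converted to nm at this boundary (PDB Angstrom x 0.1).  The GROMACS
``.top`` ``[ molecules ]`` section, ``.itp`` ``[ bonds ]``/``[ angles ]``
sections (function type 1) and the plain-text residue-map dialect are parsed
by small dedicated parsers, since only those sections are consumed.

The residue-map dialect: a line ``[ RESNAME ]`` opens a residue block; each
following non-comment line is ``bead_ordinal  atom_serial``; ``;`` starts a
comment.  The amino-acid map uses the same layout with atom *names* as
targets (see :mod:`beadcast.mapping`).
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from .records import (
    PDB_TO_NM,
    AtomRecord,
    BondedTerms,
    FormatError,
    ResidueMap,
    StructureRecord,
    TopologyCounts,
)

__all__ = [
    "read_structure",
    "write_structure",
    "parse_top_molecules",
    "parse_bonded_itp",
    "parse_residue_map",
    "write_residue_map",
    "structures_equal",
]

_SERIAL_WRAP = 100_000  # both PDB and GRO serial fields are 5 characters wide


def _sniff_format(path: str | os.PathLike, format_hint: str = "auto") -> str:
    fmt = format_hint.lower()
    if fmt == "auto":
        ext = Path(path).suffix.lower().lstrip(".")
        if ext in ("pdb", "ent"):
            return "pdb"
        if ext == "gro":
            return "gro"
        raise FormatError(f"cannot infer structure format from {path!r}; pass format_hint")
    if fmt not in ("pdb", "gro"):
        raise FormatError(f"unknown structure format {format_hint!r}")
    return fmt


def _count_atoms_quick(path: str | os.PathLike, fmt: str) -> int:
    """Cheap atom count so zero-atom files bypass MDAnalysis (which needs >= 1)."""
    with open(path) as fh:
        if fmt == "gro":
            fh.readline()
            line = fh.readline()
            try:
                return int(line.split()[0]) if line.split() else 0
            except ValueError as exc:
                raise FormatError(f"{path}: malformed GRO atom-count line 2: {line!r}") from exc
        n = 0
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                n += 1
        return n


def _read_empty(path, fmt) -> StructureRecord:
    box = None
    title = ""
    with open(path) as fh:
        lines = fh.readlines()
    if fmt == "gro":
        title = lines[0].rstrip("\n") if lines else ""
        if len(lines) >= 3:
            vals = [float(v) for v in lines[2].split()[:3]]
            if all(v > 0 for v in vals):
                box = np.array(vals)
    else:
        for line in lines:
            if line.startswith("CRYST1"):
                vals = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                if all(v > 1.001 for v in vals):
                    box = np.array(vals) * PDB_TO_NM
            elif line.startswith("TITLE"):
                title = line[10:].rstrip()
    return StructureRecord(atoms=[], box=box, title=title)


def read_structure(path: str | os.PathLike, format_hint: str = "auto") -> StructureRecord:
    """Read a PDB or GRO structure into a :class:`StructureRecord` (nm).

    Atom order is preserved exactly; the box is taken from CRYST1 / the GRO
    box line when present.  Only orthorhombic boxes are supported; a
    triclinic cell raises :class:`FormatError`.
    """
    fmt = _sniff_format(path, format_hint)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _count_atoms_quick(path, fmt) == 0:
        return _read_empty(path, fmt)

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(os.fspath(path), format=fmt, to_guess=())
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc

    box = None
    dims = u.dimensions
    if dims is not None and np.any(dims[:3] > 0):
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise FormatError(f"{path}: triclinic box not supported (angles {dims[3:]})")
        # MDAnalysis reports dimensions in Angstrom for both formats.
        box = np.asarray(dims[:3], dtype=float) * PDB_TO_NM

    ag = u.atoms
    names = ag.names
    resnames = ag.resnames
    resids = ag.resids
    serials = ag.ids
    chains = ag.chainIDs if hasattr(ag, "chainIDs") else [""] * len(ag)
    pos = ag.positions * PDB_TO_NM  # MDAnalysis always stores Angstrom
    if not np.isfinite(pos).all():
        raise FormatError(f"{path}: non-finite coordinates")
    atoms = [
        AtomRecord(
            serial=int(serials[i]),
            name=str(names[i]),
            residue_name=str(resnames[i]),
            residue_seq=int(resids[i]),
            chain=str(chains[i]).strip(),
            position=pos[i],
        )
        for i in range(len(ag))
    ]
    title = ""
    return StructureRecord(atoms=atoms, box=box, title=title)


def write_structure(s: StructureRecord, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a structure as PDB (Angstrom, 3 decimals) or GRO (nm, 3 decimals).

    Atom serials are renumbered sequentially; past 99,999 they wrap into the
    5-character field (last five digits), the overflow-safe convention both
    formats tolerate.  Blank chain identifiers come back as ``X`` from the
    PDB writer.
    """
    fmt = _sniff_format(path, format)
    if s.n_atoms == 0:
        with open(path, "w") as fh:
            if fmt == "gro":
                fh.write((s.title or "generated by beadcast") + "\n    0\n")
                b = s.box if s.box is not None else np.zeros(3)
                fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")
            else:
                if s.box is not None:
                    b = s.box / PDB_TO_NM
                    fh.write(
                        f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
                    )
                fh.write("END\n")
        return

    import MDAnalysis as mda

    n = s.n_atoms
    # residue grouping: consecutive atoms sharing (resname, resseq, chain)
    resindex = np.empty(n, dtype=int)
    resnames, resids, chain_per_res = [], [], []
    prev_key = None
    ri = -1
    for i, a in enumerate(s.atoms):
        key = (a.residue_name, a.residue_seq, a.chain)
        if key != prev_key:
            ri += 1
            resnames.append(a.residue_name)
            resids.append(a.residue_seq)
            chain_per_res.append(a.chain if a.chain else "X")
            prev_key = key
        resindex[i] = ri

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=ri + 1, atom_resindex=resindex, trajectory=True)
        u.add_TopologyAttr("names", [a.name for a in s.atoms])
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        # sequential serials; the writers themselves wrap >5-digit values
        u.add_TopologyAttr("ids", list(range(1, n + 1)))
        if fmt == "pdb":
            chains = [s.atoms[i].chain if s.atoms[i].chain else "X" for i in range(n)]
            u.add_TopologyAttr("chainIDs", chains)
            u.add_TopologyAttr("elements", [a.element for a in s.atoms])
        pos = s.positions()
        if not np.isfinite(pos).all():
            raise ValueError("non-finite coordinates")
        u.atoms.positions = pos / PDB_TO_NM  # MDAnalysis stores Angstrom
        if s.box is not None:
            u.dimensions = [*(s.box / PDB_TO_NM), 90.0, 90.0, 90.0]
        u.atoms.write(os.fspath(path))


def structures_equal(a: StructureRecord, b: StructureRecord, tol: float = 1.5e-4) -> bool:
    """Round-trip equality: same atoms/residues/positions within format precision.

    Serials are compared modulo the 5-digit field wrap; blank chains compare
    equal to the PDB writer's ``X`` placeholder; GRO files carry no chains.
    """
    if a.n_atoms != b.n_atoms:
        return False
    if (a.box is None) != (b.box is None):
        return False
    if a.box is not None and not np.allclose(a.box, b.box, atol=tol):
        return False

    def norm_chain(c):
        return "X" if c in ("", " ") else c

    for x, y in zip(a.atoms, b.atoms):
        if x.name != y.name or x.residue_name != y.residue_name:
            return False
        if x.residue_seq != y.residue_seq:
            return False
        if (x.serial % _SERIAL_WRAP) != (y.serial % _SERIAL_WRAP):
            return False
        if norm_chain(x.chain) != norm_chain(y.chain) and x.chain and y.chain:
            return False
        if not np.allclose(x.position, y.position, atol=tol):
            return False
    return True


def _iter_content_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            yield lineno, line


def parse_top_molecules(path: str | os.PathLike) -> TopologyCounts:
    """Parse the ``[ molecules ]`` section of a GROMACS ``.top`` file.

    ``#include`` and preprocessor lines are ignored; duplicate consecutive
    names are kept as separate entries (GROMACS semantics).
    """
    entries: list[tuple[str, int]] = []
    in_section = False
    found = False
    for lineno, line in _iter_content_lines(path):
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            in_section = section == "molecules"
            found = found or in_section
            continue
        if not in_section:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'name count', got {line!r}")
        name, count_s = parts
        try:
            count = int(count_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer molecule count {count_s!r}") from exc
        if count < 1:
            raise FormatError(f"{path}:{lineno}: molecule count must be >= 1, got {count}")
        entries.append((name, count))
    if not found:
        raise FormatError(f"{path}: no [ molecules ] section")
    return TopologyCounts(entries=entries)


def parse_bonded_itp(path: str | os.PathLike) -> BondedTerms:
    """Parse ``[ bonds ]`` and ``[ angles ]`` sections (function type 1).

    Parameter columns may be omitted; equilibria are then measured from the
    template geometry by the force-field builder.
    """
    bonds: list[tuple[int, int, float | None, float | None]] = []
    angles: list[tuple[int, int, int, float | None, float | None]] = []
    section = None
    seen = False
    for lineno, line in _iter_content_lines(path):
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            seen = seen or section in ("bonds", "angles")
            continue
        parts = line.split()
        try:
            if section == "bonds":
                i, j = int(parts[0]), int(parts[1])
                funct = int(parts[2]) if len(parts) > 2 else 1
                if funct != 1:
                    continue
                b0 = float(parts[3]) if len(parts) > 3 else None
                kb = float(parts[4]) if len(parts) > 4 else None
                bonds.append((i, j, b0, kb))
            elif section == "angles":
                i, j, k = int(parts[0]), int(parts[1]), int(parts[2])
                funct = int(parts[3]) if len(parts) > 3 else 1
                if funct != 1:
                    continue
                t0 = float(parts[4]) if len(parts) > 4 else None
                kt = float(parts[5]) if len(parts) > 5 else None
                angles.append((i, j, k, t0, kt))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed {section} line {line!r}") from exc
    if not seen:
        raise FormatError(f"{path}: no [ bonds ] / [ angles ] sections")
    return BondedTerms(bonds=bonds, angles=angles)


def parse_residue_map(path: str | os.PathLike) -> ResidueMap:
    """Parse the residue-map dialect (bead ordinal -> mapped atom serial)."""
    rmap = ResidueMap()
    current: str | None = None
    pending: list[tuple[int, int]] = []

    def flush():
        if current is not None:
            rmap.add(current, pending)

    for lineno, line in _iter_content_lines(path):
        if not line:
            continue
        if line.startswith("["):
            flush()
            current = line.strip("[] \t")
            if not current:
                raise FormatError(f"{path}:{lineno}: empty residue name")
            pending = []
            continue
        parts = line.split()
        if current is None:
            raise FormatError(f"{path}:{lineno}: mapping line before any [ residue ] header")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'bead atom', got {line!r}")
        try:
            bead, atom = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer entry {line!r}") from exc
        pending.append((bead, atom))
    flush()
    if not rmap.entries:
        raise FormatError(f"{path}: no residue entries")
    return rmap


def write_residue_map(rmap: ResidueMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("; residue map: bead ordinal -> mapped atom serial\n")
        for name, pairs in rmap.entries.items():
            fh.write(f"[ {name} ]\n")
            for bead, atom in pairs:
                fh.write(f"{bead:4d} {atom:6d}\n")
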