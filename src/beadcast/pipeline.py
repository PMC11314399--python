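"""End-to-end orchestration of the five back-mapping stages.

partition -> per-molecule (align, restrained relax) -> assemble -> resolvate
-> system relax -> audits -> write.  The per-molecule stage is
embarrassingly parallel; every molecule gets a deterministic seed derived
from the run seed and its index, so the output is bit-identical for any
worker count.
"""

from __future__ import annotations

import dataclasses
import json
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assemble import (
    AASystem,
    MoleculeEntry,
    SystemRelaxParams,
    assemble,
    build_system_restraints,
    check_chirality,
    check_clashes,
    system_relax,
)
from .io_formats import parse_residue_map, parse_top_molecules, read_structure, write_structure
from .mapping import (
    DEFAULT_ION_NAMES,
    DEFAULT_WATER_NAMES,
    AminoAcidMap,
    MappingError,
    build_molecule_map,
    load_template,
    partition_cg_system,
)
from .relax import RelaxParams, relax_molecule
from .solvate import DEFAULT_ION_TABLE, backmap_ions, backmap_waters

__all__ = ["PipelineConfig", "PipelineError", "AuditError", "run", "export_engine_inputs"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and molecule."""


class AuditError(RuntimeError):
    """A structure audit (chirality) failed under the 'fail' policy."""


@dataclass
class PipelineConfig:
    cg_structure: str
    cg_topology: str
    residue_map: str
    template_dir: str
    amino_map: str | None = None
    output_dir: str = "out"
    output_format: str = "gro"
    seed: int = 0
    workers: int = 1
    relax: RelaxParams = field(default_factory=RelaxParams)
    system: SystemRelaxParams = field(default_factory=SystemRelaxParams)
    water_names: frozenset = DEFAULT_WATER_NAMES
    ion_names: frozenset = DEFAULT_ION_NAMES
    chirality_policy: str = "fail"  # or "warn"
    clash_cutoff: float = 0.08
    export_engine_files: bool = False

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        """Build a config from a YAML file; keyword overrides win.

        Top-level keys mirror the dataclass fields; ``relax`` and ``system``
        may be nested mappings of their parameter names.
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        relax_kw = data.pop("relax", {}) or {}
        system_kw = data.pop("system", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"{path}: unknown config keys {sorted(unknown)}")
        config = cls(**data)
        for key, value in relax_kw.items():
            if not hasattr(config.relax, key):
                raise PipelineError(f"{path}: unknown relax parameter {key!r}")
            setattr(config.relax, key, value)
        for key, value in system_kw.items():
            if not hasattr(config.system, key):
                raise PipelineError(f"{path}: unknown system parameter {key!r}")
            setattr(config.system, key, value)
        return config

    def validate(self) -> None:
        for label, path in (
            ("CG structure", self.cg_structure),
            ("CG topology", self.cg_topology),
            ("residue map", self.residue_map),
            ("template directory", self.template_dir),
        ):
            if not os.path.exists(path):
                raise PipelineError(f"{label} not found: {path}")
        if self.amino_map and not os.path.exists(self.amino_map):
            raise PipelineError(f"amino-acid map not found: {self.amino_map}")
        if self.workers < 1:
            raise PipelineError("workers must be >= 1")
        if self.chirality_policy not in ("fail", "warn"):
            raise PipelineError("chirality_policy must be 'fail' or 'warn'")


def _molecule_seed(seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(index,))


def _process_one(args):
    """Worker: align + vacuum-relax one molecule (picklable free function)."""
    instance, template, bead_map, cg, params, seed, index = args
    coords, reports = relax_molecule(instance, template, bead_map, cg,
                                     params=params, seed=_molecule_seed(seed, index))
    return index, coords, reports


def run(config: PipelineConfig) -> AASystem:
    """Execute the full back-mapping protocol; returns the audited system.

    Writes ``aa_system.<fmt>`` and ``run_log.json`` (plus optional engine
    input files) under ``config.output_dir``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        cg = read_structure(config.cg_structure)
        top = parse_top_molecules(config.cg_topology)
        rmap = parse_residue_map(config.residue_map)
        amino = AminoAcidMap.from_file(config.amino_map) if config.amino_map \
            else AminoAcidMap.default()
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    try:
        part = partition_cg_system(cg, top, rmap, amino,
                                   water_names=config.water_names,
                                   ion_names=config.ion_names)
    except MappingError as exc:
        raise PipelineError(f"partition stage: {exc}") from exc

    # templates, one per distinct molecule name
    templates = {}
    for inst in part.instances:
        if inst.molecule_name not in templates:
            try:
                templates[inst.molecule_name] = load_template(config.template_dir,
                                                              inst.molecule_name)
            except MappingError as exc:
                raise PipelineError(f"template stage: {exc}") from exc

    jobs = []
    for i, inst in enumerate(part.instances):
        tmpl = templates[inst.molecule_name]
        try:
            bmap = build_molecule_map(inst, rmap, amino, tmpl)
        except MappingError as exc:
            raise PipelineError(f"mapping stage, molecule {i} ({inst.molecule_name}): {exc}") from exc
        jobs.append((inst, tmpl, bmap, cg, config.relax, config.seed, i))

    results: list = [None] * len(jobs)
    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            for index, coords, reports in pool.map(_process_one, jobs,
                                                   chunksize=max(1, len(jobs) // (4 * config.workers))):
                results[index] = (coords, reports)
    else:
        for job in jobs:
            index, coords, reports = _process_one(job)
            results[index] = (coords, reports)

    entries = []
    mol_logs = []
    cg_pos = cg.positions()
    for (inst, tmpl, bmap, _cg, _p, _s, i), (coords, reports) in zip(jobs, results):
        start, stop = inst.bead_slice
        beads = cg_pos[start:stop]
        if cg.box is not None:
            ref = beads[0]
            delta = beads - ref
            delta -= cg.box * np.round(delta / cg.box)
            beads = ref + delta
        entries.append(MoleculeEntry(
            name=inst.molecule_name, instance=inst, template=tmpl, coords=coords,
            mapped_atom_indices=bmap.atom_indices(),
            bead_references=beads[bmap.bead_indices()],
        ))
        mol_logs.append({"index": i, "name": inst.molecule_name, **reports})

    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(2 ** 20,))
    seed_w, seed_i, seed_sys = ss.spawn(3)
    try:
        waters = backmap_waters(cg_pos[part.water_bead_indices], seed=seed_w)
        ion_beads = [(name, cg_pos[idx]) for name, idx in part.ion_beads]
        ions, shell = backmap_ions(ion_beads, seed=seed_i, ion_table=DEFAULT_ION_TABLE)
    except Exception as exc:
        raise PipelineError(f"solvation stage: {exc}") from exc

    # one water block: bead waters then ion-shell waters; ions last
    waters.positions = np.concatenate([waters.positions, shell.positions], axis=0)
    waters.names += shell.names
    waters.resnames += shell.resnames
    waters.mol_sizes += shell.mol_sizes

    sys0 = assemble(entries, waters, ions, cg.box)

    mapped = []
    mol_provs = sys0.entries_of_kind("molecule")
    for prov, entry in zip(mol_provs, entries):
        mapped.append((prov.span[0] + entry.mapped_atom_indices, entry.bead_references))
    restraints = build_system_restraints(sys0, config.system, mapped)
    relaxed, sys_report = system_relax(sys0, restraints, config.system, seed=seed_sys)

    chir = check_chirality(relaxed)
    clashes = check_clashes(relaxed, cutoff=config.clash_cutoff)
    relaxed.audit = {
        "chirality": chir.as_dict(),
        "n_clashes": len(clashes),
        "clash_cutoff_nm": config.clash_cutoff,
    }

    out_structure = outdir / f"aa_system.{config.output_format}"
    write_structure(relaxed.structure, out_structure, config.output_format)

    log = {
        "seed": config.seed,
        "workers": config.workers,
        "n_molecules": len(entries),
        "n_water_beads": len(part.water_bead_indices),
        "n_ion_beads": len(part.ion_beads),
        "n_atoms": relaxed.n_atoms,
        "molecules": mol_logs,
        "system_relax": sys_report,
        "audit": relaxed.audit,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)

    if config.export_engine_files:
        export_engine_inputs(relaxed, entries, outdir)

    if not chir.all_ok:
        msg = (f"chirality audit failed: {chir.n_flipped}/{chir.n_checked} "
               f"stereocenters flipped (see run_log.json)")
        if config.chirality_policy == "fail":
            raise AuditError(msg)
        import warnings

        warnings.warn(msg)
    return relaxed


def export_engine_inputs(sys: AASystem, entries: list[MoleculeEntry], outdir) -> list[str]:
    """Write external-engine inputs: AA structure (GRO), an assembled .top
    [ molecules ] section, and per-molecule [ position_restraints ] stanzas
    (function type 1, the restraint constant in all three dimensions) so the
    engine-based restrained relaxation can be reproduced outside the tool."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    gro = outdir / "aa_system_engine.gro"
    write_structure(sys.structure, gro, "gro")
    written.append(str(gro))

    # block-run [ molecules ] in output order
    runs: list[tuple[str, int]] = []
    for p in sys.provenance:
        name = p.name if p.kind == "molecule" else ("SOL" if p.kind == "water" else p.name)
        if runs and runs[-1][0] == name:
            runs[-1] = (name, runs[-1][1] + 1)
        else:
            runs.append((name, 1))
    top = outdir / "aa_system.top"
    with open(top, "w") as fh:
        fh.write("; assembled back-mapped system\n")
        for name in sorted({e.name for e in entries}):
            fh.write(f'#include "posre_{name}.itp"\n')
        fh.write("\n[ system ]\nback-mapped atomistic system\n\n[ molecules ]\n")
        for name, count in runs:
            fh.write(f"{name:10s} {count:8d}\n")
    written.append(str(top))

    by_name: dict[str, MoleculeEntry] = {}
    for e in entries:
        by_name.setdefault(e.name, e)
    for name, entry in sorted(by_name.items()):
        path = outdir / f"posre_{name}.itp"
        with open(path, "w") as fh:
            fh.write(f"; position restraints for mapped atoms of {name}\n")
            fh.write("[ position_restraints ]\n;  atom  funct  kx  ky  kz\n")
            for idx in entry.mapped_atom_indices:
                fh.write(f"{int(idx) + 1:6d}   1   10000 10000 10000\n")
        written.append(str(path))
    return written
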