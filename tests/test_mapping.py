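import numpy as np
import pytest

from beadcast.fixtures import (
    benzyl_alcohol_residue_map,
    gen_bilayer,
    toy_peptide_template,
    toy_residue_map,
    write_template_files,
)
from beadcast.mapping import (
    AminoAcidMap,
    MappingError,
    MoleculeTemplate,
    build_molecule_map,
    load_template,
    partition_cg_system,
)
from beadcast.records import AtomRecord, BondedTerms, ResidueMap, StructureRecord, TopologyCounts


def _chain_template(name, n, resname=None, spacing=0.15):
    atoms = [
        AtomRecord(i + 1, f"C{i + 1}", resname or name, 1,
                   position=[i * spacing, 0.0, 0.0])
        for i in range(n)
    ]
    bonds = [(i, i + 1, spacing, 5000.0) for i in range(1, n)]
    return MoleculeTemplate(name=name, atoms=atoms, bonded=BondedTerms(bonds=bonds))


def _cg(atoms, box=None):
    return StructureRecord(atoms=atoms, box=box)


def _beads(name, n, start_serial=1, resseq=1, chain=""):
    return [
        AtomRecord(start_serial + i, f"B{i + 1}", name, resseq, chain=chain,
                   position=np.random.default_rng(start_serial + i).uniform(0, 3, 3))
        for i in range(n)
    ]


class TestPartition:
    def test_two_molecules_plus_waters(self):
        rmap = ResidueMap()
        rmap.add("TOY", [(1, 1), (2, 2), (3, 3)])
        atoms = _beads("TOY", 3) + _beads("TOY", 3, 4, 2) + [
            AtomRecord(7 + i, "W", "W", 3 + i, position=[i, 0, 0]) for i in range(8)
        ]
        top = TopologyCounts([("TOY", 2), ("W", 8)])
        part = partition_cg_system(_cg(atoms), top, rmap)
        assert len(part.instances) == 2
        assert [i.bead_slice for i in part.instances] == [(0, 3), (3, 6)]
        assert part.water_bead_indices == list(range(6, 14))
        assert part.ion_beads == []

    def test_bead_count_mismatch_names_first_bad_block(self):
        rmap = ResidueMap()
        rmap.add("TOY", [(1, 1), (2, 2), (3, 3)])
        atoms = _beads("TOY", 3) + _beads("TOY", 3, 4, 2)
        top = TopologyCounts([("TOY", 3)])
        with pytest.raises(MappingError, match="TOY"):
            partition_cg_system(_cg(atoms), top, rmap)

    def test_unknown_residue_named_in_error(self):
        rmap = ResidueMap()
        rmap.add("TOY", [(1, 1)])
        atoms = [AtomRecord(1, "B1", "XXX", 1, position=[0, 0, 0])]
        with pytest.raises(MappingError, match="XXX"):
            partition_cg_system(_cg(atoms), TopologyCounts([("XXX", 1)]), rmap)

    def test_protein_then_lipids_partition(self):
        rmap = ResidueMap()
        rmap.add("TOY", [(1, 1), (2, 2), (3, 3)])
        amino = AminoAcidMap.default()
        # 5-residue protein: ALA CYS ALA ALA CYS -> 1+2+1+1+2 = 7 beads, chain A
        seq = ["ALA", "CYS", "ALA", "ALA", "CYS"]
        atoms = []
        serial = 0
        for ri, res in enumerate(seq, 1):
            for b in range(len(amino[res])):
                serial += 1
                atoms.append(AtomRecord(serial, f"B{b + 1}", res, ri, chain="A",
                                        position=[0.3 * serial, 0, 0]))
        for m in range(64):
            for b in range(3):
                serial += 1
                atoms.append(AtomRecord(serial, f"B{b + 1}", "TOY", 100 + m,
                                        position=[0.3 * serial, 1, 0]))
        top = TopologyCounts([("Protein", 1), ("TOY", 64)])
        part = partition_cg_system(_cg(atoms), top, rmap, amino)
        assert len(part.instances) == 65
        prot = part.instances[0]
        assert prot.is_protein and prot.n_beads == 7
        assert [r[0] for r in prot.residue_breakdown] == seq
        assert all(not i.is_protein and i.n_beads == 3 for i in part.instances[1:])

    def test_every_nonsolvent_bead_claimed_exactly_once(self, toy_template):
        cg, top = gen_bilayer(2, 2, seed=3, template=toy_template)
        part = partition_cg_system(cg, top, toy_residue_map(toy_template))
        claimed = []
        for inst in part.instances:
            claimed.extend(range(*inst.bead_slice))
        claimed += part.water_bead_indices + [i for _, i in part.ion_beads]
        assert sorted(claimed) == list(range(cg.n_atoms))
        assert len(set(claimed)) == cg.n_atoms


class TestBuildMap:
    def test_aromatic_alcohol_serials_to_zero_based_indices(self):
        rmap = benzyl_alcohol_residue_map()
        template = _chain_template("BZA", 8)
        atoms = _beads("BZA", 3)
        part = partition_cg_system(_cg(atoms), TopologyCounts([("BZA", 1)]), rmap)
        bmap = build_molecule_map(part.instances[0], rmap, None, template)
        assert bmap.pairs == [(0, 6), (1, 4), (2, 1)]

    def test_one_bead_one_atom_ion(self):
        rmap = ResidueMap()
        rmap.add("ION", [(1, 1)])
        template = MoleculeTemplate(
            name="ION",
            atoms=[AtomRecord(1, "NA", "ION", 1, position=[0, 0, 0])],
            bonded=BondedTerms(),
        )
        atoms = [AtomRecord(1, "B1", "ION", 1, position=[1, 2, 3])]
        part = partition_cg_system(_cg(atoms), TopologyCounts([("ION", 1)]), rmap,
                                   ion_names=frozenset())
        bmap = build_molecule_map(part.instances[0], rmap, None, template)
        assert bmap.pairs == [(0, 0)]

    def test_peptide_atom_indices_stay_within_residue_spans(self):
        template = toy_peptide_template(("ALA", "CYS", "ALA"))
        amino = AminoAcidMap.default()
        rmap = ResidueMap()
        atoms = []
        serial = 0
        for ri, res in enumerate(("ALA", "CYS", "ALA"), 1):
            for b in range(len(amino[res])):
                serial += 1
                atoms.append(AtomRecord(serial, f"B{b + 1}", res, ri, chain="A",
                                        position=[0.3 * ri + 0.1 * b, 0, 0]))
        part = partition_cg_system(_cg(atoms), TopologyCounts([("TPEP", 1)]), rmap, amino)
        bmap = build_molecule_map(part.instances[0], rmap, amino, template)
        assert bmap.n_beads == 4
        spans = template.residue_spans()
        for (bead, atom), (_, _, stop) in zip(bmap.pairs[:1] + bmap.pairs[1:3] + bmap.pairs[3:],
                                              [spans[0]] * 1 + [spans[1]] * 2 + [spans[2]] * 1):
            assert atom < stop
        # the CYS SG bead maps inside the CYS span
        cys_span = spans[1]
        assert cys_span[1] <= bmap.pairs[2][1] < cys_span[2]

    def test_missing_atom_name_names_residue_and_atom(self):
        template = toy_peptide_template(("ALA", "ALA"))  # no SG anywhere
        amino = AminoAcidMap.default()
        atoms = []
        serial = 0
        for ri, res in enumerate(("ALA", "CYS"), 1):
            for b in range(len(amino[res])):
                serial += 1
                atoms.append(AtomRecord(serial, f"B{b + 1}", res, ri, chain="A",
                                        position=[0.3 * serial, 0, 0]))
        part = partition_cg_system(_cg(atoms), TopologyCounts([("TPEP", 1)]), None or
                                   ResidueMap(), amino)
        with pytest.raises(MappingError, match="CYS"):
            build_molecule_map(part.instances[0], ResidueMap(), amino, template)

    def test_duplicate_atom_target_rejected(self):
        rmap = ResidueMap()
        with pytest.raises(Exception):
            rmap.add("DUP", [(1, 3), (2, 3)])


class TestExtensibility:
    def test_novel_residue_needs_only_template_itp_and_map_entry(self, tmp_path):
        """Registering a new molecule type touches no core code paths."""
        template = _chain_template("NEWM", 4)
        write_template_files(template, tmp_path)
        loaded = load_template(tmp_path, "NEWM")
        assert loaded.n_atoms == 4
        rmap = ResidueMap()
        rmap.add("NEWM", [(1, 1), (2, 4)])
        atoms = _beads("NEWM", 2)
        part = partition_cg_system(_cg(atoms), TopologyCounts([("NEWM", 1)]), rmap)
        bmap = build_molecule_map(part.instances[0], rmap, None, loaded)
        assert bmap.pairs == [(0, 0), (1, 3)]

    def test_amino_map_override_requires_flag(self):
        amino = AminoAcidMap.default()
        with pytest.raises(MappingError, match="override"):
            amino.add_residue("ALA", [(1, "CB")])
        amino.add_residue("ALA", [(1, "CB")], override=True)
        assert amino["ALA"] == [(1, "CB")]
        amino.add_residue("NST", [(1, "CA"), (2, "ZZ1")])  # nonstandard residue
        assert "NST" in amino
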