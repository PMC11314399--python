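import numpy as np

from beadcast.assemble import (
    MoleculeEntry,
    SystemRelaxParams,
    assemble,
    build_system_restraints,
    check_chirality,
    check_clashes,
    system_relax,
)
from beadcast.fixtures import oracle_all_pairs_clashes, toy_residue_map
from beadcast.mapping import MoleculeInstance
from beadcast.solvate import SolventAtoms, backmap_waters


def _entry(template, coords, index=0, name=None):
    serial_to_idx = {a.serial: i for i, a in enumerate(template.atoms)}
    rmap = toy_residue_map(template)
    mapped_idx = np.array([serial_to_idx[s] for _, s in rmap[template.name]])
    return MoleculeEntry(
        name=name or template.name,
        instance=MoleculeInstance(template.name, (0, 3)),
        template=template,
        coords=coords,
        mapped_atom_indices=mapped_idx,
        bead_references=coords[mapped_idx],
    )


def _empty_solvent():
    return SolventAtoms()


class TestAssemble:
    def test_atom_count_and_order(self, toy_template, rng):
        box = np.array([5.0, 5.0, 5.0])
        entries = [
            _entry(toy_template, toy_template.positions() + [1.0, 1.0, 1.0], 0),
            _entry(toy_template, toy_template.positions() + [3.0, 3.0, 3.0], 1),
        ]
        waters = backmap_waters(rng.uniform(0.5, 4.5, (8, 3)), seed=0)
        sys_ = assemble(entries, waters, _empty_solvent(), box)
        assert sys_.n_atoms == 2 * toy_template.n_atoms + 96
        kinds = [p.kind for p in sys_.provenance]
        assert kinds == ["molecule"] * 2 + ["water"] * 32
        # spans partition the atom list
        spans = [p.span for p in sys_.provenance]
        assert spans[0][0] == 0 and spans[-1][1] == sys_.n_atoms
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
        assert np.allclose(sys_.structure.box, box)

    def test_centroid_wrap_keeps_molecules_whole(self, toy_template):
        box = np.array([4.0, 4.0, 4.0])
        coords = toy_template.positions() + [5.5, -1.2, 2.0]  # centroid outside box
        sys_ = assemble([_entry(toy_template, coords)], _empty_solvent(),
                        _empty_solvent(), box)
        out = sys_.structure.positions()
        centroid = out.mean(axis=0)
        assert (centroid >= 0).all() and (centroid < box).all()
        d_in = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.abs(d_in - d_out).max() < 1e-12


class TestChirality:
    def test_untouched_template_passes(self, toy_template):
        sys_ = assemble([_entry(toy_template, toy_template.positions())],
                        _empty_solvent(), _empty_solvent(), None)
        report = check_chirality(sys_)
        assert report.n_checked == 1
        assert report.all_ok

    def test_mirrored_coordinates_flip_every_center(self, toy_template):
        mirrored = toy_template.positions() * np.array([1.0, 1.0, -1.0])
        sys_ = assemble([_entry(toy_template, mirrored)],
                        _empty_solvent(), _empty_solvent(), None)
        report = check_chirality(sys_)
        assert report.n_checked == 1
        assert report.n_flipped == 1
        assert not report.all_ok


class TestClashes:
    def test_clash_free_system_reports_nothing(self, toy_template):
        entries = [
            _entry(toy_template, toy_template.positions()),
            _entry(toy_template, toy_template.positions() + [2.0, 0.0, 0.0], 1),
        ]
        sys_ = assemble(entries, _empty_solvent(), _empty_solvent(),
                        np.array([6.0, 6.0, 6.0]))
        assert check_clashes(sys_) == []

    def test_hand_built_overlap_reported(self, toy_template):
        entries = [
            _entry(toy_template, toy_template.positions()),
            _entry(toy_template, toy_template.positions() + [0.03, 0.0, 0.0], 1),
        ]
        sys_ = assemble(entries, _empty_solvent(), _empty_solvent(),
                        np.array([6.0, 6.0, 6.0]))
        clashes = check_clashes(sys_, cutoff=0.05)
        assert len(clashes) >= 1
        assert any({i % toy_template.n_atoms, j % toy_template.n_atoms} == {0}
                   for i, j, _ in clashes)

    def test_cell_list_matches_brute_force(self, rng):
        """Periodic KD-tree search reproduces the O(N^2) minimum-image oracle."""
        from beadcast.records import AtomRecord, StructureRecord
        from beadcast.assemble import AASystem

        box = np.array([2.0, 2.0, 2.0])
        n = 500
        pos = rng.uniform(0, 2, (n, 3))
        atoms = [AtomRecord(i + 1, "C", "X", i + 1, position=pos[i]) for i in range(n)]
        sys_ = AASystem(
            structure=StructureRecord(atoms=atoms, box=box),
            provenance=[],
            molecule_of=np.arange(n),
        )
        for cutoff in (0.08, 0.2):
            fast = check_clashes(sys_, cutoff=cutoff)
            slow = oracle_all_pairs_clashes(sys_, cutoff=cutoff)
            assert [(i, j) for i, j, _ in fast] == [(i, j) for i, j, _ in slow]
            assert len(fast) > 0  # the comparison is non-vacuous at this density


class TestSystemRelax:
    def test_overlapping_waters_pushed_apart(self):
        waters = backmap_waters(np.array([[1.0, 1.0, 1.0]]), seed=0)
        # duplicate the cluster almost on top of itself: severe O-O overlap
        shifted = backmap_waters(np.array([[1.02, 1.0, 1.0]]), seed=5)
        waters.positions = np.concatenate([waters.positions, shifted.positions])
        waters.names += shifted.names
        waters.resnames += shifted.resnames
        waters.mol_sizes += shifted.mol_sizes
        box = np.array([3.0, 3.0, 3.0])
        sys_ = assemble([], waters, _empty_solvent(), box)
        params = SystemRelaxParams(solvent_restraint_k=100.0, sd_steps=0,
                                   em_max_steps=500, em_f_tol=5.0)
        restraints = build_system_restraints(sys_, params, [])
        relaxed, _ = system_relax(sys_, restraints, params, seed=0)
        pos = relaxed.structure.positions()
        oxygens = pos[::3]
        from scipy.spatial.distance import pdist

        assert pdist(oxygens).min() > 0.15

    def test_clash_free_system_is_near_noop(self, toy_template):
        entries = [_entry(toy_template, toy_template.positions() + [1.0, 1.0, 1.0])]
        box = np.array([4.0, 4.0, 4.0])
        sys_ = assemble(entries, _empty_solvent(), _empty_solvent(), box)
        params = SystemRelaxParams(sd_steps=0)
        restraints = build_system_restraints(
            sys_, params, [(entries[0].mapped_atom_indices, entries[0].bead_references)]
        )
        relaxed, report = system_relax(sys_, restraints, params, seed=0)
        e0 = report["em1"]["initial_energy"]
        e1 = report["em1"]["final_energy"]
        assert e1 <= e0
        assert abs(e0 - e1) <= 0.01 * max(abs(e0), 1.0)

    def test_box_conserved_exactly(self, toy_template, rng):
        box = np.array([4.0, 4.0, 4.0])
        entries = [_entry(toy_template, toy_template.positions() + [1.0, 1.0, 1.0])]
        waters = backmap_waters(rng.uniform(0.5, 3.5, (5, 3)), seed=1)
        sys_ = assemble(entries, waters, _empty_solvent(), box)
        params = SystemRelaxParams(sd_steps=20)
        restraints = build_system_restraints(
            sys_, params, [(entries[0].mapped_atom_indices, entries[0].bead_references)]
        )
        relaxed, _ = system_relax(sys_, restraints, params, seed=3)
        assert np.array_equal(relaxed.structure.box, box)
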