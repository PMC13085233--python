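"""Structure reading, residue fragmentation, caps, and subsystem geometry."""

import io

import numpy as np
import pytest

from mbescreen.errors import FragmentationError, InputError
from mbescreen.fixtures import write_fixture_pdb
from mbescreen.graph import SubsystemKey
from mbescreen.structure import (
    AtomRecord,
    FragmentationConfig,
    emit_subsystem_geometry,
    fragment_structure,
    read_fragment_map,
    read_structure,
    read_xyz,
    write_fragment_map,
)

from conftest import tripeptide_atoms


def _ion(serial, position, name="ZN", element="Zn"):
    return AtomRecord(
        serial=serial, name=name, element=element, position=np.asarray(position, float),
        residue_name=name, residue_index=500, chain_id="A", is_ion=True,
    )


class TestReadStructure:
    def test_pdb_round_trip_preserves_residues(self, tmp_path, tripeptide):
        path = tmp_path / "tri.pdb"
        with open(path, "w") as fh:
            write_fixture_pdb(tripeptide, fh)
        atoms = read_structure(str(path))
        assert len(atoms) == len(tripeptide)
        assert sorted({(a.chain_id, a.residue_index) for a in atoms}) == [
            ("A", 1), ("A", 2), ("A", 3)
        ]
        orig = {a.serial: a for a in tripeptide}
        for a in atoms:
            np.testing.assert_allclose(a.position, orig[a.serial].position, atol=1e-3)
            assert a.name == orig[a.serial].name

    def test_xyz_without_fragment_map_is_an_error(self, tmp_path):
        path = tmp_path / "bare.xyz"
        path.write_text("2\ncomment\nO 0 0 0\nH 1 0 0\n")
        with pytest.raises(InputError):
            read_structure(str(path), "xyz", FragmentationConfig())

    def test_hetatm_ion_flagged(self, tmp_path):
        path = tmp_path / "ion.pdb"
        atoms_in = tripeptide_atoms() + [_ion(99, [0.0, 8.0, 0.0])]
        with open(path, "w") as fh:
            write_fixture_pdb(atoms_in, fh)
        atoms = read_structure(str(path))
        ions = [a for a in atoms if a.is_ion]
        assert len(ions) == 1 and ions[0].element == "Zn"

    def test_xyz_charge_tag_parsed(self, tmp_path):
        path = tmp_path / "q.xyz"
        path.write_text("1\ncharge=-2 multiplicity=3\nO 0 0 0\n")
        elements, coords, charge, mult = read_xyz(str(path))
        assert elements == ["O"] and charge == -2 and mult == 3


class TestFragmentation:
    def test_tripeptide_three_fragments_four_caps(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        assert scheme.N == 3
        # two backbone cuts, two hydrogen caps per cut
        assert sum(len(f.cap_atoms) for f in scheme.fragments) == 4
        assert all(f.role == "residue" for f in scheme.fragments)

    def test_cut_moves_carbonyl_to_next_residue(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        # fragment of residue 2 owns residue 1's carbonyl C and O
        frag2 = scheme.fragments[1]
        owned = {(a.residue_index, a.name) for a in frag2.member_atoms}
        assert (1, "C") in owned and (1, "O") in owned
        assert (2, "C") not in owned  # its own carbonyl moved on to residue 3

    def test_cap_geometry_along_cut_bond(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        atoms = {(a.residue_index, a.name): a for a in tripeptide}
        for frag in scheme.fragments:
            for cap in frag.cap_atoms:
                # each cap sits 1.09 A from some heavy atom of its host
                dists = [np.linalg.norm(cap.position - a.position) for a in frag.member_atoms]
                assert min(dists) == pytest.approx(1.09, abs=1e-6)
        ca1, c1 = atoms[(1, "CA")], atoms[(1, "C")]
        frag1_caps = scheme.fragments[0].cap_atoms
        assert len(frag1_caps) == 1
        direction = (c1.position - ca1.position) / np.linalg.norm(c1.position - ca1.position)
        np.testing.assert_allclose(frag1_caps[0].position, ca1.position + 1.09 * direction)

    def test_atom_conservation_and_disjointness(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        member_serials = sorted(a.serial for f in scheme.fragments for a in f.member_atoms)
        assert member_serials == sorted(a.serial for a in tripeptide)

    def test_ion_within_cutoff_merges_with_residue(self, tripeptide):
        carbonyl_o = next(a for a in tripeptide if a.residue_index == 1 and a.name == "O")
        ion = _ion(99, carbonyl_o.position + np.array([0.0, 2.4, 0.0]))
        scheme = fragment_structure(tripeptide + [ion])
        assert scheme.N == 3  # ion absorbed, not a fragment of its own
        groups = [f for f in scheme.fragments if f.role == "ion_group"]
        assert len(groups) == 1
        assert groups[0].formal_charge == 2  # Zn2+ on a neutral residue

    def test_ion_at_cutoff_boundary_not_merged(self, tripeptide):
        carbonyl_o = next(a for a in tripeptide if a.residue_index == 1 and a.name == "O")
        ion = _ion(99, carbonyl_o.position + np.array([0.0, 2.5, 0.0]))
        far = all(
            np.linalg.norm(a.position - ion.position) >= 2.5 for a in tripeptide
        )
        assert far
        scheme = fragment_structure(tripeptide + [ion])
        assert scheme.N == 4  # strict inequality: 2.5 A exactly does not merge

    def test_ion_near_only_ligand_stays_separate(self):
        # a divalent ion 2.4 A from the ligand cannot be combined with it:
        # the ligand must remain separable for the interaction energy
        ligand = [
            AtomRecord(serial=1, name="C1", element="C", position=np.zeros(3),
                       residue_name="LIG", residue_index=900, chain_id="L", is_ligand=True)
        ]
        ion = _ion(2, [2.4, 0.0, 0.0])
        scheme = fragment_structure(ligand + [ion])
        assert scheme.N == 2
        assert sorted(f.role for f in scheme.fragments) == ["ion_group", "ligand"]

    def test_residue_template_charges_applied(self, tripeptide):
        renamed = [
            AtomRecord(
                serial=a.serial, name=a.name, element=a.element, position=a.position,
                residue_name="GLU" if a.residue_index == 2 else a.residue_name,
                residue_index=a.residue_index, chain_id=a.chain_id,
            )
            for a in tripeptide
        ]
        scheme = fragment_structure(renamed)
        assert [f.formal_charge for f in scheme.fragments] == [0, -1, 0]
        assert scheme.total_charge == -1

    def test_missing_backbone_raises_when_cut_demanded(self, tripeptide):
        broken = [a for a in tripeptide if not (a.residue_index == 1 and a.name == "CA")]
        with pytest.raises(FragmentationError):
            fragment_structure(broken)

    def test_refragmentation_is_deterministic(self, tripeptide):
        s1 = fragment_structure(tripeptide)
        s2 = fragment_structure(tripeptide)
        for f1, f2 in zip(s1.fragments, s2.fragments):
            assert [a.serial for a in f1.member_atoms] == [a.serial for a in f2.member_atoms]
            assert len(f1.cap_atoms) == len(f2.cap_atoms)
            for c1, c2 in zip(f1.cap_atoms, f2.cap_atoms):
                np.testing.assert_array_equal(c1.position, c2.position)


class TestSubsystemGeometry:
    def test_monomer_includes_its_caps(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        block = emit_subsystem_geometry(scheme, SubsystemKey((0,)))
        assert block.is_cap.sum() == 1
        assert block.n_atoms == len(scheme.fragments[0].member_atoms) + 1

    def test_adjacent_dimer_restores_cut_bond(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        mono_a = emit_subsystem_geometry(scheme, SubsystemKey((0,)))
        mono_b = emit_subsystem_geometry(scheme, SubsystemKey((1,)))
        dimer = emit_subsystem_geometry(scheme, SubsystemKey((0, 1)))
        # the two caps of the interior A-B cut are omitted
        assert dimer.n_atoms == mono_a.n_atoms + mono_b.n_atoms - 2

    def test_nonadjacent_dimer_keeps_all_caps(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        block = emit_subsystem_geometry(scheme, SubsystemKey((0, 2)))
        expected_caps = len(scheme.fragments[0].cap_atoms) + len(scheme.fragments[2].cap_atoms)
        assert int(block.is_cap.sum()) == expected_caps

    def test_full_union_reproduces_structure_without_caps(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        block = emit_subsystem_geometry(scheme, SubsystemKey(range(scheme.N)))
        assert int(block.is_cap.sum()) == 0
        assert sorted(block.serials.tolist()) == sorted(a.serial for a in tripeptide)

    def test_empty_key_rejected(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        with pytest.raises((InputError, ValueError)):
            emit_subsystem_geometry(scheme, ())

    def test_charge_and_multiplicity_aggregation(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        scheme.fragments[0].formal_charge = -1
        scheme.fragments[1].formal_charge = 1
        block = emit_subsystem_geometry(scheme, SubsystemKey((0, 1)))
        assert block.charge == 0 and block.multiplicity == 1


class TestFragmentMap:
    def test_write_read_round_trip(self, tripeptide):
        scheme = fragment_structure(tripeptide)
        buf = io.StringIO()
        write_fragment_map(scheme, buf)
        buf.seek(0)
        entries = read_fragment_map(buf)
        assert [e.fragment_id for e in entries] == [0, 1, 2]
        assert all(e.role == "residue" for e in entries)
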