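"""Contact labelling against brute-force distance oracles and invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucsite.contacts import (
    classify_protein_atom,
    label_chain,
    residue_ligand_contact,
)
from nucsite.structure_io import (
    AtomRecord,
    LigandInstance,
    ProteinChain,
    ResidueRecord,
    classify_ligand_atoms,
)
from oracles import brute_min_distance


def _residue(atom_specs, aa="H", index=0):
    atoms = [AtomRecord(name, name[0], np.asarray(coord, dtype=float))
             for name, coord in atom_specs]
    return ResidueRecord(aa, "HIS", index, atoms)


def _ligand(atom_specs, het="ATP"):
    atoms = [AtomRecord(name, name[0], np.asarray(coord, dtype=float))
             for name, coord in atom_specs]
    tags = classify_ligand_atoms(het, [a.name for a in atoms])
    return LigandInstance(het, "adenine", 3, False, atoms, tags)


class TestResidueLigandContact:
    def test_cutoff_is_inclusive(self):
        res = _residue([("CA", (0, 0, 0))])
        lig = _ligand([("N9", (4.5, 0, 0))])
        assert residue_ligand_contact(res, lig) is True

    def test_beyond_cutoff_is_false(self):
        res = _residue([("CA", (0, 0, 0))])
        lig = _ligand([("N9", (4.6, 0, 0))])
        assert residue_ligand_contact(res, lig) is False

    def test_agrees_with_brute_force_on_random_clouds(self, rng):
        for _ in range(50):
            n, m = rng.integers(1, 9), rng.integers(1, 25)
            res_xyz = rng.uniform(-6, 6, size=(n, 3))
            lig_xyz = rng.uniform(-6, 6, size=(m, 3))
            res = _residue([("CA", c) for c in res_xyz])
            lig = _ligand([("N9", c) for c in lig_xyz])
            expected = brute_min_distance(res_xyz, lig_xyz) <= 4.5
            assert residue_ligand_contact(res, lig) == expected

    def test_empty_atom_list_rejected(self):
        res = _residue([("CA", (0, 0, 0))])
        lig = _ligand([("N9", (1, 0, 0))])
        lig.atoms = []
        with pytest.raises(ValueError):
            residue_ligand_contact(res, lig)

    def test_hydrogens_excluded_by_default(self):
        res = _residue([("CA", (10, 0, 0)), ("H", (4.0, 0, 0))])
        lig = _ligand([("N9", (0, 0, 0))])
        assert residue_ligand_contact(res, lig) is False
        assert residue_ligand_contact(res, lig, include_hydrogens=True) is True


@pytest.mark.parametrize(
    "aa,atom,expected",
    [
        ("GLY", "CA", "main_chain"),
        ("HIS", "NE2", "side_chain"),
        ("ALA", "OXT", "main_chain"),
        ("ALA", "CB", "side_chain"),
        ("SER", "O", "main_chain"),
    ],
)
def test_classify_protein_atom(aa, atom, expected):
    assert classify_protein_atom(aa, atom) == expected


def _toy_chain_and_ligand():
    """Residue 5's NE2 sits 3.0 Å from the base N9; all else is far."""
    residues = []
    for i in range(10):
        atoms = [("N", (50 + 4 * i, 0, 0)), ("CA", (51 + 4 * i, 0, 0))]
        if i == 5:
            atoms.append(("NE2", (3.0, 0, 0)))
        residues.append(_residue(atoms, aa="H", index=i))
    chain = ProteinChain("1TOY", "A", residues, 1.5)
    ligand = _ligand([("N9", (0, 0, 0)), ("PG", (0, 30, 0)), ("C1'", (0, -30, 0))])
    return chain, ligand


class TestLabelChain:
    def test_single_side_chain_base_contact(self):
        chain, ligand = _toy_chain_and_ligand()
        labels = label_chain(chain, [ligand])
        assert list(np.flatnonzero(labels.overall)) == [5]
        assert list(np.flatnonzero(labels.channels["sc_base"])) == [5]
        for key in ("mc_base", "mc_phos", "sc_phos"):
            assert not labels.channels[key].any()

    def test_far_chain_all_false(self):
        chain, ligand = _toy_chain_and_ligand()
        far = _ligand([("N9", (0, 0, 500))])
        labels = label_chain(chain, [far])
        assert not labels.overall.any()

    def test_any_copy_rule_with_two_ligands(self):
        chain, ligand = _toy_chain_and_ligand()
        copy2 = _ligand([("N9", (51 + 4 * 8, 0, 4.0))])  # near residue 8 CA only
        labels = label_chain(chain, [ligand, copy2])
        assert set(np.flatnonzero(labels.overall)) == {5, 8}

    def test_empty_ligand_list_is_error(self):
        chain, _ = _toy_chain_and_ligand()
        with pytest.raises(ValueError):
            label_chain(chain, [])

    def test_mixed_het_codes_rejected(self):
        chain, ligand = _toy_chain_and_ligand()
        other = _ligand([("N9", (0, 0, 0))], het="GTP")
        other.het_code = "GTP"
        with pytest.raises(ValueError):
            label_chain(chain, [ligand, other])

    def test_rigid_motion_invariance(self, rng):
        chain, ligand = _toy_chain_and_ligand()
        before = label_chain(chain, [ligand])
        rot = Rotation.random(random_state=42).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = rot @ atom.coord + shift
        for atom in ligand.atoms:
            atom.coord = rot @ atom.coord + shift
        after = label_chain(chain, [ligand])
        np.testing.assert_array_equal(before.overall, after.overall)
        for key in before.channels:
            np.testing.assert_array_equal(before.channels[key], after.channels[key])

    def test_enlarging_cutoff_never_unsets_labels(self):
        chain, ligand = _toy_chain_and_ligand()
        prev = label_chain(chain, [ligand], cutoff=2.0)
        for cutoff in (3.0, 4.5, 10.0, 60.0):
            cur = label_chain(chain, [ligand], cutoff=cutoff)
            assert np.all(cur.overall >= prev.overall)
            prev = cur

    def test_channel_union_subset_of_overall(self, small_dataset):
        for entry in small_dataset.entries:
            union = entry.labels.channel_union
            assert np.all(entry.labels.overall[union])

    def test_union_equals_overall_without_ribose(self):
        # ligand with base and phosphate atoms only
        residues = [_residue([("CA", (0, 0, 0)), ("CB", (1, 0, 0))], index=0),
                    _residue([("CA", (30, 0, 0))], index=1)]
        chain = ProteinChain("1NRB", "A", residues, 1.5)
        ligand = _ligand([("N9", (3.0, 0, 0)), ("PG", (0, 3.0, 0))])
        labels = label_chain(chain, [ligand])
        np.testing.assert_array_equal(labels.channel_union, labels.overall)

    def test_labels_match_brute_force_on_fixture_dataset(self, small_dataset):
        for entry in small_dataset.entries:
            lig_xyz = [a.coord for e2 in [entry] for a in _all_ligand_atoms(e2)]
            for i, res in enumerate(entry.chain.residues):
                d = brute_min_distance([a.coord for a in res.atoms], lig_xyz)
                assert entry.labels.overall[i] == (d <= 4.5)


def _all_ligand_atoms(entry):
    from conftest import SMALL_SPEC
    from nucsite.structure_io import parse_complex
    from nucsite.synthetic import make_toy_complex

    idx = int(entry.chain.structure_id[1:])
    _, ligands = parse_complex(make_toy_complex(SMALL_SPEC, idx))
    return [a for lig in ligands for a in lig.atoms]
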