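"""Structure parsing, ligand atom tagging and dataset curation."""

import numpy as np
import pytest

from nucsite.structure_io import (
    LIGAND_CLASSES,
    PDBParseError,
    ProteinChain,
    apply_structure_filters,
    classify_ligand_atoms,
    parse_complex,
    remove_redundancy,
    sequence_identity,
    write_pdb,
)
from nucsite.synthetic import FixtureSpec, make_toy_complex

from oracles import greedy_keep, nw_identity

TWO_MODEL_PDB = """\
HEADER    NMR ENSEMBLE                            01-JAN-00   1NMR
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       2.000   1.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       3.450   1.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       9.000   9.000   9.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       9.450   9.000   9.000  1.00  0.00           C
ATOM      3  N   GLY A   2       9.000   8.000   9.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       9.450   8.000   9.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
HEADER    ALTLOC CASE                             01-JAN-00   1ALT
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA ASER A   2       3.000   0.000   0.000  0.50  0.00           C
ATOM      4  CA BSER A   2       4.000   0.000   0.000  0.50  0.00           C
ATOM      5  N   SER A   2       5.000   0.000   0.000  1.00  0.00           N
END
"""

MSE_PDB = """\
HEADER    SELENOMETHIONINE                        01-JAN-00   1MSE
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  CA  MSE A   2       3.000   0.000   0.000  1.00  0.00           C
HETATM    3  CA  XXX A   3       6.000   0.000   0.000  1.00  0.00           C
END
"""


class TestParseComplex:
    def test_toy_complex_chain_and_ligand(self):
        spec = FixtureSpec(n_proteins=1, chain_length=35, ligand_het="ATP",
                           n_binding=3, seed=3)
        chains, ligands = parse_complex(make_toy_complex(spec, 0))
        assert len(chains) == 1 and len(chains[0]) == 35
        assert len(ligands) == 1
        lig = ligands[0]
        assert (lig.base, lig.n_phosphates, lig.cyclic) == ("adenine", 3, False)

    def test_multi_model_keeps_first_model_only(self):
        chains, ligands = parse_complex(TWO_MODEL_PDB)
        assert ligands == []
        (chain,) = chains
        assert chain.resolution is None  # NMR: no REMARK 2 value
        assert len(chain) == 2
        np.testing.assert_allclose(chain.residues[0].atoms[1].coord, [1.45, 0, 0])

    def test_no_hetatm_gives_empty_ligand_list(self):
        chains, ligands = parse_complex(TWO_MODEL_PDB)
        assert chains and ligands == []

    def test_altloc_highest_occupancy_wins_ties_lowest_char(self):
        chains, _ = parse_complex(ALTLOC_PDB)
        (chain,) = chains
        ca1 = next(a for a in chain.residues[0].atoms if a.name == "CA")
        assert ca1.coord[0] == pytest.approx(2.0)  # occupancy 0.6 beats 0.4
        ca2 = next(a for a in chain.residues[1].atoms if a.name == "CA")
        assert ca2.coord[0] == pytest.approx(3.0)  # tie -> altloc A
        assert len(chain.residues[1].atoms) == 2   # CA resolved + N

    def test_modified_residue_maps_to_parent(self):
        chains, _ = parse_complex(MSE_PDB)
        assert chains[0].sequence == "AM"  # MSE -> M; XXX dropped entirely

    def test_malformed_coordinate_raises_with_line(self):
        bad = TWO_MODEL_PDB.replace("1.450", "x.450", 1)
        with pytest.raises(PDBParseError, match="line"):
            parse_complex(bad)

    def test_unknown_het_codes_silently_ignored(self):
        text = TWO_MODEL_PDB.replace(
            "END\n",
            "HETATM  9  MG  MG  A  90       1.000   1.000   1.000  1.00  0.00          MG\nEND\n",
        )
        _, ligands = parse_complex(text)
        assert ligands == []

    def test_roundtrip_preserves_atoms_and_coords(self):
        spec = FixtureSpec(n_proteins=1, chain_length=32, n_binding=3, seed=5)
        chains, ligands = parse_complex(make_toy_complex(spec, 0))
        chains2, ligands2 = parse_complex(write_pdb(chains, ligands))
        a1 = [a for r in chains[0].residues for a in r.atoms]
        a2 = [a for r in chains2[0].residues for a in r.atoms]
        assert len(a1) == len(a2)
        np.testing.assert_allclose(
            [a.coord for a in a1], [a.coord for a in a2], atol=5e-4
        )
        assert len(ligands2[0].atoms) == len(ligands[0].atoms)


class TestClassifyLigandAtoms:
    @pytest.mark.parametrize(
        "het,name,expected",
        [
            ("ATP", "PG", "phosphate"),
            ("ATP", "O3B", "phosphate"),
            ("ATP", "N9", "base"),
            ("ATP", "N6", "base"),
            ("5GP", "C2'", "ribose"),
            ("5GP", "O6", "base"),
            ("5GP", "O3P", "phosphate"),
            ("CMP", "P", "phosphate"),
            ("GDP", "O5'", "ribose"),
            ("AMP", "C2*", "ribose"),  # old-style star names
        ],
    )
    def test_table_mapping(self, het, name, expected):
        assert classify_ligand_atoms(het, [name]) == [expected]

    def test_unknown_name_tagged_ribose_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="nucsite.structure_io"):
            assert classify_ligand_atoms("ATP", ["ZZ1"]) == ["ribose"]
        assert "ZZ1" in caplog.text

    def test_unsupported_het_code_rejected(self):
        with pytest.raises(ValueError):
            classify_ligand_atoms("GNP", ["PG"])

    def test_every_supported_code_has_consistent_class_metadata(self):
        for het, (base, n_phos, cyclic) in LIGAND_CLASSES.items():
            assert base in ("adenine", "guanine")
            assert 1 <= n_phos <= 3
            assert not cyclic or n_phos == 1


def _chain(seq, resolution, sid="1ABC", cid="A"):
    from nucsite.alphabet import AA1_TO_3
    from nucsite.structure_io import AtomRecord, ResidueRecord

    residues = [
        ResidueRecord(aa, AA1_TO_3.get(aa, "UNK"), i,
                      [AtomRecord("CA", "C", np.array([3.8 * i, 0.0, 0.0]))])
        for i, aa in enumerate(seq)
    ]
    return ProteinChain(sid, cid, residues, resolution)


class TestStructureFilters:
    def test_resolution_and_length_filters(self):
        chains = [
            _chain("A" * 40, 3.0, "1LOW"),    # resolution worse than cutoff
            _chain("A" * 29, 1.5, "1SHT"),    # too short
            _chain("A" * 40, 2.5, "1BND"),    # boundary retained
            _chain("A" * 40, None, "1NMR"),   # NMR passes resolution filter
        ]
        kept = {c.structure_id for c in apply_structure_filters(chains)}
        assert kept == {"1BND", "1NMR"}

    def test_filter_is_idempotent(self):
        chains = [_chain("A" * 40, 2.0), _chain("A" * 40, 3.0, "1BAD")]
        once = apply_structure_filters(chains)
        assert apply_structure_filters(once) == once


class TestRemoveRedundancy:
    def test_identical_sequences_collapse(self):
        a = _chain("ACDEFGHIKLMNPQRSTVWY" * 2, 1.5, "1AAA")
        b = _chain("ACDEFGHIKLMNPQRSTVWY" * 2, 1.5, "1BBB")
        kept = remove_redundancy([a, b])
        assert [c.structure_id for c in kept] == ["1AAA"]

    def test_disjoint_alphabet_sequences_both_kept(self):
        a = _chain("ACDACDACDACD" * 3, 1.5, "1AAA")
        b = _chain("KLMKLMKLMKLM" * 3, 1.5, "1BBB")
        assert sequence_identity(a.sequence, b.sequence) == 0.0
        assert len(remove_redundancy([a, b])) == 2

    def test_greedy_matches_oracle_hand_simulation(self):
        seqs = {
            "1AAA": "ACDEFG" * 6,
            "1BBB": "ACDEFG" * 5 + "ACDKFG",   # ~0.97 identity to 1AAA
            "1CCC": "ACDEFG" * 5,              # prefix of 1AAA
            "1DDD": "KLMNPQ" * 6,
            "1EEE": "KLMNPQ" * 4 + "KLMNPL",   # close to 1DDD
        }
        chains = [_chain(s, 1.5, sid) for sid, s in seqs.items()]
        kept = {c.structure_id for c in remove_redundancy(chains)}
        expected = set(greedy_keep(seqs, nw_identity, 0.30))
        assert kept == expected == {"1AAA", "1DDD"}

    def test_no_retained_pair_above_cutoff(self, rng):
        base = "ACDEFGHIKL"
        seqs = {}
        for i in range(8):
            letters = list(base * 3)
            for j in rng.choice(len(letters), size=rng.integers(0, 12), replace=False):
                letters[j] = "ACDEFGHIKL"[rng.integers(10)]
            seqs[f"1S{i:02d}"] = "".join(letters)
        chains = [_chain(s, 1.5, sid) for sid, s in seqs.items()]
        kept = remove_redundancy(chains, identity_cutoff=0.30)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert nw_identity(a.sequence, b.sequence) <= 0.30 + 1e-12

    def test_implementation_identity_agrees_with_oracle(self):
        pairs = [("ACDEFG" * 4, "ACDEFG" * 4),
                 ("ACDACD" * 4, "KLMKLM" * 4),
                 ("ACDEFGHIKL" * 2, "ACDEFGHIKL" * 2 + "KLM")]
        for a, b in pairs:
            assert sequence_identity(a, b) == pytest.approx(nw_identity(a, b))
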