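"""The eight-integer neighbor label: construction, canonical form,
hydrogen handling, consolidation, and the class vocabulary."""

import itertools

import pytest

from nmrsubstruct.io_nmrshiftdb import MolecularGraph
from nmrsubstruct.neighbor_encoding import (ELEMENT_CODES, EncodingError,
                                            NeighborLabel, build_vocabulary,
                                            canonicalize, consolidate,
                                            encode_atom,
                                            hydrogen_substructure, raw_label,
                                            zero_hydrogens)


def label(*values):
    return NeighborLabel.from_values(values)


class TestElementTable:
    def test_alphabetical_codes_are_bijective(self):
        assert len(ELEMENT_CODES) == 31
        assert len(set(ELEMENT_CODES.values())) == 31
        assert ELEMENT_CODES["Ag"] == 1 and ELEMENT_CODES["Zn"] == 31
        assert ELEMENT_CODES["C"] == 7
        assert ELEMENT_CODES["N"] == 17
        assert ELEMENT_CODES["O"] == 19


class TestRawLabel:
    def test_carbon_with_single_c_double_n_and_implicit_h(self):
        # acetaldimine-like environment: the reference worked example
        graph = MolecularGraph.from_smiles("CC=N", "probe")
        lab = canonicalize(zero_hydrogens(raw_label(graph, 2)))
        assert lab.astuple() == (7, 17, 0, 0, 1, 2, 0, 0)
        assert lab.bond_sum == 3

    def test_methane_like_all_hydrogen_environment(self):
        graph = MolecularGraph.from_smiles("C", "methane")
        lab = encode_atom(graph, 1)
        assert lab.astuple() == (0,) * 8

    def test_co2_central_carbon(self):
        graph = MolecularGraph.from_smiles("O=C=O", "co2")
        lab = encode_atom(graph, 2)
        assert lab.astuple() == (19, 19, 0, 0, 2, 2, 0, 0)

    def test_non_carbon_rejected(self):
        graph = MolecularGraph.from_smiles("CO", "methanol")
        with pytest.raises(EncodingError):
            raw_label(graph, 2)


class TestZeroHydrogens:
    def test_explicit_hydrogen_slots_reset(self):
        lab = label(7, 11, 11, 0, 1, 1, 1, 0)
        assert zero_hydrogens(lab).astuple() == (7, 0, 0, 0, 1, 0, 0, 0)

    def test_no_hydrogen_fixed_point(self):
        lab = label(7, 17, 0, 0, 1, 2, 0, 0)
        assert zero_hydrogens(lab) == lab

    def test_all_hydrogen_becomes_empty(self):
        lab = label(11, 11, 11, 11, 1, 1, 1, 1)
        assert zero_hydrogens(lab).astuple() == (0,) * 8


class TestCanonicalize:
    def test_reference_resort_example(self):
        lab = label(7, 7, 19, 17, 1, 1, 1, 1)
        assert canonicalize(lab).astuple() == (7, 7, 17, 19, 1, 1, 1, 1)

    def test_equivalent_orderings_reference_pair(self):
        a = canonicalize(label(7, 17, 0, 0, 1, 2, 0, 0))
        b = canonicalize(label(17, 7, 0, 0, 2, 1, 0, 0))
        assert a == b

    def test_idempotent_and_permutation_invariant_exhaustive(self):
        pairs = ((7, 1), (17, 2), (19, 1), (0, 0))
        results = set()
        for perm in itertools.permutations(pairs):
            atoms = tuple(a for a, _ in perm)
            bonds = tuple(b for _, b in perm)
            canon = canonicalize(NeighborLabel(atoms, bonds))
            assert canonicalize(canon) == canon
            results.add(canon)
        assert len(results) == 1
        (canon,) = results
        # occupied slots sorted by (bond, atom); zeros trail
        assert canon.astuple() == (7, 19, 17, 0, 1, 1, 2, 0)


class TestConsolidate:
    def test_sulfur_maps_to_catch_all(self):
        lab = label(7, 23, 0, 0, 1, 1, 0, 0)
        assert consolidate(lab).astuple() == (7, 32, 0, 0, 1, 1, 0, 0)

    def test_cno_preserved(self):
        lab = label(7, 17, 19, 0, 1, 1, 2, 0)
        assert consolidate(lab).atoms == (7, 17, 19, 0)

    def test_halogens_collapse_together(self):
        lab = label(6, 9, 0, 0, 1, 1, 0, 0)  # Br, F
        assert consolidate(lab).astuple() == (32, 32, 0, 0, 1, 1, 0, 0)

    def test_consolidation_never_increases_class_count(self, rng):
        labels = []
        for _ in range(200):
            atoms, bonds = [], []
            for _ in range(4):
                if rng.random() < 0.3:
                    atoms.append(0)
                    bonds.append(0)
                else:
                    atoms.append(int(rng.integers(1, 32)))
                    bonds.append(int(rng.integers(1, 4)))
            labels.append(canonicalize(
                zero_hydrogens(NeighborLabel(tuple(atoms), tuple(bonds)))
            ))
        m_raw = len(set(labels))
        m_cons = len({consolidate(lab) for lab in labels})
        assert m_cons <= m_raw


class TestFullPipeline:
    def test_bond_sum_at_most_four_and_equals_four_only_without_h(self):
        for smiles, atom, n_h in [("CC(C)(C)C", 2, 0), ("CCC", 2, 2),
                                  ("C=O", 1, 2)]:
            graph = MolecularGraph.from_smiles(smiles, smiles)
            lab = encode_atom(graph, atom)
            assert lab.bond_sum <= 4
            if n_h == 0:
                assert lab.bond_sum == 4
            else:
                assert lab.bond_sum < 4

    def test_isomorphic_environments_identical_labels(self):
        # every benzene carbon, and every para-related toluene ring carbon,
        # shares its one-bond environment
        benzene = MolecularGraph.from_smiles("c1ccccc1", "benzene")
        labels = {encode_atom(benzene, i) for i, el in benzene.atoms}
        assert len(labels) == 1

    def test_degree_above_four_rejected(self):
        # artificial 5-coordinate carbon graph (no RDKit mol attached)
        graph = MolecularGraph(
            "penta",
            tuple((i, "C") for i in range(1, 7)),
            tuple((1, j, 1) for j in range(2, 7)),
        )
        with pytest.raises(EncodingError):
            raw_label(graph, 1)


class TestHydrogenSubstructure:
    def test_equals_attached_carbon_label(self):
        from rdkit import Chem

        mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
        graph = MolecularGraph.from_rdkit(mol, "benzene-H")
        h_index = next(i for i, el in graph.atoms if el == "H")
        carbon = graph.neighbors(h_index)[0][0]
        assert hydrogen_substructure(graph, h_index) == encode_atom(
            graph, carbon
        )

    def test_methane_hydrogen_all_zero(self):
        from rdkit import Chem

        mol = Chem.AddHs(Chem.MolFromSmiles("C"))
        graph = MolecularGraph.from_rdkit(mol, "methane-H")
        assert hydrogen_substructure(graph, 2).astuple() == (0,) * 8

    def test_hydroxyl_hydrogen_rejected(self):
        from rdkit import Chem

        mol = Chem.AddHs(Chem.MolFromSmiles("CO"))
        graph = MolecularGraph.from_rdkit(mol, "methanol-H")
        hydroxyl_h = next(
            i for i, el in graph.atoms
            if el == "H" and graph.element(graph.neighbors(i)[0][0]) == "O"
        )
        with pytest.raises(EncodingError):
            hydrogen_substructure(graph, hydroxyl_h)


class TestVocabulary:
    def test_single_repeated_label(self):
        lab = label(7, 0, 0, 0, 1, 0, 0, 0)
        vocab = build_vocabulary([lab, lab, lab])
        assert len(vocab) == 1 and vocab.index(lab) == 0

    def test_lexicographic_indexing(self):
        a = label(7, 0, 0, 0, 1, 0, 0, 0)
        b = label(7, 7, 0, 0, 1, 1, 0, 0)
        vocab = build_vocabulary([b, a, b])
        assert vocab.index(a) == 0 and vocab.index(b) == 1

    def test_distinct_count_matches_brute_force(self):
        from nmrsubstruct.synthetic_data import SyntheticConfig, generate

        pairs, truth = generate(SyntheticConfig(n_molecules=20, seed=3))
        labels = [NeighborLabel.from_string(t) for t in truth["label"]]
        vocab = build_vocabulary(labels)
        assert len(vocab) == len({lab.astuple() for lab in labels})

    def test_unseen_label_maps_to_unknown(self):
        vocab = build_vocabulary([label(7, 0, 0, 0, 1, 0, 0, 0)])
        assert vocab.index(label(19, 0, 0, 0, 1, 0, 0, 0)) == -1

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])

    def test_plain_text_roundtrip(self, tmp_path):
        labs = [label(7, 0, 0, 0, 1, 0, 0, 0),
                label(7, 19, 0, 0, 1, 1, 0, 0)]
        vocab = build_vocabulary(labs)
        path = tmp_path / "vocab.txt"
        with open(path, "w") as fh:
            vocab.dump(fh)
        from nmrsubstruct.neighbor_encoding import SubstructureVocabulary

        with open(path) as fh:
            again = SubstructureVocabulary.load(fh)
        assert again.labels == vocab.labels
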