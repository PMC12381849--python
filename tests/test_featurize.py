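"""Normalization, multiplicity indexing, sequence building and padding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrsubstruct.featurize import (FeatureConfig, FeaturizationError,
                                    MoleculeSequence, SolventVocabulary,
                                    build_molecule_sequence,
                                    encode_multiplicity, encode_solvent,
                                    featurize_pairs, fit_feature_config,
                                    normalize_condition, pad_sequence,
                                    zero_conditions)
from nmrsubstruct.io_nmrshiftdb import Signal, SpectrumRecord


class TestNormalizeCondition:
    @pytest.mark.parametrize(
        "value,maximum,expected",
        [(50, 700, 0.07143), (298, 323, 0.9226), (700, 700, 1.0)],
    )
    def test_reference_worked_examples(self, value, maximum, expected):
        assert normalize_condition(value, maximum) == pytest.approx(
            expected, abs=5e-5
        )

    def test_missing_maps_to_zero(self):
        assert normalize_condition(None, 700) == 0.0

    def test_value_above_maximum_names_record(self):
        with pytest.raises(FeaturizationError, match="rec7"):
            normalize_condition(800, 700, record_id="rec7")

    @given(st.floats(0, 700), st.floats(0, 700))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        fa, fb = normalize_condition(a, 700), normalize_condition(b, 700)
        assert 0.0 <= fa <= 1.0
        if a <= b:
            assert fa <= fb


class TestEncodeMultiplicity:
    @pytest.mark.parametrize(
        "symbol,code", [("s", 1), ("d", 2), ("t", 3), ("q", 4), (None, 0)]
    )
    def test_mapping(self, symbol, code):
        assert encode_multiplicity(symbol) == code

    def test_unknown_symbol_rejected(self):
        with pytest.raises(FeaturizationError):
            encode_multiplicity("x")


TABLE_SHIFTS = (17.6, 18.3, 22.6, 26.5, 31.7, 33.5, 33.5, 41.8, 42.0,
                42.2, 78.34, 140.99, 158.3, 193.4, 203.0)
TABLE_MULTS = ("q", "t", "q", "t", "t", "s", "s", "t", "s", "d", "s",
               "s", "d", "d", "d")


def _record(shifts, mults, mol_id="m"):
    return SpectrumRecord(
        molecule_id=mol_id, nucleus="13C",
        signals=tuple(
            Signal(i + 1, s, m) for i, (s, m) in enumerate(zip(shifts, mults))
        ),
    )


class TestMoleculeSequence:
    def test_fifteen_signal_worked_example(self):
        seq = build_molecule_sequence(_record(TABLE_SHIFTS, TABLE_MULTS))
        assert seq.multiplicities == (4, 3, 4, 3, 3, 1, 1, 3, 1, 2, 1, 1,
                                      2, 2, 2)
        assert seq.shifts == TABLE_SHIFTS

    def test_single_signal(self):
        seq = build_molecule_sequence(_record([10.0], ["s"]))
        assert seq.shifts == (10.0,) and seq.multiplicities == (1,)

    def test_empty_record_rejected(self):
        with pytest.raises(FeaturizationError):
            build_molecule_sequence(_record([], []))

    def test_invariant_to_every_input_permutation(self):
        shifts, mults = (5.0, 1.0, 3.0, 3.0), ("d", "q", "s", "t")
        signals = [Signal(i + 1, s, m)
                   for i, (s, m) in enumerate(zip(shifts, mults))]
        reference = None
        for perm in itertools.permutations(signals):
            rec = SpectrumRecord("m", "13C", tuple(perm))
            seq = build_molecule_sequence(rec)
            if reference is None:
                reference = seq
            assert seq == reference
        assert reference.shifts == (1.0, 3.0, 3.0, 5.0)


class TestSolventEncoding:
    def test_missing_maps_to_zero(self):
        vocab = SolventVocabulary(["CDCl3", "CDCl3", "DMSO-d6"])
        assert encode_solvent(None, vocab) == 0

    def test_codes_by_descending_frequency_then_alphabetical(self):
        vocab = SolventVocabulary(
            ["b", "b", "a", "a", "c"]
        )
        assert vocab.encode("a") == 1  # tie with b broken alphabetically
        assert vocab.encode("b") == 2
        assert vocab.encode("c") == 3

    def test_onehot_bijective_with_integer_codes(self):
        names = ["w", "x", "y", "z", "v"]
        vocab = SolventVocabulary(names)
        seen = set()
        for name in names:
            vec = encode_solvent(name, vocab, onehot=True)
            assert vec.sum() == 1.0 and len(vec) == 5
            code = int(np.argmax(vec)) + 1
            assert code == vocab.encode(name)
            seen.add(code)
        assert seen == {1, 2, 3, 4, 5}
        assert encode_solvent(None, vocab, onehot=True).sum() == 0.0


class TestPadding:
    def test_trailing_zeros(self):
        seq = MoleculeSequence((1.0, 2.0, 3.0), (1, 2, 3))
        shifts, mults = pad_sequence(seq, 8)
        assert shifts.tolist() == [1, 2, 3, 0, 0, 0, 0, 0]
        assert mults.tolist() == [1, 2, 3, 0, 0, 0, 0, 0]

    def test_exact_length_unchanged_and_roundtrip(self):
        seq = MoleculeSequence((1.0, 2.0), (4, 4))
        shifts, mults = pad_sequence(seq, 2)
        assert tuple(shifts) == seq.shifts
        padded, _ = pad_sequence(seq, 9)
        assert tuple(padded[:2]) == seq.shifts and not padded[2:].any()

    def test_overflow_rejected(self):
        with pytest.raises(FeaturizationError):
            pad_sequence(MoleculeSequence((1.0, 2.0, 3.0), (1, 1, 1)), 2)


class TestFeaturizePairs:
    def test_layout_and_condition_zeroing(self, ethanol_pair):
        cfg, vocab = fit_feature_config([ethanol_pair])
        feats = featurize_pairs([ethanol_pair], cfg, vocab)
        assert feats["fixed"].shape[0] == 2
        assert feats["seq_shifts"].shape == (2, 2)
        assert (feats["lengths"] == 2).all()
        zeroed = zero_conditions(feats)
        assert not zeroed["fixed"][:, 2:].any()
        assert np.allclose(zeroed["fixed"][:, :2], feats["fixed"][:, :2])

    def test_relative_mode_shifts_are_offset_invariant(self, ethanol_pair):
        graph, record = ethanol_pair
        moved = SpectrumRecord(
            record.molecule_id, record.nucleus,
            tuple(Signal(s.atom_index, s.shift + 30.0, s.multiplicity)
                  for s in record.signals),
            record.field_strength, record.temperature, record.solvent,
        )
        cfg, vocab = fit_feature_config([ethanol_pair])
        cfg.sequence_mode = "relative"
        a = featurize_pairs([ethanol_pair], cfg, vocab)
        b = featurize_pairs([(graph, moved)], cfg, vocab)
        assert np.allclose(a["seq_shifts"], b["seq_shifts"])

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = FeatureConfig(field_max=600.0, max_len=7,
                            solvent_names=["CDCl3"])
        path = tmp_path / "cfg.yaml"
        with open(path, "w") as fh:
            cfg.save(fh)
        with open(path) as fh:
            again = FeatureConfig.load(fh)
        assert again == cfg
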