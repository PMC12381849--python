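import numpy as np
import pytest

from nmrsubstruct.io_nmrshiftdb import (MolecularGraph, Signal,
                                        SpectrumRecord)


@pytest.fixture
def ethanol_pair():
    """Ethanol with two carbon signals — hand-checkable: 2 C, 1 O."""
    graph = MolecularGraph.from_smiles("CCO", "ethanol")
    record = SpectrumRecord(
        molecule_id="ethanol",
        nucleus="13C",
        signals=(Signal(1, 18.3, "q"), Signal(2, 57.8, "t")),
        field_strength=400.0,
        temperature=298.0,
        solvent="CDCl3",
    )
    return graph, record


@pytest.fixture
def mixed_provenance_pairs():
    """Ten records, three of them computational, with varied metadata."""
    pairs = []
    for i in range(10):
        graph = MolecularGraph.from_smiles("CC=O", f"mol{i}")
        record = SpectrumRecord(
            molecule_id=f"mol{i}",
            nucleus="13C",
            signals=(Signal(1, 30.0 + i, "q"), Signal(2, 199.0 + i, "d")),
            field_strength=None if i % 2 else 500.0,
            temperature=None if i % 3 else 300.0,
            solvent=None if i in (0, 4) else "CDCl3",
            provenance="computational" if i in (2, 5, 8) else "experimental",
        )
        pairs.append((graph, record))
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
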