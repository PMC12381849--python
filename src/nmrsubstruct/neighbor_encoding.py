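"""Neighbor-label encoding of a carbon's one-bond chemical environment.

Each carbon atom is described by eight integers: four element codes for the
atoms bonded to it and four aligned bond orders.  Element codes follow an
alphabetical table of 31 symbols (Ag=1 … Zn=31); code 32 is the catch-all
class used after consolidation for every element other than C, N and O.
Bond orders run 0 (no bond) to 3 (triple).  Hydrogens are removed from the
label (both slots zeroed), so the bond-order slots of a carbon bearing
hydrogens sum to less than four.  Canonical form sorts the occupied
(bond, atom) pairs ascending by bond order, then element code, with empty
slots trailing.

A hydrogen's substructure is defined as the label of its unique attached
carbon, which is how ¹H spectra are mapped onto the same class space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: Alphabetical element codes; 32 is reserved for "anything but C, N, O".
ELEMENT_CODES = {
    "Ag": 1, "Al": 2, "As": 3, "B": 4, "Bi": 5, "Br": 6, "C": 7, "Cl": 8,
    "F": 9, "Ge": 10, "H": 11, "Hg": 12, "I": 13, "K": 14, "Li": 15,
    "Mg": 16, "N": 17, "Na": 18, "O": 19, "P": 20, "Pb": 21, "Pd": 22,
    "S": 23, "Sb": 24, "Se": 25, "Si": 26, "Sn": 27, "Te": 28, "Ti": 29,
    "Tl": 30, "Zn": 31,
}
CONSOLIDATED_CODE = 32
HYDROGEN_CODE = ELEMENT_CODES["H"]
#: Element codes preserved by consolidation (carbon, nitrogen, oxygen).
PRESERVED_CODES = frozenset(
    {ELEMENT_CODES["C"], ELEMENT_CODES["N"], ELEMENT_CODES["O"]}
)

UNKNOWN_CLASS = -1  # class index for labels unseen when the vocabulary was built


class EncodingError(ValueError):
    """An atom environment that the encoding rejects (logged and skipped)."""


def element_code(symbol: str) -> int:
    """Map an element symbol to its numerical class, 32 for unlisted ones."""
    code = ELEMENT_CODES.get(symbol)
    if code is None:
        logger.warning("element %r outside the 31-symbol table; using 32", symbol)
        return CONSOLIDATED_CODE
    return code


@dataclass(frozen=True, order=True)
class NeighborLabel:
    """Eight-integer substructure code: 4 atom slots + 4 aligned bond slots."""

    atoms: tuple   # 4 ints, 0-32
    bonds: tuple   # 4 ints, 0-3

    def __post_init__(self) -> None:
        if len(self.atoms) != 4 or len(self.bonds) != 4:
            raise ValueError("a neighbor label has exactly 4 + 4 slots")
        for a, b in zip(self.atoms, self.bonds):
            if not (0 <= a <= 32):
                raise ValueError(f"atom code {a} outside 0-32")
            if not (0 <= b <= 3):
                raise ValueError(f"bond order {b} outside 0-3")

    def astuple(self) -> tuple:
        return tuple(self.atoms) + tuple(self.bonds)

    def __str__(self) -> str:
        return ", ".join(str(v) for v in self.astuple())

    @classmethod
    def from_values(cls, values) -> "NeighborLabel":
        values = tuple(int(v) for v in values)
        if len(values) != 8:
            raise ValueError("expected 8 integers")
        return cls(values[:4], values[4:])

    @classmethod
    def from_string(cls, text: str) -> "NeighborLabel":
        return cls.from_values(v.strip() for v in text.split(","))

    @property
    def bond_sum(self) -> int:
        return sum(self.bonds)


def raw_label(graph, atom_index: int) -> NeighborLabel:
    """Pre-canonical label of a carbon: one slot per explicit neighbor.

    Implicit hydrogens never occupy a slot (they would be zeroed anyway);
    explicit hydrogens are recorded as code 11 and removed later by
    :func:`zero_hydrogens`.  A carbon with more than four connections is
    rejected.
    """
    if graph.element(atom_index) != "C":
        raise EncodingError(
            f"{graph.molecule_id}: atom {atom_index} is "
            f"{graph.element(atom_index)}, not carbon"
        )
    neighbors = graph.neighbors(atom_index)
    if len(neighbors) + graph.implicit_hydrogens(atom_index) > 4:
        raise EncodingError(
            f"{graph.molecule_id}: carbon {atom_index} has degree > 4"
        )
    atoms = [0, 0, 0, 0]
    bonds = [0, 0, 0, 0]
    for slot, (nbr, order) in enumerate(neighbors):
        atoms[slot] = element_code(graph.element(nbr))
        bonds[slot] = order
    return NeighborLabel(tuple(atoms), tuple(bonds))


def zero_hydrogens(label: NeighborLabel) -> NeighborLabel:
    """Reset every hydrogen slot (atom code and bond order) to zero."""
    atoms = list(label.atoms)
    bonds = list(label.bonds)
    for i, a in enumerate(atoms):
        if a == HYDROGEN_CODE:
            atoms[i] = 0
            bonds[i] = 0
    return NeighborLabel(tuple(atoms), tuple(bonds))


def canonicalize(label: NeighborLabel) -> NeighborLabel:
    """Sort occupied slots by (bond order, element code); zeros trail.

    Idempotent, and invariant under any permutation of the input slots.
    """
    occupied = [
        (b, a)
        for a, b in zip(label.atoms, label.bonds)
        if a != 0
    ]
    occupied.sort()
    atoms = [a for _, a in occupied] + [0] * (4 - len(occupied))
    bonds = [b for b, _ in occupied] + [0] * (4 - len(occupied))
    return NeighborLabel(tuple(atoms), tuple(bonds))


def consolidate(label: NeighborLabel) -> NeighborLabel:
    """Collapse every element other than C, N, O onto class 32, re-sorting."""
    atoms = tuple(
        a if (a == 0 or a in PRESERVED_CODES) else CONSOLIDATED_CODE
        for a in label.atoms
    )
    return canonicalize(NeighborLabel(atoms, label.bonds))


def encode_atom(graph, atom_index: int) -> NeighborLabel:
    """Full pipeline: raw label → hydrogen zeroing → canonical → consolidated."""
    return consolidate(canonicalize(zero_hydrogens(raw_label(graph, atom_index))))


def hydrogen_substructure(graph, h_index: int) -> NeighborLabel:
    """Label for a hydrogen: the pipeline label of its attached carbon."""
    if graph.element(h_index) != "H":
        raise EncodingError(
            f"{graph.molecule_id}: atom {h_index} is not hydrogen"
        )
    neighbors = graph.neighbors(h_index)
    if len(neighbors) != 1:
        raise EncodingError(
            f"{graph.molecule_id}: hydrogen {h_index} has "
            f"{len(neighbors)} bonds, expected 1"
        )
    carbon, _ = neighbors[0]
    if graph.element(carbon) != "C":
        raise EncodingError(
            f"{graph.molecule_id}: hydrogen {h_index} attached to "
            f"{graph.element(carbon)}, not carbon"
        )
    return encode_atom(graph, carbon)


class SubstructureVocabulary:
    """Bijection between consolidated labels and dense class indices.

    Classes are numbered in lexicographic order of the 8-integer code so
    the mapping is deterministic for a given corpus.  Labels unseen at
    build time map to :data:`UNKNOWN_CLASS` and are excluded from accuracy
    numerators downstream.
    """

    def __init__(self, labels: Iterable) -> None:
        distinct = sorted(set(labels), key=lambda lab: lab.astuple())
        if not distinct:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        self._to_index = {lab: i for i, lab in enumerate(distinct)}
        self._labels = distinct

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: NeighborLabel) -> bool:
        return label in self._to_index

    def index(self, label: NeighborLabel) -> int:
        return self._to_index.get(label, UNKNOWN_CLASS)

    def label(self, index: int) -> NeighborLabel:
        return self._labels[index]

    @property
    def labels(self) -> list:
        return list(self._labels)

    def onehot(self, label: NeighborLabel):
        import numpy as np

        vec = np.zeros(len(self), dtype=float)
        idx = self.index(label)
        if idx != UNKNOWN_CLASS:
            vec[idx] = 1.0
        return vec

    # -- plain-text persistence -------------------------------------------

    def dump(self, stream) -> None:
        for i, lab in enumerate(self._labels):
            stream.write(f"{i}\t{lab}\n")

    @classmethod
    def load(cls, stream) -> "SubstructureVocabulary":
        labels = []
        for line in stream:
            if not line.strip():
                continue
            _, text = line.split("\t", 1)
            labels.append(NeighborLabel.from_string(text))
        return cls(labels)


def build_vocabulary(labels: Iterable) -> SubstructureVocabulary:
    """Vocabulary over a corpus of consolidated labels."""
    return SubstructureVocabulary(labels)
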