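"""Ordered-SMARTS functional-group classification of atoms.

Every queried atom is assigned to exactly one functional group: the first
pattern in an ordered SMARTS list whose match contains the atom.  Atoms
matching no pattern fall into a single catch-all class (index ``len(list)``),
which is logged so the list can be extended.  Because assignment is
first-match, the list order matters; :func:`baseline_order` builds the
canonical starting order (aromatic patterns first, longer strings first)
and :func:`optimize_order` searches random reorderings for the one that
maximizes a caller-supplied validation score.

For ¹H spectra the hydrogen's attached carbon is classified and its group
becomes the hydrogen's substructure.

Default pattern lists for the two nuclei ship with the package and are
loaded with :meth:`SmartsList.default`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from itertools import permutations as _all_permutations
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

_DATA_FILES = {"13C": "functional_groups_13c.smarts",
               "1H": "functional_groups_1h.smarts"}

# aromatic primitives: lowercase organic-subset atoms or the ':' bond
_AROMATIC_TOKEN = re.compile(r"(\[[^]]*\b[cnosp]\b[^]]*\]|(?<![A-Z])[cnosp]\d|:)")


class SmartsError(ValueError):
    pass


@dataclass(frozen=True)
class SmartsPattern:
    smarts: str
    name: Optional[str] = None
    aromatic: Optional[bool] = None  # None: infer from the pattern text

    def is_aromatic(self) -> bool:
        if self.aromatic is not None:
            return self.aromatic
        return bool(_AROMATIC_TOKEN.search(self.smarts))


class SmartsList:
    """An ordered, pre-compiled list of SMARTS patterns for one nucleus."""

    def __init__(self, patterns: Sequence, nucleus: str = "13C") -> None:
        self.nucleus = nucleus
        self.patterns = tuple(
            p if isinstance(p, SmartsPattern) else SmartsPattern(p)
            for p in patterns
        )
        self._queries = []
        for p in self.patterns:
            q = Chem.MolFromSmarts(p.smarts)
            if q is None:
                raise SmartsError(f"invalid SMARTS {p.smarts!r}")
            self._queries.append(q)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    @property
    def fallback_class(self) -> int:
        """Class index of the catch-all 'unclassified' group."""
        return len(self.patterns)

    @property
    def n_classes(self) -> int:
        return len(self.patterns) + 1

    def queries(self) -> list:
        return list(self._queries)

    def reordered(self, order: Sequence) -> "SmartsList":
        if sorted(order) != list(range(len(self))):
            raise SmartsError("order must be a permutation of the list")
        return SmartsList([self.patterns[i] for i in order], self.nucleus)

    # -- persistence -------------------------------------------------------

    @classmethod
    def from_stream(cls, stream, nucleus: str = "13C") -> "SmartsList":
        """One SMARTS per line, optional name after a tab."""
        patterns = []
        for line in stream:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            smarts, _, name = line.partition("\t")
            patterns.append(SmartsPattern(smarts.strip(), name.strip() or None))
        return cls(patterns, nucleus)

    @classmethod
    def default(cls, nucleus: str = "13C") -> "SmartsList":
        """The packaged (order-optimized) pattern list for a nucleus."""
        try:
            fname = _DATA_FILES[nucleus]
        except KeyError:
            raise SmartsError(f"no default list for nucleus {nucleus!r}")
        text = resources.files("nmrsubstruct.data").joinpath(fname).read_text()
        return cls.from_stream(text.splitlines(), nucleus)

    def dump(self, stream) -> None:
        for p in self.patterns:
            stream.write(f"{p.smarts}\t{p.name or ''}\n".rstrip() + "\n")


def _resolve_query_atom(graph, atom_index: int, nucleus: str) -> int:
    """0-based RDKit index of the atom to classify.

    In ¹H mode a hydrogen is resolved to its unique attached carbon, whose
    group becomes the hydrogen's substructure.
    """
    element = graph.element(atom_index)
    if nucleus == "13C":
        if element != "C":
            raise SmartsError(
                f"{graph.molecule_id}: atom {atom_index} is {element}, not C"
            )
        return atom_index - 1
    if element == "C":
        return atom_index - 1
    if element != "H":
        raise SmartsError(
            f"{graph.molecule_id}: atom {atom_index} is {element}"
        )
    carbons = [n for n, _ in graph.neighbors(atom_index)
               if graph.element(n) == "C"]
    if len(carbons) != 1:
        raise SmartsError(
            f"{graph.molecule_id}: hydrogen {atom_index} not bonded to "
            "exactly one carbon"
        )
    return carbons[0] - 1


def assign_group(graph, atom_index: int, smarts_list: SmartsList) -> int:
    """First-match class index of an atom, or the fallback class.

    The atom belongs to a pattern's group when it appears anywhere in a
    substructure match of that pattern.
    """
    if graph.mol is None:
        raise SmartsError(f"{graph.molecule_id}: graph lacks an RDKit molecule")
    rd_idx = _resolve_query_atom(graph, atom_index, smarts_list.nucleus)
    for class_index, query in enumerate(smarts_list.queries()):
        for match in graph.mol.GetSubstructMatches(query):
            if rd_idx in match:
                return class_index
    logger.debug(
        "%s: atom %d matched no pattern; fallback class",
        graph.molecule_id, atom_index,
    )
    return smarts_list.fallback_class


def assign_all(graph, smarts_list: SmartsList,
               atom_indices: Optional[Sequence] = None) -> dict:
    """Classify several atoms at once (all carbons by default for ¹³C)."""
    if atom_indices is None:
        atom_indices = [i for i, el in graph.atoms if el == "C"]
    return {i: assign_group(graph, i, smarts_list) for i in atom_indices}


def baseline_order(patterns: Sequence, nucleus: str = "13C") -> SmartsList:
    """Canonical starting order: aromatic block first, then aliphatic;
    within each block longest string first, equal lengths alphabetical."""
    pats = [p if isinstance(p, SmartsPattern) else SmartsPattern(p)
            for p in patterns]
    ordered = sorted(
        pats, key=lambda p: (not p.is_aromatic(), -len(p.smarts), p.smarts)
    )
    return SmartsList(ordered, nucleus)


def optimize_order(smarts_list: SmartsList,
                   score_fn: Callable[[SmartsList], float],
                   n_perm: int = 100,
                   seed: int = 0,
                   exhaustive: bool = False) -> SmartsList:
    """Best-scoring order among the input order and random reorderings.

    ``score_fn`` maps an ordered list to a validation accuracy.  The input
    (baseline) order is always evaluated first, so the result never scores
    below it; ties keep the earliest candidate.  With ``exhaustive=True``
    every permutation is evaluated instead of ``n_perm`` random draws.
    A ``score_fn`` failure on a candidate skips that candidate with a log.
    """
    n = len(smarts_list)
    rng = np.random.default_rng(seed)
    if exhaustive:
        candidates = (list(p) for p in _all_permutations(range(n)))
    else:
        if n_perm < 1:
            raise SmartsError("n_perm must be >= 1")
        candidates = (list(rng.permutation(n)) for _ in range(n_perm))

    best_order = smarts_list
    best_score = score_fn(smarts_list)
    for order in candidates:
        candidate = smarts_list.reordered(order)
        try:
            score = score_fn(candidate)
        except Exception as exc:  # deliberate: skip-and-log per candidate
            logger.warning("scoring failed for order %s: %s", order, exc)
            continue
        if score > best_score:
            best_order, best_score = candidate, score
    return best_order
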