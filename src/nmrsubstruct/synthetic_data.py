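"""Desk-scale synthetic molecule/spectrum fixtures.

The generator emits ``(MolecularGraph, SpectrumRecord)`` pairs in the same
dialect the I/O layer reads, with ground-truth neighbor labels alongside,
so every pipeline stage is testable without any download.  Each carbon's
chemical shift is a deterministic function of its consolidated neighbor
label (a per-class base shift) plus condition effects (a per-solvent
offset and small linear field/temperature terms) plus Gaussian noise;
multiplicities follow the true attached-hydrogen count (0/1/2/3 H →
s/d/t/q).  Conditions are always *applied*; the metadata reporting them
can be dropped independently at a configured rate, emulating the heavy
missingness of public NMR archives.

This is statistical scaffolding, not shift physics: base shifts are an
evenly spaced grid assigned per class, not HOSE- or DFT-level predictions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .io_nmrshiftdb import MolecularGraph, Signal, SpectrumRecord
from .neighbor_encoding import encode_atom

#: Small C/N/O organics used as realistic fixture molecules.
DEFAULT_LIBRARY = (
    "CCO", "CC(C)=O", "CC(=O)O", "CCOC(C)=O", "Cc1ccccc1", "Oc1ccccc1",
    "c1ccncc1", "Nc1ccccc1", "O=Cc1ccccc1", "CCOCC", "CCC#N", "CC#N",
    "CN(C)C=O", "c1cc[nH]c1", "c1ccoc1", "C1CCCCC1", "C1CCC=CC1",
    "CC(C)O", "CCN", "CC=O",
)

#: Named case-study molecules for encoder demonstrations.
CASE_STUDIES = {
    "beta-sitosterol": (
        "CC[C@H](CC[C@@H](C)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](O)CC[C@]4(C)"
        "[C@H]3CC[C@]12C)C(C)C"
    ),
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "cyclopropylbenzene": "c1ccc(cc1)C1CC1",
}

_VALENCE = {"C": 4, "N": 3, "O": 2}
_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}
_H_TO_MULT = {0: "s", 1: "d", 2: "t", 3: "q"}


@dataclass
class ConditionEffects:
    """How acquisition conditions perturb every shift of a record (ppm)."""

    #: Offsets are whole multiples of the default 15-ppm class spacing, so
    #: that a class observed in one solvent aliases onto a different class
    #: in another: the shift alone is then ambiguous and only the solvent
    #: metadata resolves it, which is what makes the metadata ablation bite.
    solvent_offsets: dict = dc_field(
        default_factory=lambda: {"CDCl3": 0.0, "DMSO-d6": 15.0,
                                 "CD3OD": 30.0}
    )
    #: Optional per-(class, solvent) spread of the solvent response (ppm).
    #: Zero by default: the benchmark relies on exact grid aliasing, and a
    #: nonzero spread makes each (class, solvent) band unique again.
    class_jitter_sd: float = 0.0
    field_coefficient: float = 2.0       # ppm at the reference field
    temperature_coefficient: float = 2.0  # ppm at the reference temperature
    field_reference: float = 700.0       # MHz
    temperature_reference: float = 323.0  # K

    @classmethod
    def none(cls) -> "ConditionEffects":
        return cls(solvent_offsets={"CDCl3": 0.0, "DMSO-d6": 0.0,
                                    "CD3OD": 0.0},
                   class_jitter_sd=0.0,
                   field_coefficient=0.0, temperature_coefficient=0.0)

    def offset(self, solvent: str, field: float, temperature: float) -> float:
        return (self.solvent_offsets[solvent]
                + self.field_coefficient * field / self.field_reference
                + self.temperature_coefficient
                * temperature / self.temperature_reference)


@dataclass
class SyntheticConfig:
    n_molecules: int = 200
    atoms_per_molecule: tuple = (4, 9)   # heavy atoms in random graphs
    element_palette: tuple = ("C", "N", "O")
    base_shift_table: Optional[dict] = None  # label -> ppm; grown on demand
    base_shift_start: float = 10.0
    base_shift_gap: float = 15.0         # ppm between consecutive classes
    condition_effects: ConditionEffects = dc_field(
        default_factory=ConditionEffects
    )
    noise_sd: float = 0.5                # ppm
    missing_condition_rate: float = 0.0  # per condition, independent
    library_fraction: float = 0.5
    smiles_library: tuple = DEFAULT_LIBRARY
    field_values: tuple = (300.0, 400.0, 500.0, 600.0, 700.0)
    temperature_range: tuple = (283.0, 323.0)
    double_bond_rate: float = 0.15   # chance a random-graph bond is double
    triple_bond_rate: float = 0.2    # chance a double upgrade goes to triple
    #: Fraction of a molecule's carbons whose signals are listed (at least
    #: one is always kept).  Below 1.0 this emulates partial peak
    #: assignment, so that a record's shift list does not by itself pin
    #: down the molecular structure.
    signal_fraction: float = 1.0
    separable: bool = True
    seed: int = 0

    @classmethod
    def benchmark(cls, seed: int = 0, n_molecules: int = 200
                  ) -> "SyntheticConfig":
        """The canonical desk-scale training benchmark.

        Random C/O single-bonded molecules give a compact, well-supported
        class space; partial peak assignment (60% of carbons listed) keeps
        the per-record shift list from pinning down the structure; solvent
        offsets alias classes onto each other on the 15-ppm grid, so the
        condition metadata carries information no other input provides.
        """
        return cls(n_molecules=n_molecules, element_palette=("C", "O"),
                   atoms_per_molecule=(6, 12), signal_fraction=0.4,
                   library_fraction=0.0, double_bond_rate=0.0,
                   triple_bond_rate=0.0, seed=seed)

    def __post_init__(self) -> None:
        lo, hi = self.atoms_per_molecule
        if not (2 <= lo <= hi):
            raise ValueError("invalid atoms_per_molecule range")
        if not (0.0 <= self.missing_condition_rate <= 1.0):
            raise ValueError("missing_condition_rate outside [0, 1]")
        if self.separable and self.noise_sd > 0:
            if self.base_shift_gap <= 6 * self.noise_sd:
                raise ValueError(
                    "separable mode needs base shifts spaced by > 6*noise_sd"
                )


def _random_tree(rng: np.random.Generator, cfg: SyntheticConfig,
                 molecule_id: str) -> MolecularGraph:
    """Random valence-respecting acyclic molecule over the palette."""
    for _ in range(50):  # retries for the rare sanitization failure
        n = int(rng.integers(cfg.atoms_per_molecule[0],
                             cfg.atoms_per_molecule[1] + 1))
        weights = {"C": 0.7, "N": 0.15, "O": 0.15}
        palette = [e for e in cfg.element_palette if e in _VALENCE]
        p = np.array([weights.get(e, 0.1) for e in palette])
        p /= p.sum()
        elements = ["C"] + [str(rng.choice(palette, p=p))
                            for _ in range(n - 1)]
        remaining = [_VALENCE[e] for e in elements]
        rw = Chem.RWMol()
        for e in elements:
            rw.AddAtom(Chem.Atom(e))
        ok = True
        for child in range(1, n):
            parents = [i for i in range(child) if remaining[i] >= 1]
            if not parents:
                ok = False
                break
            parent = int(rng.choice(parents))
            order = 1
            if (remaining[parent] >= 2 and remaining[child] >= 2
                    and rng.random() < cfg.double_bond_rate):
                order = 2
            if (order == 2 and remaining[parent] >= 3
                    and remaining[child] >= 3
                    and rng.random() < cfg.triple_bond_rate):
                order = 3
            rw.AddBond(parent, child, _BOND_TYPES[order])
            remaining[parent] -= order
            remaining[child] -= order
        if not ok:
            continue
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
            continue
        return MolecularGraph.from_rdkit(mol, molecule_id)
    raise RuntimeError("could not build a valid random molecule")


class ShiftModel:
    """The deterministic part of the synthetic shift function.

    Base shifts sit on an evenly spaced per-class grid (grown on demand in
    class-encounter order); every (class, solvent) pair additionally has a
    fixed jitter offset derived from a stable digest of (seed, class,
    solvent), so it does not depend on query order and two ShiftModels
    built from the same config agree.
    """

    def __init__(self, cfg: SyntheticConfig) -> None:
        self.table = dict(cfg.base_shift_table or {})
        self.effects = cfg.condition_effects
        self._start = cfg.base_shift_start
        self._gap = cfg.base_shift_gap
        self._seed = cfg.seed
        self._jitter_sd = self.effects.class_jitter_sd

    @staticmethod
    def _class_sort_key(label):
        # group classes carrying the same attached-H count (same number of
        # occupied slots, hence the same multiplicity) onto adjacent grid
        # positions, so solvent aliasing crosses within-multiplicity bands
        occupied = sum(1 for a in label.atoms if a != 0)
        return (occupied, label.astuple())

    def assign(self, labels) -> None:
        """Fix grid positions for a label corpus, grouped by slot count."""
        fresh = sorted(
            (lab for lab in set(labels) if lab not in self.table),
            key=self._class_sort_key,
        )
        for lab in fresh:
            self.table[lab] = self._start + self._gap * len(self.table)

    def base(self, label) -> float:
        if label not in self.table:
            self.table[label] = self._start + self._gap * len(self.table)
        return self.table[label]

    def jitter(self, label, solvent: str) -> float:
        if not self._jitter_sd:
            return 0.0
        key = f"{self._seed}|{label}|{solvent}".encode()
        rng = np.random.default_rng(zlib.crc32(key))
        return float(rng.normal(0.0, self._jitter_sd))

    def expected(self, label, solvent: str, field: float,
                 temperature: float) -> float:
        """Noise-free shift of a class under fully known conditions."""
        return (self.base(label)
                + self.effects.offset(solvent, field, temperature)
                + self.jitter(label, solvent))


def generate(cfg: SyntheticConfig,
             shift_model: Optional[ShiftModel] = None) -> tuple:
    """Generate ``(pairs, truth)``: spectrum records plus ground truth.

    ``truth`` is a DataFrame with one row per signal, in the same order
    the signals appear in the records: record_index, molecule_id,
    atom_index, label (comma notation), base_shift, true shift components.
    Fully reproducible from ``cfg.seed``.  Pass in a :class:`ShiftModel`
    built from the same config to share its tables with
    :func:`oracle_classifier`.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = cfg.condition_effects
    model = shift_model if shift_model is not None else ShiftModel(cfg)
    solvents = sorted(effects.solvent_offsets)

    # pass 1: structures, probed atoms and acquisition conditions
    drafts = []
    corpus = []
    for i in range(cfg.n_molecules):
        use_library = (cfg.smiles_library
                       and rng.random() < cfg.library_fraction)
        if use_library:
            smiles = str(rng.choice(cfg.smiles_library))
            graph = MolecularGraph.from_smiles(smiles, f"SYN{i:05d}")
        else:
            graph = _random_tree(rng, cfg, f"SYN{i:05d}")
        solvent = str(rng.choice(solvents))
        fs = float(rng.choice(cfg.field_values))
        temp = float(rng.uniform(*cfg.temperature_range))
        carbons = [idx for idx, el in graph.atoms if el == "C"]
        if cfg.signal_fraction < 1.0:
            keep = max(1, int(round(cfg.signal_fraction * len(carbons))))
            carbons = sorted(
                rng.choice(carbons, size=keep, replace=False).tolist()
            )
        labels = {idx: encode_atom(graph, idx) for idx in carbons}
        corpus.extend(labels.values())
        drop = rng.random(3) < cfg.missing_condition_rate
        drafts.append((graph, solvent, fs, temp, carbons, labels, drop))

    # grid positions are fixed once for the whole corpus so that classes
    # sharing a multiplicity sit on adjacent positions
    model.assign(corpus)

    # pass 2: shifts and records
    pairs = []
    truth_rows = []
    for i, (graph, solvent, fs, temp, carbons, labels, drop) in enumerate(
            drafts):
        signals = []
        for idx in carbons:
            label = labels[idx]
            base = model.base(label)
            offset = model.expected(label, solvent, fs, temp) - base
            noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else 0.0
            shift = base + offset + noise
            n_h = graph.implicit_hydrogens(idx) + sum(
                1 for nbr, _ in graph.neighbors(idx)
                if graph.element(nbr) == "H"
            )
            signals.append(Signal(idx, shift, _H_TO_MULT.get(n_h)))
            truth_rows.append({
                "record_index": i,
                "molecule_id": graph.molecule_id,
                "atom_index": idx,
                "label": str(label),
                "base_shift": base,
                "condition_offset": offset,
                "shift": shift,
            })
        record = SpectrumRecord(
            molecule_id=graph.molecule_id,
            nucleus="13C",
            signals=tuple(signals),
            field_strength=None if drop[0] else fs,
            temperature=None if drop[1] else temp,
            solvent=None if drop[2] else solvent,
        )
        pairs.append((graph, record))
    truth = pd.DataFrame(truth_rows)
    return pairs, truth


def oracle_classifier(pairs: Sequence, truth: pd.DataFrame,
                      shift_model: ShiftModel,
                      use_conditions: bool = True) -> float:
    """Nearest-expected-shift accuracy: the ceiling for trained classifiers.

    With ``use_conditions`` each class's expected shift under the record's
    known conditions is used (a record with missing metadata falls back to
    the bare base for the missing terms); without conditions the raw shift
    is compared to the bare base shifts only.
    """
    labels = list(shift_model.table)
    bases = np.array([shift_model.table[lab] for lab in labels])
    correct = 0
    total = 0
    row = 0
    for _, record in pairs:
        if use_conditions and record.solvent is not None:
            field = (record.field_strength
                     if record.field_strength is not None else 0.0)
            temp = (record.temperature
                    if record.temperature is not None else 0.0)
            centers = np.array([
                shift_model.expected(lab, record.solvent, field, temp)
                for lab in labels
            ])
        else:
            centers = bases
        for s in record.signals:
            want = truth.iloc[row]["label"]
            row += 1
            pred = labels[int(np.argmin(np.abs(s.shift - centers)))]
            correct += str(pred) == want
            total += 1
    return correct / total if total else float("nan")


def misclassification_two_gaussians(gap: float, sd: float) -> float:
    """Bayes error of two equally likely 1-D Gaussian classes ``gap`` apart."""
    return 0.5 * math.erfc(gap / (2.0 * sd) / math.sqrt(2.0))


def case_study_graph(name: str) -> MolecularGraph:
    """One of the named demonstration molecules as a MolecularGraph."""
    return MolecularGraph.from_smiles(CASE_STUDIES[name], name)
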