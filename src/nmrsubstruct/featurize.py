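"""Conversion of spectrum records into model inputs.

Two kinds of input are produced for every signal (= one atom):

* a *fixed* vector — the atom's own chemical shift, its multiplicity index
  (s→1, d→2, t→3, q→4, absent→0) and the acquisition conditions, with
  field strength and temperature divided by their maxima and the solvent
  integer- or one-hot-encoded (missing conditions become 0);
* a *variable* per-molecule sequence — all shifts of the molecule ordered
  from lowest to highest, with the multiplicity indices co-permuted, and
  optionally zero-padded to a fixed length for convolutional models.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

MULTIPLICITY_INDEX = {"s": 1, "d": 2, "t": 3, "q": 4}

#: Fallback normalization maxima when no training split is supplied:
#: 700 MHz (the strongest field in wide use) and 323 K.
DEFAULT_FIELD_MAX = 700.0
DEFAULT_TEMP_MAX = 323.0


class FeaturizationError(ValueError):
    pass


def normalize_condition(value: Optional[float], maximum: float,
                        record_id: str = "") -> float:
    """Divide a condition value by its maximum; missing values become 0."""
    if maximum <= 0:
        raise FeaturizationError(f"maximum must be positive, got {maximum}")
    if value is None:
        return 0.0
    if value > maximum:
        raise FeaturizationError(
            f"condition value {value} exceeds maximum {maximum}"
            + (f" (record {record_id})" if record_id else "")
        )
    if value < 0:
        raise FeaturizationError(f"negative condition value {value}")
    return value / maximum


def encode_multiplicity(symbol: Optional[str]) -> int:
    """s→1, d→2, t→3, q→4; an absent multiplicity encodes as 0."""
    if symbol is None:
        return 0
    try:
        return MULTIPLICITY_INDEX[symbol]
    except KeyError:
        raise FeaturizationError(f"unknown multiplicity symbol {symbol!r}")


@dataclass(frozen=True)
class MoleculeSequence:
    """Shift list of one molecule sorted ascending, multiplicities aligned."""

    shifts: tuple
    multiplicities: tuple  # integer indices, co-permuted with shifts

    def __post_init__(self) -> None:
        if len(self.shifts) != len(self.multiplicities):
            raise FeaturizationError("shift/multiplicity length mismatch")
        if any(b < a for a, b in zip(self.shifts, self.shifts[1:])):
            raise FeaturizationError("shifts not sorted")

    @property
    def length(self) -> int:
        return len(self.shifts)


def build_molecule_sequence(record) -> MoleculeSequence:
    """Order a record's signals from lowest to highest chemical shift.

    Equal shifts are broken deterministically by (multiplicity index,
    atom index), keeping the output invariant to the input signal order.
    """
    if not record.signals:
        raise FeaturizationError(f"{record.molecule_id}: record has no signals")
    keyed = sorted(
        record.signals,
        key=lambda s: (s.shift, encode_multiplicity(s.multiplicity), s.atom_index),
    )
    return MoleculeSequence(
        tuple(s.shift for s in keyed),
        tuple(encode_multiplicity(s.multiplicity) for s in keyed),
    )


class SolventVocabulary:
    """Solvent-name codes assigned by descending training frequency.

    Ties are broken alphabetically; codes start at 1 so that 0 remains the
    missing/unknown sentinel in both the integer and one-hot encodings.
    """

    def __init__(self, names: Iterable) -> None:
        counts = Counter(n for n in names if n is not None)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        self._codes = {name: i + 1 for i, (name, _) in enumerate(ranked)}

    def __len__(self) -> int:
        return len(self._codes)

    def encode(self, name: Optional[str]) -> int:
        if name is None:
            return 0
        return self._codes.get(name, 0)

    def onehot(self, name: Optional[str]) -> np.ndarray:
        """Binary vector of length ``len(self)``; all-zero for missing."""
        vec = np.zeros(len(self._codes), dtype=float)
        code = self.encode(name)
        if code > 0:
            vec[code - 1] = 1.0
        return vec

    @property
    def names(self) -> list:
        return sorted(self._codes, key=self._codes.get)


def encode_solvent(name: Optional[str], vocabulary: SolventVocabulary,
                   onehot: bool = False):
    """Integer code (default) or one-hot vector for a solvent name."""
    return vocabulary.onehot(name) if onehot else vocabulary.encode(name)


def pad_sequence(seq: MoleculeSequence, max_len: int) -> tuple:
    """Zero-pad shifts and multiplicities to ``max_len`` (trailing zeros)."""
    if seq.length > max_len:
        raise FeaturizationError(
            f"sequence of length {seq.length} exceeds max_len {max_len}"
        )
    shifts = np.zeros(max_len, dtype=float)
    mults = np.zeros(max_len, dtype=float)
    shifts[: seq.length] = seq.shifts
    mults[: seq.length] = seq.multiplicities
    return shifts, mults


@dataclass
class FeatureConfig:
    """Featurization settings shared between training and prediction.

    ``shift_scale`` rescales raw ppm values at matrix-assembly time so all
    network inputs are O(1); record-level values stay in ppm.
    """

    field_max: float = DEFAULT_FIELD_MAX
    temp_max: float = DEFAULT_TEMP_MAX
    max_len: Optional[int] = None          # default: longest training molecule
    solvent_onehot: bool = False
    shift_scale: float = 1.0 / 200.0
    #: "absolute": the sequence holds the molecule's shifts as-is;
    #: "relative": each entry is the difference from the probed atom's own
    #: shift, making the context invariant to record-wide offsets
    #: (referencing and condition effects common to the whole spectrum).
    sequence_mode: str = "absolute"
    solvent_names: list = field(default_factory=list)

    def save(self, stream) -> None:
        yaml.safe_dump(self.__dict__, stream)

    @classmethod
    def load(cls, stream) -> "FeatureConfig":
        return cls(**yaml.safe_load(stream))


def fit_feature_config(pairs: Sequence, base: Optional[FeatureConfig] = None
                       ) -> tuple:
    """Derive maxima, max_len and the solvent vocabulary from training pairs.

    Field/temperature maxima are the training maxima where present, else the
    documented fallback constants.
    """
    cfg = FeatureConfig(**(base.__dict__ if base else {}))
    fields = [r.field_strength for _, r in pairs if r.field_strength is not None]
    temps = [r.temperature for _, r in pairs if r.temperature is not None]
    cfg.field_max = max(fields) if fields else DEFAULT_FIELD_MAX
    cfg.temp_max = max(temps) if temps else DEFAULT_TEMP_MAX
    vocab = SolventVocabulary(r.solvent for _, r in pairs)
    cfg.solvent_names = vocab.names
    if cfg.max_len is None:
        cfg.max_len = max(len(r.signals) for _, r in pairs)
    return cfg, vocab


def featurize_pairs(pairs: Sequence, cfg: FeatureConfig,
                    vocab: SolventVocabulary) -> dict:
    """Assemble model-input arrays for every signal of every record.

    Returns a dict with:

    ``fixed``      (n, f) float array — scaled shift, multiplicity index,
                   field_norm, temp_norm, solvent (integer code or one-hot);
    ``seq_shifts`` (n, max_len) zero-padded scaled shift sequences;
    ``seq_mults``  (n, max_len) zero-padded multiplicity sequences;
    ``lengths``    (n,) true sequence lengths;
    ``atom_index`` (n,), ``record_index`` (n,) provenance of each row.
    """
    if cfg.max_len is None:
        raise FeaturizationError("max_len unset; call fit_feature_config first")
    if cfg.sequence_mode not in ("absolute", "relative"):
        raise FeaturizationError(f"unknown sequence_mode {cfg.sequence_mode!r}")
    relative = cfg.sequence_mode == "relative"
    fixed_rows, seq_s, seq_m, lengths, atom_idx, rec_idx = [], [], [], [], [], []
    for ri, (graph, record) in enumerate(pairs):
        seq = build_molecule_sequence(record)
        if seq.length > cfg.max_len:
            raise FeaturizationError(
                f"{record.molecule_id}: {seq.length} signals exceed "
                f"max_len {cfg.max_len}"
            )
        shifts_pad, mults_pad = pad_sequence(seq, cfg.max_len)
        shifts_pad = shifts_pad * cfg.shift_scale
        f_norm = normalize_condition(
            record.field_strength, cfg.field_max, record.molecule_id
        )
        t_norm = normalize_condition(
            record.temperature, cfg.temp_max, record.molecule_id
        )
        if cfg.solvent_onehot:
            solv = list(vocab.onehot(record.solvent))
        else:
            solv = [float(vocab.encode(record.solvent))]
        for s in record.signals:
            fixed_rows.append(
                [s.shift * cfg.shift_scale,
                 float(encode_multiplicity(s.multiplicity)),
                 f_norm, t_norm] + solv
            )
            if relative:
                rel = shifts_pad - s.shift * cfg.shift_scale
                rel[seq.length:] = 0.0
                seq_s.append(rel)
            else:
                seq_s.append(shifts_pad)
            seq_m.append(mults_pad)
            lengths.append(seq.length)
            atom_idx.append(s.atom_index)
            rec_idx.append(ri)
    return {
        "fixed": np.asarray(fixed_rows, dtype=float),
        "seq_shifts": np.asarray(seq_s, dtype=float),
        "seq_mults": np.asarray(seq_m, dtype=float),
        "lengths": np.asarray(lengths, dtype=int),
        "atom_index": np.asarray(atom_idx, dtype=int),
        "record_index": np.asarray(rec_idx, dtype=int),
    }


def zero_conditions(features: dict) -> dict:
    """Copy of a feature dict with the condition columns zeroed.

    Used for the metadata ablation: the fixed vector layout is unchanged but
    field, temperature and solvent carry no information.
    """
    out = {k: v.copy() for k, v in features.items()}
    out["fixed"][:, 2:] = 0.0
    return out


def save_features(features: dict, path) -> None:
    np.savez(path, **features)


def load_features(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
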