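"""Reading and writing of nmrshiftdb2-style spectrum records.

A record is an SDF (V2000) entry: a CTAB molecular graph followed by tagged
property fields carrying the per-atom NMR signals and the experimental
conditions under which the spectrum was acquired.  One SDF entry corresponds
to one spectrum of one molecule; a molecule may legitimately appear several
times with different spectra, and no deduplication is performed.

Property tags of the dialect::

    > <NUCLEUS>          13C or 1H
    > <SIGNALS>          one line per signal: atom_index shift [multiplicity]
    > <FIELD_STRENGTH>   MHz (omitted when unknown)
    > <TEMPERATURE>      K (omitted when unknown)
    > <SOLVENT>          free-text name (omitted when unknown)
    > <Program>          present only on computationally simulated spectra

Records whose spectra were simulated rather than measured are marked by the
presence of a ``Program`` tag; :func:`filter_experimental` drops them.
Malformed entries are skipped with a logged warning, never aborting a file.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about valence oddities in public dumps; the skip-and-log
# policy below is the error surface we expose instead.
RDLogger.DisableLog("rdApp.*")

VALID_NUCLEI = ("13C", "1H")
VALID_MULTIPLICITIES = ("s", "d", "t", "q")


class RecordError(ValueError):
    """A single record could not be parsed or validated."""


@dataclass(frozen=True)
class Signal:
    """One NMR signal assigned to one atom."""

    atom_index: int          # 1-based index into the CTAB
    shift: float             # ppm
    multiplicity: Optional[str] = None  # s/d/t/q for 13C, None when absent


@dataclass
class MolecularGraph:
    """Atom/bond graph parsed from a CTAB, kekulized to integer bond orders.

    ``atoms`` holds ``(index, element_symbol)`` with 1-based contiguous
    indices; ``bonds`` holds ``(i, j, order)`` with order in {1, 2, 3}.
    The RDKit molecule (aromatic perception intact) is kept alongside for
    SMARTS matching; it does not participate in equality.
    """

    molecule_id: str
    atoms: tuple
    bonds: tuple
    mol: Optional[Chem.Mol] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        indices = [i for i, _ in self.atoms]
        if indices != list(range(1, len(indices) + 1)):
            raise RecordError(
                f"{self.molecule_id}: atom indices must be contiguous from 1"
            )
        n = len(indices)
        for i, j, order in self.bonds:
            if i == j or not (1 <= i <= n and 1 <= j <= n):
                raise RecordError(f"{self.molecule_id}: bad bond ({i},{j})")
            if order not in (1, 2, 3):
                raise RecordError(
                    f"{self.molecule_id}: bond order {order} outside 1-3"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def element(self, index: int) -> str:
        return self.atoms[index - 1][1]

    def neighbors(self, index: int) -> list:
        """Explicit neighbors of ``index`` as (atom_index, bond_order)."""
        out = []
        for i, j, order in self.bonds:
            if i == index:
                out.append((j, order))
            elif j == index:
                out.append((i, order))
        return out

    def implicit_hydrogens(self, index: int) -> int:
        """Hydrogens completed from standard valence for a heavy atom.

        CTAB entries in public dumps frequently omit hydrogens; the count
        is recovered from the sanitized RDKit molecule.
        """
        if self.mol is None:
            return 0
        return self.mol.GetAtomWithIdx(index - 1).GetTotalNumHs()

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, molecule_id: str) -> "MolecularGraph":
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        atoms = tuple(
            (a.GetIdx() + 1, a.GetSymbol()) for a in kek.GetAtoms()
        )
        bonds = []
        for b in kek.GetBonds():
            order = int(round(b.GetBondTypeAsDouble()))
            bonds.append(
                (b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1, order)
            )
        return cls(molecule_id, atoms, tuple(sorted(bonds)), mol=mol)

    @classmethod
    def from_smiles(cls, smiles: str, molecule_id: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise RecordError(f"unparseable SMILES for {molecule_id!r}")
        return cls.from_rdkit(mol, molecule_id)


@dataclass
class SpectrumRecord:
    """Per-atom shifts and multiplicities plus acquisition conditions."""

    molecule_id: str
    nucleus: str
    signals: tuple            # of Signal
    field_strength: Optional[float] = None   # MHz
    temperature: Optional[float] = None      # K
    solvent: Optional[str] = None
    provenance: str = "experimental"         # or "computational"

    def __post_init__(self) -> None:
        if self.nucleus not in VALID_NUCLEI:
            raise RecordError(f"unknown nucleus {self.nucleus!r}")
        if self.provenance not in ("experimental", "computational"):
            raise RecordError(f"bad provenance {self.provenance!r}")
        for s in self.signals:
            if s.multiplicity is not None and (
                s.multiplicity not in VALID_MULTIPLICITIES
            ):
                raise RecordError(
                    f"{self.molecule_id}: multiplicity {s.multiplicity!r}"
                )


@dataclass(frozen=True)
class MissingnessSummary:
    """Metadata-missingness accounting for a set of spectrum records.

    ``missing_field`` / ``missing_solvent`` / ``missing_temperature`` are
    marginal counts (that condition missing, regardless of the others);
    the pair fields count exact combinations (exactly that pair missing,
    the third present) and ``missing_all`` is the exact triple.
    """

    total_records: int
    missing_field: int
    missing_solvent: int
    missing_temperature: int
    missing_fs_and_solvent: int
    missing_fs_and_temp: int
    missing_solv_and_temp: int
    missing_all: int

    @property
    def only_field(self) -> int:
        return (
            self.missing_field
            - self.missing_fs_and_solvent
            - self.missing_fs_and_temp
            - self.missing_all
        )

    @property
    def only_solvent(self) -> int:
        return (
            self.missing_solvent
            - self.missing_fs_and_solvent
            - self.missing_solv_and_temp
            - self.missing_all
        )

    @property
    def only_temperature(self) -> int:
        return (
            self.missing_temperature
            - self.missing_fs_and_temp
            - self.missing_solv_and_temp
            - self.missing_all
        )

    @property
    def missing_at_least_one(self) -> int:
        return (
            self.only_field
            + self.only_solvent
            + self.only_temperature
            + self.missing_fs_and_solvent
            + self.missing_fs_and_temp
            + self.missing_solv_and_temp
            + self.missing_all
        )

    @property
    def complete(self) -> int:
        return self.total_records - self.missing_at_least_one

    def report(self) -> str:
        """Plain-text summary, percentages rounded to whole numbers."""

        def pct(x: int) -> str:
            if self.total_records == 0:
                return "n/a"
            return f"{round(100 * x / self.total_records)}%"

        lines = [
            f"records:                       {self.total_records}",
            f"missing field strength:        {self.missing_field}",
            f"missing solvent:               {self.missing_solvent}",
            f"missing temperature:           {self.missing_temperature}",
            f"missing field+solvent only:    {self.missing_fs_and_solvent}",
            f"missing field+temp only:       {self.missing_fs_and_temp}",
            f"missing solvent+temp only:     {self.missing_solv_and_temp}",
            f"missing all three:             {self.missing_all}"
            f"  ({pct(self.missing_all)})",
            f"missing at least one:          {self.missing_at_least_one}"
            f"  ({pct(self.missing_at_least_one)})",
            f"fully specified:               {self.complete}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing


def _split_sdf(stream: TextIO) -> Iterable[str]:
    """Yield raw SDF entries (text up to and excluding the $$$$ line)."""
    chunk: list = []
    for line in stream:
        if line.rstrip("\r\n") == "$$$$":
            yield "".join(chunk)
            chunk = []
        else:
            chunk.append(line)
    if any(line.strip() for line in chunk):
        yield "".join(chunk)


def _parse_properties(text: str) -> dict:
    """Parse the tagged data fields that follow ``M  END``."""
    props: dict = {}
    tag = None
    values: list = []
    for line in text.splitlines():
        if line.startswith(">"):
            if tag is not None:
                props[tag] = "\n".join(values).strip("\n")
            lo, hi = line.find("<"), line.rfind(">")
            if lo == -1 or hi <= lo:
                raise RecordError(f"malformed property header {line!r}")
            tag = line[lo + 1 : hi]
            values = []
        elif tag is not None:
            values.append(line)
    if tag is not None:
        props[tag] = "\n".join(values).strip("\n")
    return props


def _parse_signals(text: str, graph: MolecularGraph, nucleus: str) -> tuple:
    signals = []
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise RecordError(f"bad signal line {line!r}")
        idx = int(parts[0])
        shift = float(parts[1])
        mult = parts[2] if len(parts) == 3 else None
        if not (1 <= idx <= graph.n_atoms):
            raise RecordError(
                f"{graph.molecule_id}: signal atom index {idx} out of range"
            )
        element = graph.element(idx)
        want = "C" if nucleus == "13C" else "H"
        if element != want:
            raise RecordError(
                f"{graph.molecule_id}: {nucleus} signal on {element} atom {idx}"
            )
        if shift != shift or shift in (float("inf"), float("-inf")):
            raise RecordError(f"{graph.molecule_id}: non-finite shift")
        signals.append(Signal(idx, shift, mult))
    return tuple(signals)


def _parse_one(entry: str) -> tuple:
    try:
        mol_part, _, prop_part = entry.partition("M  END")
    except ValueError:  # pragma: no cover - partition never raises
        raise RecordError("no CTAB terminator")
    if not prop_part and "M  END" not in entry:
        raise RecordError("no CTAB terminator 'M  END'")
    molblock = mol_part + "M  END\n"
    molecule_id = entry.splitlines()[0].strip() or "unnamed"
    mol = Chem.MolFromMolBlock(molblock, sanitize=True, removeHs=False)
    if mol is None:
        raise RecordError(f"{molecule_id}: unparseable CTAB")
    graph = MolecularGraph.from_rdkit(mol, molecule_id)

    props = _parse_properties(prop_part)
    nucleus = props.get("NUCLEUS", "13C").strip()
    signals = _parse_signals(props.get("SIGNALS", ""), graph, nucleus)

    def opt_float(tag: str) -> Optional[float]:
        raw = props.get(tag, "").strip()
        return float(raw) if raw else None

    record = SpectrumRecord(
        molecule_id=molecule_id,
        nucleus=nucleus,
        signals=signals,
        field_strength=opt_float("FIELD_STRENGTH"),
        temperature=opt_float("TEMPERATURE"),
        solvent=props.get("SOLVENT", "").strip() or None,
        provenance="computational" if "Program" in props else "experimental",
    )
    return graph, record


def parse_records(stream) -> list:
    """Parse an SDF stream into ``(MolecularGraph, SpectrumRecord)`` pairs.

    ``stream`` may be a text file object or a string.  Malformed entries are
    skipped with a warning; use :func:`parse_records_counted` when the skip
    count matters.
    """
    pairs, _ = parse_records_counted(stream)
    return pairs


def parse_records_counted(stream) -> tuple:
    """As :func:`parse_records` but also return the skipped-record count."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs = []
    skipped = 0
    for entry in _split_sdf(stream):
        try:
            pairs.append(_parse_one(entry))
        except (RecordError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping malformed record: %s", exc)
    return pairs, skipped


def filter_experimental(pairs: Sequence) -> list:
    """Keep only measured spectra, dropping simulated ('Program') records."""
    return [
        (g, r) for g, r in pairs if r.provenance == "experimental"
    ]


def missingness_summary(records: Iterable) -> MissingnessSummary:
    """Tabulate condition-metadata missingness over spectrum records.

    Accepts SpectrumRecords or (graph, record) pairs.
    """
    total = f_ = s_ = t_ = fs = ft = st = fst = 0
    for item in records:
        rec = item[1] if isinstance(item, tuple) else item
        mf = rec.field_strength is None
        ms = rec.solvent is None
        mt = rec.temperature is None
        total += 1
        f_ += mf
        s_ += ms
        t_ += mt
        fs += mf and ms and not mt
        ft += mf and mt and not ms
        st += ms and mt and not mf
        fst += mf and ms and mt
    return MissingnessSummary(total, f_, s_, t_, fs, ft, st, fst)


# ---------------------------------------------------------------------------
# writing


def _format_float(x: float) -> str:
    # repr round-trips exactly through float(), keeping write∘parse lossless
    return repr(float(x))


def write_records(pairs: Sequence, stream: TextIO) -> None:
    """Serialize pairs in the same SDF dialect that ``parse_records`` reads.

    Output is byte-stable for a fixed input ordering, and
    ``parse_records(write_records(x))`` is structurally equal to ``x``.
    """
    for graph, record in pairs:
        if graph.mol is None:
            raise RecordError(
                f"{graph.molecule_id}: graph has no RDKit molecule to write"
            )
        mol = Chem.Mol(graph.mol)
        mol.SetProp("_Name", graph.molecule_id)
        stream.write(Chem.MolToMolBlock(mol, kekulize=True))
        stream.write(f"\n> <NUCLEUS>\n{record.nucleus}\n\n")
        lines = []
        for s in record.signals:
            base = f"{s.atom_index} {_format_float(s.shift)}"
            lines.append(base + (f" {s.multiplicity}" if s.multiplicity else ""))
        stream.write("> <SIGNALS>\n" + "\n".join(lines) + "\n\n")
        if record.field_strength is not None:
            stream.write(
                f"> <FIELD_STRENGTH>\n{_format_float(record.field_strength)}\n\n"
            )
        if record.temperature is not None:
            stream.write(
                f"> <TEMPERATURE>\n{_format_float(record.temperature)}\n\n"
            )
        if record.solvent is not None:
            stream.write(f"> <SOLVENT>\n{record.solvent}\n\n")
        if record.provenance == "computational":
            stream.write("> <Program>\nsimulated\n\n")
        stream.write("$$$$\n")


def dumps_records(pairs: Sequence) -> str:
    buf = io.StringIO()
    write_records(pairs, buf)
    return buf.getvalue()
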