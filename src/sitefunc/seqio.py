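"""Sequence, alignment, and activity-table I/O.

Strict, validating wrappers around Biopython's SeqIO/AlignIO and pandas:
every input either yields a valid object or raises a located error.  No
science lives here.

Supported formats: FASTA for sequence collections; FASTA, Clustal, and
Stockholm for alignments; CSV/TSV (dialect auto-detected from the header
line) for enzyme x substrate activity tables.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: 20 canonical amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"

ALIGNMENT_FORMATS = ("fasta", "clustal", "stockholm")


class SeqIOError(ValueError):
    """Raised for any malformed sequence, alignment, or table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single ungapped protein sequence.

    Residues are upper-case and restricted to the 20 canonical amino
    acids plus ``X``.  Ambiguity codes (B, Z, U, ...) are rejected because
    the numeric property scales downstream are undefined for them.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record with empty id")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r} has no residues")
        _check_alphabet(self.id, self.residues, allow_gap=False)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GappedRecord:
    """A row of an alignment: like :class:`SequenceRecord` but may contain '-'."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("alignment row with empty id")
        _check_alphabet(self.id, self.residues, allow_gap=True)

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), self.description)

    def __len__(self) -> int:
        return len(self.residues)


def _check_alphabet(rec_id: str, residues: str, *, allow_gap: bool) -> None:
    allowed = ALLOWED_RESIDUES | {GAP} if allow_gap else ALLOWED_RESIDUES
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise SeqIOError(
                f"illegal residue character {ch!r} at position {pos} of sequence {rec_id!r}"
            )


def _check_unique_ids(records: Sequence) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


class Alignment:
    """An ordered multiple sequence alignment with a fixed column count.

    All rows have identical length; at least two rows are required; the
    gap character is ``-`` ('.' from Stockholm input is normalized on
    read).  De-gapping any row yields a valid :class:`SequenceRecord`.
    """

    def __init__(self, records: Iterable[GappedRecord]):
        records = list(records)
        if len(records) < 2:
            raise SeqIOError(f"alignment needs at least 2 sequences, got {len(records)}")
        _check_unique_ids(records)
        n_cols = len(records[0])
        for rec in records[1:]:
            if len(rec) != n_cols:
                raise SeqIOError(
                    f"ragged alignment: sequence {rec.id!r} has length "
                    f"{len(rec)}, expected {n_cols}"
                )
        for rec in records:
            rec.ungapped()  # ensures no all-gap rows and a valid alphabet
        self.records: list[GappedRecord] = records
        self.n_columns: int = n_cols
        self._index = {rec.id: i for i, rec in enumerate(records)}

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> GappedRecord:
        try:
            return self.records[self._index[seq_id]]
        except KeyError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return [(r.id, r.residues) for r in self.records] == [
            (r.id, r.residues) for r in other.records
        ]


# ---------------------------------------------------------------------------
# sequences


def read_sequences(path, format: str = "fasta") -> list[SequenceRecord]:
    """Read a collection of ungapped sequences, preserving file order."""
    if format != "fasta":
        raise SeqIOError(f"unsupported sequence format {format!r}")
    raw = list(SeqIO.parse(str(path), format))
    if not raw:
        raise SeqIOError(f"no sequences found in {path}")
    records = [
        SequenceRecord(r.id, str(r.seq).upper(), _strip_id(r.description, r.id))
        for r in raw
    ]
    _check_unique_ids(records)
    return records


def write_sequences(records: Iterable[SequenceRecord], path, format: str = "fasta") -> None:
    if format != "fasta":
        raise SeqIOError(f"unsupported sequence format {format!r}")
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), format)


def _strip_id(description: str, rec_id: str) -> str:
    # Biopython keeps "id rest" in description; store only the free text.
    if description.startswith(rec_id):
        return description[len(rec_id):].strip()
    return description


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an alignment in FASTA, Clustal, or Stockholm format."""
    if format not in ALIGNMENT_FORMATS:
        raise SeqIOError(
            f"unsupported alignment format {format!r}; expected one of {ALIGNMENT_FORMATS}"
        )
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise SeqIOError(f"could not parse {path} as {format}: {exc}") from exc
    records = [
        GappedRecord(
            r.id,
            str(r.seq).upper().replace(".", GAP),
            _strip_id(r.description, r.id),
        )
        for r in msa
    ]
    return Alignment(records)


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    if format not in ALIGNMENT_FORMATS:
        raise SeqIOError(
            f"unsupported alignment format {format!r}; expected one of {ALIGNMENT_FORMATS}"
        )
    msa = MultipleSeqAlignment(
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in alignment.records
    )
    AlignIO.write(msa, str(path), format)


# ---------------------------------------------------------------------------
# activity tables

#: matches "4.58", "4.58 ± 0.18", "4.58 +/- 0.18"
_CELL_RE = re.compile(
    r"^\s*(?P<value>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)"
    r"(?:\s*(?:±|\+/-)\s*(?P<err>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?))?\s*$"
)


@dataclass
class ActivityTable:
    """Enzymes x substrates matrix of observed rates (s^-1).

    ``rates`` holds non-negative floats with ``NaN`` marking a
    below-detection ("not detected") cell; ``errors`` optionally carries
    the "± err" halves of cells, which downstream statistics ignore.
    ``detection_floor`` is the smallest detectable rate and is used when
    below-detection cells are floored for log-scale analysis.
    """

    rates: pd.DataFrame
    detection_floor: float = 1e-3
    errors: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.detection_floor <= 0:
            raise SeqIOError(f"detection_floor must be > 0, got {self.detection_floor}")
        vals = self.rates.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise SeqIOError("negative rate in activity table")
        if self.rates.index.duplicated().any() or self.rates.columns.duplicated().any():
            raise SeqIOError("duplicate enzyme or substrate id in activity table")

    @property
    def enzymes(self) -> list[str]:
        return list(self.rates.index)

    @property
    def substrates(self) -> list[str]:
        return list(self.rates.columns)

    def is_detected(self) -> pd.DataFrame:
        return self.rates.notna()


def read_activity_table(path, nd_marker: str = "n.d.",
                        detection_floor: float = 1e-3) -> ActivityTable:
    """Read a rectangular enzyme x substrate rate table.

    First row: substrate ids; first column: enzyme ids.  Comma or tab
    separation is auto-detected from the header line.  Cells are numbers,
    optionally "value ± error", or the not-detected marker.
    """
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    rates = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    errors = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for enzyme in frame.index:
        for substrate in frame.columns:
            cell = frame.loc[enzyme, substrate]
            cell = "" if pd.isna(cell) else str(cell).strip()
            if cell == nd_marker:
                continue  # below detection -> NaN
            m = _CELL_RE.match(cell)
            if m is None:
                raise SeqIOError(
                    f"cell ({enzyme!r}, {substrate!r}) = {cell!r} is neither a rate "
                    f"nor the marker {nd_marker!r}"
                )
            rates.loc[enzyme, substrate] = float(m.group("value"))
            if m.group("err") is not None:
                errors.loc[enzyme, substrate] = float(m.group("err"))
    return ActivityTable(rates=rates, detection_floor=detection_floor, errors=errors)


def write_activity_table(table: ActivityTable, path, nd_marker: str = "n.d.",
                         sep: str = ",") -> None:
    out = table.rates.astype(object).copy()
    for enzyme in out.index:
        for substrate in out.columns:
            v = table.rates.loc[enzyme, substrate]
            if pd.isna(v):
                out.loc[enzyme, substrate] = nd_marker
            else:
                cell = repr(float(v))
                if table.errors is not None and not pd.isna(
                    table.errors.loc[enzyme, substrate]
                ):
                    cell += f" ± {table.errors.loc[enzyme, substrate]!r}"
                out.loc[enzyme, substrate] = cell
    out.to_csv(path, sep=sep)
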