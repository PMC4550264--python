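"""Aligned-FASTA ingestion, validation and per-site alignment statistics.

The central container is :class:`MultipleAlignment`, a rectangular matrix of
aligned nucleotide characters.  Characters are upper-cased on ingest and RNA
``U`` is normalised to ``T``.  For site classification and for all downstream
distance counting, only the four canonical bases ``A C G T`` are *determinate*;
gaps (``-``), unknowns (``?``, ``N``) and IUPAC ambiguity codes are treated as
missing data (the PAUP*/MEGA convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MultipleAlignment",
    "SiteSummary",
    "AlignmentError",
    "AlignmentShapeError",
    "IdentifierError",
    "AlphabetError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "degap_unique_count",
    "site_summary",
]

#: Canonical determinate nucleotide states.
DETERMINATE = "ACGT"

#: Full accepted alphabet after upper-casing and U->T normalisation.
ALPHABET = frozenset("ACGTN-?" "RYSWKMBDHV")

#: Integer codes used by the packed representation: A=0 C=1 G=2 T=3, missing=4.
MISSING_CODE = 4

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(DETERMINATE):
    _ENCODE[ord(_c)] = _i
for _c in "N-?RYSWKMBDHV":
    _ENCODE[ord(_c)] = MISSING_CODE


class AlignmentError(ValueError):
    """Base class for alignment validation problems."""


class AlignmentShapeError(AlignmentError):
    """Rows of unequal length (the input is not a rectangular alignment)."""


class IdentifierError(AlignmentError):
    """Duplicate or empty sequence identifiers."""


class AlphabetError(AlignmentError):
    """A character outside the accepted nucleotide alphabet."""


@dataclass(frozen=True)
class MultipleAlignment:
    """A validated rectangular multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique, non-empty sequence identifiers (FASTA header token before the
        first whitespace).
    rows
        Aligned sequences, one per id, all of identical length, over the
        alphabet ``{A,C,G,T,N,-,?}`` plus IUPAC ambiguity codes.  Stored
        upper-cased with ``U`` already normalised to ``T``.
    descriptions
        Full FASTA headers (defaults to the ids).
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    descriptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise AlignmentError("alignment has no records")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if not self.descriptions:
            object.__setattr__(self, "descriptions", tuple(self.ids))
        seen: set[str] = set()
        for i in self.ids:
            if not i:
                raise IdentifierError("empty sequence identifier")
            if i in seen:
                raise IdentifierError(f"duplicate sequence identifier: {i!r}")
            seen.add(i)
        length = len(self.rows[0])
        if length == 0:
            raise AlignmentShapeError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"record {sid!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                col = next(k for k, ch in enumerate(row) if ch in bad)
                raise AlphabetError(
                    f"illegal character {row[col]!r} in record {sid!r} at column {col}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]], descriptions: Iterable[str] | None = None
    ) -> "MultipleAlignment":
        """Build an alignment from ``(id, sequence)`` pairs, normalising case and U->T."""
        ids, rows = [], []
        for sid, seq in records:
            ids.append(sid)
            rows.append(seq.upper().replace("U", "T"))
        desc = tuple(descriptions) if descriptions is not None else ()
        return cls(tuple(ids), tuple(rows), desc)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        """Packed ``(n_sequences, length)`` uint8 matrix.

        ``A,C,G,T`` map to ``0..3``; every gap/ambiguity/unknown character maps
        to :data:`MISSING_CODE`.
        """
        buf = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_sequences, self.length)
        return _ENCODE[buf]

    def subset(self, ids: Iterable[str]) -> "MultipleAlignment":
        """Row-subset preserving the given id order."""
        index = {sid: k for k, sid in enumerate(self.ids)}
        sel = [index[i] for i in ids]
        return MultipleAlignment(
            tuple(self.ids[k] for k in sel),
            tuple(self.rows[k] for k in sel),
            tuple(self.descriptions[k] for k in sel),
        )


@dataclass(frozen=True)
class SiteSummary:
    """Per-alignment column classification (gaps-as-missing convention).

    ``n_constant + n_pu + n_pi + n_all_missing == length`` always holds.
    """

    length: int
    n_constant: int
    n_pu: int
    n_pi: int
    n_all_missing: int

    def as_dict(self) -> dict[str, int]:
        return {
            "length": self.length,
            "constant": self.n_constant,
            "pu": self.n_pu,
            "pi": self.n_pi,
            "all_missing": self.n_all_missing,
        }


def read_fasta_alignment(source: Union[str, Path, IO[str]]) -> MultipleAlignment:
    """Read an aligned FASTA file (wrapped or unwrapped) into a :class:`MultipleAlignment`.

    The identifier is the header token before the first whitespace; the full
    header is retained as the description.  Raises :class:`AlignmentShapeError`
    for ragged input, :class:`IdentifierError` for duplicate ids and
    :class:`AlphabetError` for characters outside the nucleotide alphabet.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    return MultipleAlignment.from_records(
        ((r.id, str(r.seq)) for r in records),
        descriptions=(r.description for r in records),
    )


def write_fasta_alignment(
    aln: MultipleAlignment, dest: Union[str, Path, IO[str]], wrap: int = 70
) -> None:
    """Write the alignment as multi-record FASTA (round-trips with the reader)."""
    records = [
        SeqRecord(Seq(row), id=sid, description=desc if desc != sid else "")
        for sid, row, desc in zip(aln.ids, aln.rows, aln.descriptions)
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            _write_records(records, fh, wrap)
    else:
        _write_records(records, dest, wrap)


def _write_records(records: list[SeqRecord], fh: IO[str], wrap: int) -> None:
    writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
    writer.write_file(records)


def to_fasta(aln: MultipleAlignment) -> str:
    """The alignment as a FASTA string."""
    buf = StringIO()
    write_fasta_alignment(aln, buf)
    return buf.getvalue()


def degap_unique_count(aln: MultipleAlignment) -> int:
    """Number of distinct sequences after removing ``-`` and ``?``.

    Two rows that differ only in their gap placement collapse to one.  Used to
    report how many unique barcodes a set of aligned isolates contains.
    """
    table = str.maketrans("", "", "-?")
    return len({row.translate(table) for row in aln.rows})


def site_summary(aln: MultipleAlignment) -> SiteSummary:
    """Classify every column as constant / parsimony-uninformative variable /
    parsimony-informative / effectively missing.

    A column is *parsimony-informative* iff at least two distinct determinate
    states (``A,C,G,T``) each occur in at least two rows; *constant* iff
    exactly one determinate state occurs in two or more rows; columns with
    fewer than two determinate characters are counted separately as
    ``n_all_missing``; the remaining variable columns are uninformative.
    """
    enc = aln.encoded()
    # counts[s, col] = number of rows with state s in that column
    counts = np.stack([(enc == s).sum(axis=0) for s in range(4)])  # (4, L)
    n_det = counts.sum(axis=0)  # determinate characters per column
    n_states = (counts > 0).sum(axis=0)  # distinct determinate states
    n_states_ge2 = (counts >= 2).sum(axis=0)  # states occurring in >=2 rows

    all_missing = n_det < 2
    informative = (~all_missing) & (n_states_ge2 >= 2)
    constant = (~all_missing) & (n_states == 1)
    pu = ~(all_missing | informative | constant)
    return SiteSummary(
        length=aln.length,
        n_constant=int(constant.sum()),
        n_pu=int(pu.sum()),
        n_pi=int(informative.sum()),
        n_all_missing=int(all_missing.sum()),
    )
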