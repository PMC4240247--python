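"""Multiple sequence alignment container and readers.

An :class:`Msa` is the substrate of motif extraction: a rectangular block of
aligned protein sequences over the 20 standard amino acids plus the gap
symbol ``-``.  The first record is, by convention, the query from which
patterns inherit their coordinates.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO

from .matrices import AMINO_ACIDS, GAP

_VALID = set(AMINO_ACIDS) | {GAP}


@dataclass(frozen=True)
class Msa:
    """Equal-length aligned protein sequences with unique identifiers."""

    records: tuple  # of (id, aligned_seq)

    def __post_init__(self):
        records = tuple((str(i), str(s).upper().replace(".", GAP)) for i, s in self.records)
        object.__setattr__(self, "records", records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        ids = [i for i, _ in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dupes}")
        n = len(records[0][1])
        if n < 1:
            raise ValueError("alignment has zero columns")
        for rid, seq in records:
            if len(seq) != n:
                raise ValueError(
                    f"record {rid!r} has length {len(seq)}, expected {n} "
                    "(all aligned sequences must have equal length)"
                )
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"record {rid!r} contains invalid symbols: {sorted(bad)}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list:
        return [i for i, _ in self.records]

    def column(self, j: int) -> list:
        """Residues (and gaps) of column ``j``, in record order."""
        return [seq[j] for _, seq in self.records]

    def ungapped(self, record_index: int = 0) -> str:
        """Gap-stripped sequence of one record (default: the query)."""
        return self.records[record_index][1].replace(GAP, "")


def read_msa(path, fmt: str = None) -> Msa:
    """Read an alignment from aligned-FASTA or Clustal.

    ``fmt`` is ``"fasta"`` or ``"clustal"``; when omitted it is inferred from
    the file suffix (``.aln``/``.clustal`` -> clustal, otherwise fasta).
    """
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    if fmt == "fasta":
        # parse record-by-record so ragged alignments are rejected with the
        # offending record named, rather than by the alignment reader
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        aln = AlignIO.read(str(path), fmt)
        records = [(rec.id, str(rec.seq)) for rec in aln]
    return Msa(tuple(records))


def msa_from_sequences(pairs: Iterable) -> Msa:
    """Build an Msa from ``(id, sequence)`` pairs of equal length.

    This is the trivial aligner used for synthetic data, where homologs are
    generated without indels and therefore align column-for-column.
    """
    return Msa(tuple(pairs))


def write_msa(msa: Msa, path) -> None:
    """Write as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, seq in msa.records:
            fh.write(f">{rid}\n{seq}\n")
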