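"""Conserved-motif extraction from multiple sequence alignments.

Every alignment column is scored by the average pairwise amino-acid exchange
score over all sequence pairs; a motif is a maximal gap-free run of three or
more consecutive columns in which every column is either completely
conserved (one residue across all sequences) or favourably substituted
(average pairwise score at or above a configurable threshold).  Each motif
reports the aligned stretch of every sequence together with its position on
the gap-stripped first (query) sequence, so downstream patterns can anchor
to contiguous query residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from .matrices import (
    DEFAULT_CONSERVATION_THRESHOLD,
    DEFAULT_GAP_SCORE,
    GAP,
    ExchangeMatrix,
    default_matrix,
)
from .msa import Msa


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column conservation summary.

    ``residues`` holds the observed residues (gaps excluded, multiplicity
    preserved); ``avg_pair_score`` is the mean exchange score over all
    unordered sequence pairs, with gapped pairs contributing the gap score.
    """

    col_index: int
    residues: tuple
    gap_count: int
    avg_pair_score: float

    @property
    def has_gap(self) -> bool:
        return self.gap_count > 0

    @property
    def distinct_residues(self) -> frozenset:
        return frozenset(self.residues)

    @property
    def identical(self) -> bool:
        return self.gap_count == 0 and len(self.distinct_residues) == 1


@dataclass(frozen=True)
class Motif:
    """A conserved alignment stretch.

    ``start_col``/``end_col`` are 0-based inclusive alignment columns;
    ``query_anchor`` is the 1-based start position on the gap-stripped first
    sequence of the source alignment.  ``per_sequence_stretches`` holds the
    aligned substring of every sequence over the motif columns.
    """

    start_col: int
    end_col: int
    per_sequence_stretches: tuple  # of (id, substring)
    query_anchor: int

    def __post_init__(self):
        if self.length < 3:
            raise ValueError("a motif spans at least 3 columns")
        for rid, s in self.per_sequence_stretches:
            if len(s) != self.length:
                raise ValueError(f"stretch for {rid!r} has length {len(s)}, expected {self.length}")

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1

    def column_residue_sets(self) -> list:
        """Distinct residues observed at each motif column, left to right."""
        return [
            frozenset(s[j] for _, s in self.per_sequence_stretches)
            for j in range(self.length)
        ]


def column_scores(
    msa: Msa,
    matrix: ExchangeMatrix = None,
    gap_score: float = DEFAULT_GAP_SCORE,
) -> list:
    """Score every alignment column by average pairwise exchange.

    For each column the score is the mean, over all C(n, 2) unordered
    sequence pairs, of the matrix score of the two residues; any pair
    involving a gap contributes ``gap_score``.  Raises ``ValueError`` naming
    the column and symbol if a residue is not covered by the matrix.
    """
    if matrix is None:
        matrix = default_matrix()
    profiles = []
    n = msa.n_seqs
    npairs = n * (n - 1) // 2
    for j in range(msa.n_cols):
        col = msa.column(j)
        for sym in col:
            if sym != GAP and not matrix.covers(sym):
                raise ValueError(
                    f"column {j}: symbol {sym!r} is not covered by matrix {matrix.name}"
                )
        total = 0.0
        for a, b in combinations(col, 2):
            total += gap_score if (a == GAP or b == GAP) else matrix.score(a, b)
        profiles.append(
            ColumnProfile(
                col_index=j,
                residues=tuple(r for r in col if r != GAP),
                gap_count=sum(1 for r in col if r == GAP),
                avg_pair_score=total / npairs,
            )
        )
    return profiles


def is_conserved(
    profile: ColumnProfile,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> bool:
    """Conservation predicate for one column.

    A column qualifies when it is gap-free and either completely conserved
    (identical residue in all sequences) or favourably substituted (average
    pairwise score >= threshold).  Gapped columns never qualify, so motifs
    always map to contiguous residues on every sequence.
    """
    if profile.has_gap:
        return False
    return profile.identical or profile.avg_pair_score >= conservation_threshold


def find_motifs(
    profiles: list,
    msa: Msa,
    min_len: int = 3,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> list:
    """Report maximal conserved runs of ``min_len`` or more columns.

    Returns motifs sorted by start column; runs are maximal and therefore
    disjoint.  ``query_anchor`` is computed on the gap-stripped first
    sequence.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if len(profiles) != msa.n_cols:
        raise ValueError(
            f"profile count ({len(profiles)}) does not match alignment columns ({msa.n_cols})"
        )
    flags = [is_conserved(p, conservation_threshold) for p in profiles]
    query_seq = msa.records[0][1]

    motifs = []
    j = 0
    ncols = msa.n_cols
    while j < ncols:
        if not flags[j]:
            j += 1
            continue
        start = j
        while j < ncols and flags[j]:
            j += 1
        end = j - 1  # inclusive
        if end - start + 1 < min_len:
            continue
        # 1-based position of column `start` on the gap-stripped query;
        # conserved columns are gap-free, so the query has a residue there.
        anchor = sum(1 for c in query_seq[: start + 1] if c != GAP)
        stretches = tuple(
            (rid, seq[start : end + 1]) for rid, seq in msa.records
        )
        motifs.append(
            Motif(
                start_col=start,
                end_col=end,
                per_sequence_stretches=stretches,
                query_anchor=anchor,
            )
        )
    return motifs


def extract_motifs(
    msa: Msa,
    matrix: ExchangeMatrix = None,
    min_len: int = 3,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    gap_score: float = DEFAULT_GAP_SCORE,
) -> list:
    """Convenience: score columns then find motifs in one call."""
    profiles = column_scores(msa, matrix, gap_score)
    return find_motifs(profiles, msa, min_len, conservation_threshold)


def write_motif_report(motifs: list, path, conservation_threshold: float = None) -> None:
    """Write a TSV motif report: id, columns, length, anchor, stretches."""
    path = Path(path)
    with open(path, "w") as fh:
        if conservation_threshold is not None:
            fh.write(f"# conservation_threshold={conservation_threshold}\n")
        fh.write("motif_id\tstart_col\tend_col\tlength\tquery_anchor\tstretches\n")
        for k, m in enumerate(motifs, 1):
            stretches = ";".join(f"{rid}:{s}" for rid, s in m.per_sequence_stretches)
            fh.write(
                f"m{k}\t{m.start_col}\t{m.end_col}\t{m.length}\t{m.query_anchor}\t{stretches}\n"
            )
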