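"""Homolog selection for pattern generation.

Patterns are deduced from an alignment of close-but-not-identical homologs
of the query: hits from a stringent pre-search are kept when their percent
identity to the query lies in a 60-90% window.  If fewer than 10 hits
qualify, the window is relaxed to 40-95% so enough sequences remain to
deduce a conserved pattern.  Both bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrices import GAP


@dataclass(frozen=True)
class IdentityWindow:
    """Inclusive percent-identity bounds used for homolog selection."""

    low: float
    high: float
    name: str

    def __post_init__(self):
        if not 0 <= self.low < self.high <= 100:
            raise ValueError(f"invalid identity window [{self.low}, {self.high}]")

    def contains(self, pid: float) -> bool:
        return self.low <= pid <= self.high


STRICT_WINDOW = IdentityWindow(60.0, 90.0, "strict")
RELAXED_WINDOW = IdentityWindow(40.0, 95.0, "relaxed")


def percent_identity(aligned_query: str, aligned_subject: str) -> float:
    """Percent identity over query-residue columns of a pairwise alignment.

    Counts columns where both sequences carry the same residue, divided by
    the aligned columns in which the query has a residue (gap columns in the
    query are excluded from the denominator).
    """
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned sequences must have equal length")
    query_cols = 0
    identical = 0
    for q, s in zip(aligned_query, aligned_subject):
        if q == GAP:
            continue
        query_cols += 1
        if q == s:
            identical += 1
    if query_cols == 0:
        raise ValueError("query has no residues in the alignment")
    return 100.0 * identical / query_cols


def select_for_patterns(
    hits: list,
    min_count: int = 10,
    strict: IdentityWindow = STRICT_WINDOW,
    relaxed: IdentityWindow = RELAXED_WINDOW,
):
    """Pick hits for pattern generation by identity window.

    Each hit must expose ``percent_identity``.  Hits inside the strict
    window are kept; when fewer than ``min_count`` qualify, the relaxed
    window is applied instead and reported as the window used.

    Returns ``(selected_hits, window_used)``.
    """
    strict_sel = [h for h in hits if strict.contains(h.percent_identity)]
    if len(strict_sel) >= min_count:
        return strict_sel, strict
    relaxed_sel = [h for h in hits if relaxed.contains(h.percent_identity)]
    return relaxed_sel, relaxed
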