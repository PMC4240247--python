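"""PROSITE pattern generation from conserved motifs.

A motif column becomes a pattern element by counting its distinct residues:
one residue is a fixed position, two or three become a bracketed choice, and
four or more are collapsed to the wildcard ``x``.  The raw element list is
then pushed through an ordered filter cascade so that every emitted pattern
simultaneously satisfies the generation rules:

* length between 3 and 15 positions,
* at most 3 allowed residues at any non-wildcard position,
* no two consecutive wildcards (such runs split the pattern in two),
* no leading or trailing wildcard.

The cascade order is: wildcard assignment -> split at double-wildcard runs
-> trim wildcard ends -> greedy left-to-right split of fragments longer
than 15 (re-trimming ends) -> discard fragments shorter than 3.  This is
the only order under which all rules can hold of every output at once.

Only the dialect emitted here is supported by the parser/matcher: fixed
letters, ``[...]`` choices, ``x`` wildcards, joined by ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .matrices import AMINO_ACIDS
from .motifs import Motif

MAX_PATTERN_LEN = 15
MIN_PATTERN_LEN = 3
MAX_CHOICE = 3  # residue preferences above this collapse to a wildcard

_AA_SET = set(AMINO_ACIDS)


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: fixed residue, residue choice, or wildcard."""

    kind: str  # "fixed" | "choice" | "wildcard"
    residues: frozenset

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))
        if self.kind == "fixed" and len(self.residues) != 1:
            raise ValueError("fixed element needs exactly one residue")
        if self.kind == "choice" and not 2 <= len(self.residues) <= MAX_CHOICE:
            raise ValueError(f"choice element needs 2-{MAX_CHOICE} residues")
        if self.kind == "wildcard" and self.residues:
            raise ValueError("wildcard element carries no residues")
        if self.kind not in ("fixed", "choice", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        bad = self.residues - _AA_SET
        if bad:
            raise ValueError(f"non-amino-acid residues in element: {sorted(bad)}")

    @property
    def is_wildcard(self) -> bool:
        return self.kind == "wildcard"

    def accepts(self, residue: str) -> bool:
        return self.is_wildcard or residue in self.residues


WILDCARD = PatternElement("wildcard", frozenset())


def fixed(residue: str) -> PatternElement:
    return PatternElement("fixed", frozenset(residue))


def choice(residues) -> PatternElement:
    return PatternElement("choice", frozenset(residues))


def element_for_residue_set(residues) -> PatternElement:
    """Map a column's distinct-residue set to its pattern element."""
    rs = frozenset(residues)
    if not rs:
        raise ValueError("empty residue set")
    if len(rs) == 1:
        return PatternElement("fixed", rs)
    if len(rs) <= MAX_CHOICE:
        return PatternElement("choice", rs)
    return WILDCARD


def motif_to_elements(motif: Motif) -> list:
    """One element per motif column, by distinct residues across sequences."""
    return [element_for_residue_set(rs) for rs in motif.column_residue_sets()]


def _trim(offset: int, elements: list):
    """Strip leading/trailing wildcards; returns (new offset, elements)."""
    i, j = 0, len(elements)
    while i < j and elements[i].is_wildcard:
        i += 1
    while j > i and elements[j - 1].is_wildcard:
        j -= 1
    return offset + i, elements[i:j]


def filter_cascade_with_offsets(elements: list) -> list:
    """Filter cascade keeping each fragment's offset in the input.

    Returns ``(offset, elements)`` pairs where ``offset`` is the 0-based
    index of the fragment's first element in the original list; used to
    re-anchor patterns on the source query after trimming and splitting.
    """
    if not elements:
        raise ValueError("empty element list")

    # split at every run of >= 2 consecutive wildcards (the run is dropped)
    fragments = []
    cur_start, cur = 0, []
    i = 0
    n = len(elements)
    while i < n:
        if elements[i].is_wildcard and i + 1 < n and elements[i + 1].is_wildcard:
            if cur:
                fragments.append((cur_start, cur))
            while i < n and elements[i].is_wildcard:
                i += 1
            cur_start, cur = i, []
            continue
        cur.append(elements[i])
        i += 1
    if cur:
        fragments.append((cur_start, cur))

    # trim wildcard ends
    fragments = [_trim(off, frag) for off, frag in fragments]

    # greedy left-to-right split of over-long fragments, re-trimming ends
    chunked = []
    for off, frag in fragments:
        for k in range(0, len(frag), MAX_PATTERN_LEN):
            chunked.append(_trim(off + k, frag[k : k + MAX_PATTERN_LEN]))

    # minimum-length rule
    return [(off, frag) for off, frag in chunked if len(frag) >= MIN_PATTERN_LEN]


def filter_cascade(elements: list) -> list:
    """Apply the ordered pattern filters; returns compliant element lists."""
    return [frag for _, frag in filter_cascade_with_offsets(elements)]


def to_prosite(elements: list) -> str:
    """Serialise elements to the emitted PROSITE dialect."""
    parts = []
    for el in elements:
        if el.is_wildcard:
            parts.append("x")
        elif el.kind == "fixed":
            parts.append(next(iter(el.residues)))
        else:
            parts.append("[" + "".join(sorted(el.residues)) + "]")
    return "-".join(parts)


def parse_prosite(text: str) -> list:
    """Parse the emitted PROSITE dialect back to elements.

    Rejects malformed strings with the position (1-based character offset)
    of the first offense.
    """
    if not text:
        raise ValueError("empty pattern string (position 1)")
    elements = []
    pos = 1
    for token in text.split("-"):
        if token == "x":
            elements.append(WILDCARD)
        elif len(token) == 1 and token in _AA_SET:
            elements.append(PatternElement("fixed", frozenset(token)))
        elif token.startswith("[") and token.endswith("]"):
            inner = token[1:-1]
            bad = set(inner) - _AA_SET
            if bad or not 2 <= len(inner) <= MAX_CHOICE or len(set(inner)) != len(inner):
                raise ValueError(f"malformed choice token {token!r} (position {pos})")
            elements.append(PatternElement("choice", frozenset(inner)))
        else:
            raise ValueError(f"malformed pattern token {token!r} (position {pos})")
        pos += len(token) + 1
    return elements


def pattern_matches(pattern, sequence: str) -> list:
    """All 1-based positions where the pattern matches (overlaps allowed).

    ``pattern`` may be a :class:`Pattern`, an element list, or a PROSITE
    string.  The sequence must be gap-free.
    """
    if isinstance(pattern, Pattern):
        elements = pattern.elements
    elif isinstance(pattern, str):
        elements = parse_prosite(pattern)
    else:
        elements = list(pattern)
    if "-" in sequence:
        raise ValueError("pattern matching requires a gap-free sequence")
    m = len(elements)
    hits = []
    for start in range(len(sequence) - m + 1):
        if all(el.accepts(sequence[start + k]) for k, el in enumerate(elements)):
            hits.append(start + 1)
    return hits


@dataclass(frozen=True)
class Pattern:
    """A compliant PROSITE pattern bound to its source query."""

    elements: tuple
    prosite: str
    query_id: str
    query_start: int  # 1-based on the gap-free source query

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        n = len(self.elements)
        if not MIN_PATTERN_LEN <= n <= MAX_PATTERN_LEN:
            raise ValueError(f"pattern length {n} outside [{MIN_PATTERN_LEN}, {MAX_PATTERN_LEN}]")
        if self.elements[0].is_wildcard or self.elements[-1].is_wildcard:
            raise ValueError("pattern must not start or end with a wildcard")
        for a, b in zip(self.elements, self.elements[1:]):
            if a.is_wildcard and b.is_wildcard:
                raise ValueError("pattern must not contain consecutive wildcards")
        if to_prosite(self.elements) != self.prosite:
            raise ValueError("prosite string does not round-trip to elements")

    @property
    def length(self) -> int:
        return len(self.elements)

    def matches(self, sequence: str) -> list:
        return pattern_matches(self.elements, sequence)


def patterns_from_motif(motif: Motif, query_id: str = None, query_seq: str = None) -> list:
    """Full motif -> pattern pipeline for one motif.

    The source query defaults to the first sequence of the motif's
    alignment.  Each cascade fragment is re-anchored on the gap-free query
    by its column offset (motif columns are gap-free, so column offsets and
    residue offsets coincide) and verified to match there.
    """
    if query_id is None:
        query_id = motif.per_sequence_stretches[0][0]
    elements = motif_to_elements(motif)
    patterns = []
    for offset, frag in filter_cascade_with_offsets(elements):
        start = motif.query_anchor + offset
        pat = Pattern(
            elements=tuple(frag),
            prosite=to_prosite(frag),
            query_id=query_id,
            query_start=start,
        )
        if query_seq is not None and start not in pat.matches(query_seq):
            raise AssertionError(
                f"pattern {pat.prosite} does not match its source query at {start}"
            )
        patterns.append(pat)
    return patterns


def write_patterns(patterns: list, path) -> None:
    """One PROSITE pattern per line, preceded by a query-anchor comment."""
    with open(path, "w") as fh:
        for pat in patterns:
            fh.write(f"# query={pat.query_id} start={pat.query_start}\n")
            fh.write(pat.prosite + "\n")


def read_patterns(path) -> list:
    """Inverse of :func:`write_patterns`."""
    patterns = []
    query_id, start = None, None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = dict(
                    tok.split("=", 1) for tok in line.lstrip("# ").split() if "=" in tok
                )
                query_id = fields.get("query")
                start = int(fields["start"]) if "start" in fields else None
                continue
            if query_id is None or start is None:
                raise ValueError(f"line {lineno}: pattern without a query header")
            elements = parse_prosite(line)
            patterns.append(
                Pattern(tuple(elements), to_prosite(elements), query_id, start)
            )
            query_id, start = None, None
    return patterns
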