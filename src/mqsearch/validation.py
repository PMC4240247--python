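"""True-positive validation of pooled hits against superfamily HMM verdicts.

A hit is a true positive when an HMM-library scan (E <= 0.01) associates it
with exactly the query's superfamily; any cross-superfamily association is
a false positive even within the same fold.  Hits the superfamily-level
library cannot place may be retried on a fallback single-query-HMM library;
hits that still match nothing are tracked as "unvalidated" — they count
against precision but are not cross-superfamily errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

DEFAULT_VALIDATION_EVALUE = 0.01

TP = "TP"
FP = "FP"
UNVALIDATED = "unvalidated"


@dataclass(frozen=True)
class ValidationVerdict:
    """Per-GI validation outcome."""

    gi: str
    matched_superfamily_ids: tuple
    best_evalue: float = None  # None when nothing matched
    label: str = UNVALIDATED

    def __post_init__(self):
        object.__setattr__(
            self, "matched_superfamily_ids", tuple(self.matched_superfamily_ids)
        )
        if self.label not in (TP, FP, UNVALIDATED):
            raise ValueError(f"unknown verdict label {self.label!r}")


@runtime_checkable
class ValidationBackend(Protocol):
    """Contract for an HMM-library scanner (mock or hmmscan adapter)."""

    level: str  # "superfamily_hmm" | "single_query_hmm"

    def scan(self, gi: str):
        """Return ``[(superfamily_id, evalue), ...]`` associations for a GI."""
        ...


@dataclass
class MockValidationBackend:
    """Lookup-table verdict backend: ``gi -> [(superfamily_id, evalue)]``."""

    table: dict
    level: str = "superfamily_hmm"
    fail_on: frozenset = field(default_factory=frozenset)

    def scan(self, gi: str):
        if gi in self.fail_on:
            raise RuntimeError(f"simulated backend failure for {gi}")
        return list(self.table.get(gi, ()))


def _verdict_for(gi, associations, target_superfamily, evalue):
    """Label one GI from its reported HMM associations.

    The backend reports associations at its own library operating
    threshold; any reported cross-superfamily association is an error
    regardless of the tunable ``evalue``, which gates only whether the
    target association is significant enough to validate the hit.  This
    keeps labelling monotone: tightening ``evalue`` can demote a TP to
    unvalidated but can never promote an FP.
    """
    if not associations:
        return None
    matched = sorted({sf for sf, _ in associations})
    best = min(e for _, e in associations)
    if any(sf != target_superfamily for sf in matched):
        label = FP
    elif any(sf == target_superfamily and e <= evalue for sf, e in associations):
        label = TP
    else:
        label = UNVALIDATED
    return ValidationVerdict(gi, tuple(matched), best, label)


def validate_hits(
    gis,
    target_superfamily: str,
    backend: ValidationBackend,
    evalue: float = DEFAULT_VALIDATION_EVALUE,
    fallback_backend: ValidationBackend = None,
) -> dict:
    """Label every unique GI as TP, FP or unvalidated.

    GIs that the primary (superfamily-level) backend cannot associate with
    any superfamily are retried on the fallback backend when one is given.
    A backend failure leaves the affected GI unvalidated rather than
    aborting the run.  Returns ``{gi: ValidationVerdict}``; the labels
    partition the input set.
    """
    verdicts = {}
    for gi in sorted(set(gis)):
        verdict = None
        for be in (backend, fallback_backend):
            if be is None:
                continue
            try:
                associations = be.scan(gi)
            except Exception:
                continue
            verdict = _verdict_for(gi, associations, target_superfamily, evalue)
            if verdict is not None:
                break
        if verdict is None:
            verdict = ValidationVerdict(gi, (), None, UNVALIDATED)
        verdicts[gi] = verdict
    return verdicts


def tp_set(verdicts: dict) -> set:
    return {gi for gi, v in verdicts.items() if v.label == TP}


def fp_set(verdicts: dict) -> set:
    return {gi for gi, v in verdicts.items() if v.label == FP}


@dataclass(frozen=True)
class StructuralReport:
    """Single-superfamily association check for structural (PDB-like) hits."""

    per_entry_single_association: dict  # gi -> bool
    cross_superfamily_count: int


def structural_entry_check(structural_gis, verdicts: dict) -> StructuralReport:
    """Check that each structural hit associates with exactly one superfamily.

    ``structural_gis`` are the hits flagged as structural entries;
    ``verdicts`` is the output of :func:`validate_hits`.  The aggregate
    count is the number of structural entries with a cross-superfamily
    association (more than one matched superfamily, or an FP label).
    """
    per_entry = {}
    cross = 0
    for gi in sorted(set(structural_gis)):
        v = verdicts.get(gi)
        matched = v.matched_superfamily_ids if v is not None else ()
        single = len(set(matched)) == 1
        per_entry[gi] = single
        if len(set(matched)) > 1:
            cross += 1
    return StructuralReport(per_entry, cross)


def write_verdicts_tsv(verdicts: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gi\tlabel\tmatched_ids\tbest_evalue\n")
        for gi in sorted(verdicts):
            v = verdicts[gi]
            matched = ",".join(v.matched_superfamily_ids)
            best = "" if v.best_evalue is None else f"{v.best_evalue:.3g}"
            fh.write(f"{gi}\t{v.label}\t{matched}\t{best}\n")
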