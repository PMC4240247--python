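"""Deterministic mock search backend over a labelled sequence database.

The mock reproduces the qualitative dynamics of an iterative profile
search without an external engine: per iteration the included set grows by
transitive identity neighbours of the current profile, convergence is
reached when an iteration adds nothing new, and pattern-constrained runs
intersect the first iteration's candidates with the sequences the pattern
matches — the behaviour that makes pattern-constrained searches stringent
at the start.

Similarity model: percent identity is the fraction of matching positions
over the longer sequence (the synthetic data contains no indels), mapped to
a pseudo E-value by ``log10 E = 11 - 0.35 * pid``.  The calibration anchors
pid ~40 at the default 1e-3 threshold and pid 60 at the stringent 1e-10
pattern-prep threshold, so homologs in the 60-90% pattern window pass the
stringent pre-search while random decoys (~5% identity) are far outside
every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .patterns import pattern_matches
from .search import HitRecord, QueryRun, SearchConfig


@dataclass(frozen=True)
class DbRecord:
    """One database sequence with its ground-truth label."""

    gi: str
    seq: str
    label: str  # "homolog" | "decoy"
    member_id: str = None  # the member this homolog derives from
    superfamily_id: str = None
    is_structural: bool = False

    def __post_init__(self):
        if self.label not in ("homolog", "decoy"):
            raise ValueError(f"unknown database label {self.label!r}")


def mock_percent_identity(a: str, b: str) -> float:
    """Alignment-free identity: matching positions over the longer length."""
    if not a or not b:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / max(len(a), len(b))


def mock_evalue(pid: float) -> float:
    """Pseudo E-value from percent identity: ``10 ** (11 - 0.35 * pid)``."""
    return 10.0 ** (11.0 - 0.35 * pid)


@dataclass
class MockSearchBackend:
    """In-memory search engine over a labelled database.

    ``drift_after`` maps a query id to the last iteration in which the
    query is retained in its own profile, emulating PSSM corruption (query
    drift); queries not listed are retained throughout.
    """

    database: list  # of DbRecord
    drift_after: dict = field(default_factory=dict)

    profile_iterative = True
    pattern_constrained = True

    def __post_init__(self):
        gis = [r.gi for r in self.database]
        if len(set(gis)) != len(gis):
            raise ValueError("database GIs must be unique")

    def run_profile(self, query_id: str, query_seq: str, config: SearchConfig):
        return self._run(query_id, query_seq, config, pattern=None)

    def run_pattern(self, query_id: str, query_seq: str, pattern, config: SearchConfig):
        return self._run(query_id, query_seq, config, pattern=pattern)

    def _run(self, query_id: str, query_seq: str, config: SearchConfig, pattern):
        profile_seqs = [query_seq]
        included: dict = {}  # gi -> HitRecord
        iteration_sets = []
        presence = []
        converged = False
        for it in range(1, config.max_iterations + 1):
            new_records = []
            for rec in self.database:
                if rec.gi in included:
                    continue
                best_e = min(
                    mock_evalue(mock_percent_identity(rec.seq, pseq))
                    for pseq in profile_seqs
                )
                if best_e > config.inclusion_threshold:
                    continue
                if pattern is not None and it == 1 and not pattern_matches(pattern, rec.seq):
                    continue
                span = min(len(rec.seq), len(query_seq))
                new_records.append(
                    HitRecord(
                        gi=rec.gi,
                        evalue=best_e,
                        percent_identity=mock_percent_identity(rec.seq, query_seq),
                        query_range=(1, span),
                        subject_range=(1, span),
                        iteration_found=it,
                    )
                )
            for rec_hit in new_records:
                included[rec_hit.gi] = rec_hit
            profile_seqs = [query_seq] + [
                r.seq for r in self.database if r.gi in included
            ]
            iteration_sets.append(frozenset(included))
            drift = self.drift_after.get(query_id)
            presence.append(drift is None or it <= drift)
            if not new_records:
                converged = True
                break
        run = QueryRun(
            query_id=query_id,
            iterations=tuple(iteration_sets),
            converged=converged,
            query_present_per_iteration=tuple(presence),
        )
        hits = [h for h in included.values() if h.evalue <= config.evalue_threshold]
        return run, hits
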