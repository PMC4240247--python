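"""MQ and MPMQ search orchestration over a pluggable backend.

The multiple-query (MQ) strategy runs an iterative profile search from
every member of a superfamily and pools the unique hit identifiers (GIs);
the multiple-pattern-multiple-query (MPMQ) strategy additionally constrains
each member's searches with its PROSITE patterns, one search per
(member, pattern) pair, giving many specific start points in sequence
space.  Backends are abstract: anything implementing :class:`SearchBackend`
(the shipped deterministic mock, or an external engine adapter) can drive
either strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable


@dataclass(frozen=True)
class SearchConfig:
    """Iterative-search thresholds.

    ``evalue_threshold`` filters reported hits, ``inclusion_threshold``
    gates profile inclusion; both default to 0.001 with at most 20
    iterations.  The ``pattern_prep`` preset (1e-10, 1e-10, 10 iterations)
    reproduces the stringent pre-search used to collect homologs for
    pattern generation.
    """

    evalue_threshold: float = 1e-3
    inclusion_threshold: float = 1e-3
    max_iterations: int = 20
    preset: str = "default"

    def __post_init__(self):
        if self.evalue_threshold <= 0 or self.inclusion_threshold <= 0:
            raise ValueError("E-value and inclusion thresholds must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @classmethod
    def pattern_prep(cls) -> "SearchConfig":
        return cls(1e-10, 1e-10, 10, "pattern_prep")


@dataclass(frozen=True)
class HitRecord:
    """One reported homolog from a search run."""

    gi: str
    evalue: float
    percent_identity: float
    query_range: tuple  # 1-based inclusive (start, end)
    subject_range: tuple
    iteration_found: int

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        for lo, hi in (self.query_range, self.subject_range):
            if not (1 <= lo <= hi):
                raise ValueError(f"malformed range ({lo}, {hi})")
        if self.iteration_found < 1:
            raise ValueError("iteration_found is 1-based")


@dataclass(frozen=True)
class QueryRun:
    """Iteration-by-iteration trace of one query's search."""

    query_id: str
    iterations: tuple  # per-iteration frozensets of included hit ids
    converged: bool
    query_present_per_iteration: tuple  # booleans, same length

    def __post_init__(self):
        object.__setattr__(self, "iterations", tuple(frozenset(s) for s in self.iterations))
        object.__setattr__(
            self, "query_present_per_iteration", tuple(bool(b) for b in self.query_present_per_iteration)
        )
        if len(self.iterations) != len(self.query_present_per_iteration):
            raise ValueError("iteration trace lengths disagree")

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


@runtime_checkable
class SearchBackend(Protocol):
    """Contract for iterative search engines (mock or external adapter)."""

    profile_iterative: bool
    pattern_constrained: bool

    def run_profile(self, query_id: str, query_seq: str, config: SearchConfig):
        """Iterative profile search; returns ``(QueryRun, [HitRecord])``."""
        ...

    def run_pattern(self, query_id: str, query_seq: str, pattern, config: SearchConfig):
        """Pattern-constrained search; returns ``(QueryRun, [HitRecord])``."""
        ...


class BackendError(RuntimeError):
    """Raised by a backend when one search cannot be completed."""


@dataclass
class MQResult:
    """Per-member traces and hits of a multiple-query search."""

    per_member_hits: dict  # member_id -> list[HitRecord]
    runs: dict  # member_id -> QueryRun
    failed_members: list = field(default_factory=list)

    def gi_set(self, member_id: str) -> set:
        return {h.gi for h in self.per_member_hits[member_id]}

    def gi_sets(self) -> dict:
        return {m: self.gi_set(m) for m in self.per_member_hits}

    def pooled(self) -> set:
        return pool_unique(self.gi_sets().values())


@dataclass
class MPMQResult:
    """Per-(member, pattern) hits of a multiple-pattern-multiple-query search."""

    per_pair_hits: dict  # (member_id, pattern_index) -> list[HitRecord]
    runs: dict  # (member_id, pattern_index) -> QueryRun
    skipped_members: list = field(default_factory=list)
    failed_pairs: list = field(default_factory=list)

    def member_gi_sets(self) -> dict:
        pooled: dict = {}
        for (member, _), hits in self.per_pair_hits.items():
            pooled.setdefault(member, set()).update(h.gi for h in hits)
        return pooled

    def pooled(self) -> set:
        return pool_unique(self.member_gi_sets().values())


def run_mq(members: list, backend: SearchBackend, config: SearchConfig = None) -> MQResult:
    """Run an iterative profile search from every superfamily member.

    ``members`` is a list of ``(member_id, sequence)``.  A backend failure
    on one member marks that member failed without aborting the rest.  All
    alignment regions of every hit are retained (no per-hit filtering
    beyond the E-value threshold the backend applies).
    """
    if not members:
        raise ValueError("at least one member query is required")
    if not getattr(backend, "profile_iterative", False):
        raise ValueError("backend does not support profile-iterative search")
    config = config or SearchConfig()
    result = MQResult(per_member_hits={}, runs={})
    for member_id, seq in members:
        try:
            run, hits = backend.run_profile(member_id, seq, config)
        except BackendError:
            result.failed_members.append(member_id)
            continue
        result.per_member_hits[member_id] = list(hits)
        result.runs[member_id] = run
    return result


def run_mpmq(
    members: list,
    patterns_per_member: dict,
    backend: SearchBackend,
    config: SearchConfig = None,
) -> MPMQResult:
    """Run one pattern-constrained search per (member, pattern) pair.

    Members with zero patterns are skipped with a record in
    ``skipped_members``.  Every pattern's ``query_id`` must name a member.
    """
    if not getattr(backend, "pattern_constrained", False):
        raise ValueError("backend does not support pattern-constrained search")
    config = config or SearchConfig()
    member_ids = {m for m, _ in members}
    for member, pats in patterns_per_member.items():
        for pat in pats:
            if pat.query_id not in member_ids:
                raise ValueError(
                    f"pattern {pat.prosite} names unknown query {pat.query_id!r}"
                )
    result = MPMQResult(per_pair_hits={}, runs={})
    for member_id, seq in members:
        pats = patterns_per_member.get(member_id, [])
        if not pats:
            result.skipped_members.append(member_id)
            continue
        for k, pat in enumerate(pats):
            try:
                run, hits = backend.run_pattern(member_id, seq, pat, config)
            except BackendError:
                result.failed_pairs.append((member_id, k))
                continue
            result.per_pair_hits[(member_id, k)] = list(hits)
            result.runs[(member_id, k)] = run
    return result


def pool_unique(hit_sets) -> set:
    """Cumulative set of unique GIs: the union of the given sets."""
    pooled: set = set()
    for s in hit_sets:
        pooled |= set(s)
    return pooled


def retention_trace(run: QueryRun) -> int:
    """Quartile bin (1-4) of the last iteration where the query was present.

    The N iterations of a run are divided into four bins with upper limits
    ceil(k*N/4) for k = 1..4 (for N = 16: iterations 4, 8, 12, 16).  Returns
    0 when the query was never present (immediate profile drift).
    """
    n = run.n_iterations
    if n < 1:
        raise ValueError("run has no iterations")
    last = 0
    for i, present in enumerate(run.query_present_per_iteration, 1):
        if present:
            last = i
    if last == 0:
        return 0
    for k in (1, 2, 3, 4):
        if last <= math.ceil(k * n / 4):
            return k
    raise AssertionError("unreachable: last iteration exceeds bin 4 limit")
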