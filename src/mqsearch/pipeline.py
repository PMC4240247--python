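"""End-to-end workflow: fixtures -> patterns -> MQ/MPMQ -> validation -> stats.

`run_all` reproduces the full search strategy on a synthetic superfamily
(or any pre-built member list + database): a stringent pre-search collects
each member's 60-90% identity homologs, patterns are deduced from their
alignment, the MQ (profile) and MPMQ (pattern-constrained) strategies are
run over the backend, hits are validated against the superfamily verdict
table, and the coverage statistics are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import coverage as cov
from .backends import MockSearchBackend
from .fixtures import FixtureSpec, SuperfamilyFixture, build_validation_table, make_superfamily
from .homologs import select_for_patterns
from .matrices import DEFAULT_CONSERVATION_THRESHOLD
from .motifs import extract_motifs
from .msa import msa_from_sequences
from .patterns import patterns_from_motif, write_patterns
from .search import SearchConfig, run_mq, run_mpmq
from .validation import (
    MockValidationBackend,
    structural_entry_check,
    tp_set,
    validate_hits,
    write_verdicts_tsv,
)


@dataclass
class PipelineResult:
    """Everything one `run_all` invocation computed."""

    fixture: SuperfamilyFixture
    patterns_per_member: dict
    mq: object
    mpmq: object
    verdicts_mq: dict
    verdicts_mpmq: dict
    result_mq: cov.SuperfamilyResult
    result_mpmq: cov.SuperfamilyResult
    overlap: dict
    named_sets: dict
    retention_histogram: dict
    levels: cov.CoverageLevels
    report: dict = field(repr=False, default=None)


def generate_patterns_for_member(
    member_id: str,
    member_seq: str,
    backend,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    gi_to_seq: dict = None,
) -> list:
    """Pattern-generation leg for one member.

    Runs the stringent pre-search (1e-10, max 10 iterations), keeps hits in
    the 60-90% identity window (relaxed to 40-95% when fewer than 10
    qualify), aligns them to the query column-for-column (the synthetic
    data carries no indels), and converts every conserved motif into
    compliant PROSITE patterns anchored on the member.
    """
    if gi_to_seq is None:
        gi_to_seq = {r.gi: r.seq for r in backend.database}
    _, hits = backend.run_profile(member_id, member_seq, SearchConfig.pattern_prep())
    selected, _window = select_for_patterns(hits)
    rows = [(member_id, member_seq)]
    seen = {member_id}
    for h in selected:
        seq = gi_to_seq.get(h.gi)
        if seq is None or len(seq) != len(member_seq) or h.gi in seen:
            continue
        rows.append((h.gi, seq))
        seen.add(h.gi)
    if len(rows) < 2:
        return []
    msa = msa_from_sequences(rows)
    patterns = []
    for motif in extract_motifs(msa, conservation_threshold=conservation_threshold):
        patterns.extend(patterns_from_motif(motif, query_id=member_id, query_seq=member_seq))
    return patterns


def run_all(
    spec: FixtureSpec = None,
    fixture: SuperfamilyFixture = None,
    config: SearchConfig = None,
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    validation_backend=None,
    fallback_backend=None,
    outdir=None,
) -> PipelineResult:
    """Run the complete search strategy on one superfamily.

    Provide either a :class:`FixtureSpec` (a fixture is generated) or a
    pre-built fixture.  ``validation_backend`` defaults to the fixture's
    ground-truth verdict table.  When ``outdir`` is given, all artefacts
    (FASTA, patterns, hit tables, verdicts, reports, provenance) are
    written there.
    """
    if fixture is None:
        if spec is None:
            spec = FixtureSpec()
        fixture = make_superfamily(spec)
    config = config or SearchConfig()
    sf = fixture.superfamily_id
    backend = MockSearchBackend(fixture.database)
    gi_to_seq = {r.gi: r.seq for r in fixture.database}

    patterns_per_member = {
        member_id: generate_patterns_for_member(
            member_id, seq, backend, conservation_threshold, gi_to_seq
        )
        for member_id, seq in fixture.members
    }

    mq = run_mq(fixture.members, backend, config)
    mpmq = run_mpmq(fixture.members, patterns_per_member, backend, config)

    if validation_backend is None:
        validation_backend = MockValidationBackend(build_validation_table(fixture))

    def validated(member_sets: dict):
        pooled = set().union(*member_sets.values()) if member_sets else set()
        verdicts = validate_hits(pooled, sf, validation_backend, fallback_backend=fallback_backend)
        tps = tp_set(verdicts)
        per_member_tp = {m: s & tps for m, s in member_sets.items()}
        return verdicts, per_member_tp, pooled

    verdicts_mq, tp_mq, pooled_mq = validated(mq.gi_sets())
    verdicts_mpmq, tp_mpmq, pooled_mpmq = validated(mpmq.member_gi_sets())

    result_mq = cov.SuperfamilyResult.from_tp_sets(sf, tp_mq, pooled_mq)
    result_mpmq = cov.SuperfamilyResult.from_tp_sets(sf, tp_mpmq, pooled_mpmq)

    named_sets = {
        "MPMQ": pooled_mpmq,
        "MQ": pooled_mq,
        "BRS-pattern": mpmq.member_gi_sets().get(result_mpmq.brs_member, set()),
        "BRS-profile": mq.gi_set(result_mq.brs_member),
    }
    overlap = cov.approach_overlap(named_sets)
    retention = cov.retention_histogram(mq.runs.values())

    structural = structural_entry_check(
        fixture.structural_gis() & pooled_mq, verdicts_mq
    )
    member_ids = [m for m, _ in fixture.members]
    levels = cov.compute_coverage_levels(
        result_mq.cum_tp_set,
        member_gis=member_ids,
        structural_report=structural,
    )

    report = cov.coverage_report(
        [result_mq, result_mpmq],
        levels={sf: levels},
        retention_runs={sf: list(mq.runs.values())},
    )

    result = PipelineResult(
        fixture=fixture,
        patterns_per_member=patterns_per_member,
        mq=mq,
        mpmq=mpmq,
        verdicts_mq=verdicts_mq,
        verdicts_mpmq=verdicts_mpmq,
        result_mq=result_mq,
        result_mpmq=result_mpmq,
        overlap=overlap,
        named_sets=named_sets,
        retention_histogram=retention,
        levels=levels,
        report=report,
    )
    if outdir is not None:
        _write_outputs(result, config, conservation_threshold, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, config: SearchConfig, threshold: float, outdir: Path):
    from . import io as mio

    outdir.mkdir(parents=True, exist_ok=True)
    fixture = result.fixture
    mio.write_fasta(fixture.members, outdir / "members.fasta")
    mio.write_database_fasta(fixture.database, outdir / "database.fasta")
    all_patterns = [p for pats in result.patterns_per_member.values() for p in pats]
    write_patterns(all_patterns, outdir / "patterns.prosite")
    mio.write_hits_tsv(
        (h for hits in result.mq.per_member_hits.values() for h in hits),
        outdir / "hits_mq.tsv",
    )
    mio.write_hits_tsv(
        (h for hits in result.mpmq.per_pair_hits.values() for h in hits),
        outdir / "hits_mpmq.tsv",
    )
    mio.write_runs_jsonl(result.mq.runs.values(), outdir / "runs_mq.jsonl")
    write_verdicts_tsv(result.verdicts_mq, outdir / "verdicts_mq.tsv")
    write_verdicts_tsv(result.verdicts_mpmq, outdir / "verdicts_mpmq.tsv")
    cov.write_report(result.report, outdir / "reports")
    spec = fixture.spec
    mio.write_provenance(
        outdir / "provenance.yaml",
        seed=None if spec is None else spec.seed,
        superfamily=fixture.superfamily_id,
        evalue_threshold=config.evalue_threshold,
        inclusion_threshold=config.inclusion_threshold,
        max_iterations=config.max_iterations,
        conservation_threshold=threshold,
    )
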