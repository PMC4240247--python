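"""Search orchestration: MQ/MPMQ over the mock backend, pooling, retention."""

import math

import pytest

from mqsearch import (
    FixtureSpec,
    MockSearchBackend,
    QueryRun,
    SearchConfig,
    make_superfamily,
    pool_unique,
    retention_trace,
    run_mpmq,
    run_mq,
)
from mqsearch.backends import mock_evalue, mock_percent_identity
from mqsearch.patterns import Pattern, fixed
from mqsearch.search import BackendError


def two_member_fixture(**kwargs):
    """Two single-member families: per-member hit sets are disjoint."""
    defaults = dict(
        seed=11,
        n_families=2,
        members_per_family=1,
        homologs_per_member=5,
        decoy_count=10,
        include_members_in_db=False,
    )
    defaults.update(kwargs)
    return make_superfamily(FixtureSpec(**defaults))


class TestSearchConfig:
    def test_defaults_and_pattern_prep_preset(self):
        cfg = SearchConfig()
        assert (cfg.evalue_threshold, cfg.inclusion_threshold, cfg.max_iterations) == (1e-3, 1e-3, 20)
        prep = SearchConfig.pattern_prep()
        assert (prep.evalue_threshold, prep.inclusion_threshold, prep.max_iterations) == (1e-10, 1e-10, 10)

    def test_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(evalue_threshold=0)
        with pytest.raises(ValueError):
            SearchConfig(max_iterations=0)


class TestRunMQ:
    def test_disjoint_planted_homologs_pool_additively(self):
        fixture = two_member_fixture()
        result = run_mq(fixture.members, MockSearchBackend(fixture.database))
        sets = result.gi_sets()
        for member_id, _ in fixture.members:
            assert sets[member_id] == fixture.homolog_gis(member_id)
            assert len(sets[member_id]) == 5
        assert len(result.pooled()) == 10

    def test_empty_database_converges_immediately_with_no_hits(self):
        result = run_mq([("q", "ACDEFGHIKL" * 5)], MockSearchBackend([]))
        assert result.gi_set("q") == set()
        run = result.runs["q"]
        assert run.converged and run.n_iterations == 1

    def test_homologs_beyond_threshold_yield_empty_set(self):
        # ladder at 30% identity: mock E-value ~3.2, far above the 1e-3 cutoff
        fixture = two_member_fixture(identity_ladder=(30.0,))
        result = run_mq(fixture.members, MockSearchBackend(fixture.database))
        assert result.pooled() == set()

    def test_no_decoy_ever_reported_and_all_passing_homologs_found(self):
        fixture = two_member_fixture(seed=21, decoy_count=30)
        result = run_mq(fixture.members, MockSearchBackend(fixture.database))
        pooled = result.pooled()
        assert pooled & fixture.decoy_gis() == set()
        for member_id, seq in fixture.members:
            for rec in fixture.database:
                if rec.member_id != member_id:
                    continue
                if mock_evalue(mock_percent_identity(rec.seq, seq)) <= 1e-3:
                    assert rec.gi in result.gi_set(member_id)

    def test_backend_failure_marks_member_failed_not_fatal(self):
        class Flaky:
            profile_iterative = True
            pattern_constrained = False

            def run_profile(self, qid, seq, config):
                if qid == "bad":
                    raise BackendError("boom")
                return MockSearchBackend([]).run_profile(qid, seq, config)

        result = run_mq([("ok", "ACD" * 20), ("bad", "ACD" * 20)], Flaky())
        assert result.failed_members == ["bad"]
        assert "ok" in result.per_member_hits and "bad" not in result.per_member_hits

    def test_requires_members_and_capability(self):
        with pytest.raises(ValueError):
            run_mq([], MockSearchBackend([]))

        class NoProfile:
            profile_iterative = False

        with pytest.raises(ValueError):
            run_mq([("q", "ACD")], NoProfile())


class TestRunMPMQ:
    def test_two_patterns_pool_their_exclusive_matches(self):
        fixture = two_member_fixture(seed=31)
        backend = MockSearchBackend(fixture.database)
        member_id, seq = fixture.members[0]
        # pattern anchored on the first planted span matches this member's homologs
        from mqsearch import generate_patterns_for_member

        pats = generate_patterns_for_member(member_id, seq, backend)
        assert pats, "planted spans must produce at least one pattern"
        result = run_mpmq([(member_id, seq)], {member_id: pats}, backend)
        pooled = result.member_gi_sets()[member_id]
        assert pooled == fixture.homolog_gis(member_id)

    def test_pattern_matching_nothing_gives_empty_pair_set(self):
        fixture = two_member_fixture()
        backend = MockSearchBackend(fixture.database)
        member_id, seq = fixture.members[0]
        unmatchable = Pattern(
            (fixed("W"), fixed("W"), fixed("W")), "W-W-W", member_id, 1
        )
        result = run_mpmq([(member_id, seq)], {member_id: [unmatchable]}, backend)
        assert result.per_pair_hits[(member_id, 0)] == []

    def test_duplicate_pattern_pooling_idempotent(self):
        fixture = two_member_fixture(seed=31)
        backend = MockSearchBackend(fixture.database)
        member_id, seq = fixture.members[0]
        from mqsearch import generate_patterns_for_member

        pats = generate_patterns_for_member(member_id, seq, backend)[:1]
        once = run_mpmq([(member_id, seq)], {member_id: pats}, backend)
        twice = run_mpmq([(member_id, seq)], {member_id: pats + pats}, backend)
        assert once.member_gi_sets() == twice.member_gi_sets()

    def test_first_iteration_hits_match_the_pattern(self):
        fixture = two_member_fixture(seed=31)
        backend = MockSearchBackend(fixture.database)
        member_id, seq = fixture.members[0]
        from mqsearch import generate_patterns_for_member

        pat = generate_patterns_for_member(member_id, seq, backend)[0]
        result = run_mpmq([(member_id, seq)], {member_id: [pat]}, backend)
        seq_of = {r.gi: r.seq for r in fixture.database}
        for h in result.per_pair_hits[(member_id, 0)]:
            if h.iteration_found == 1:
                assert pat.matches(seq_of[h.gi])

    def test_member_without_patterns_skipped_with_warning_record(self):
        fixture = two_member_fixture()
        backend = MockSearchBackend(fixture.database)
        result = run_mpmq(fixture.members, {}, backend)
        assert sorted(result.skipped_members) == sorted(m for m, _ in fixture.members)

    def test_unknown_pattern_query_rejected(self):
        fixture = two_member_fixture()
        stray = Pattern((fixed("A"), fixed("C"), fixed("D")), "A-C-D", "nobody", 1)
        with pytest.raises(ValueError, match="nobody"):
            run_mpmq(fixture.members, {fixture.members[0][0]: [stray]}, MockSearchBackend(fixture.database))

    def test_pooled_sets_are_supersets_of_any_single_pair(self):
        fixture = make_superfamily(FixtureSpec(seed=41))
        backend = MockSearchBackend(fixture.database)
        from mqsearch import generate_patterns_for_member

        pats = {
            m: generate_patterns_for_member(m, s, backend) for m, s in fixture.members
        }
        result = run_mpmq(fixture.members, pats, backend)
        pooled = result.pooled()
        member_sets = result.member_gi_sets()
        for (member, _k), hits in result.per_pair_hits.items():
            pair_set = {h.gi for h in hits}
            assert pair_set <= member_sets[member] <= pooled


class TestPooling:
    def test_simple_union(self):
        assert pool_unique([{1, 2}, {2, 3}]) == {1, 2, 3}

    def test_mutually_exclusive_per_member_sets_sum(self):
        sets = [
            {f"a{i}" for i in range(97)},
            {f"b{i}" for i in range(356)},
            {f"c{i}" for i in range(15)},
        ]
        assert len(pool_unique(sets)) == 468

    def test_union_bounds_and_order_independence(self, rng):
        for _ in range(100):
            sets = [
                set(rng.integers(0, 50, size=int(rng.integers(0, 30))).tolist())
                for _ in range(int(rng.integers(1, 6)))
            ]
            pooled = pool_unique(sets)
            brute = set()
            for s in sets:
                for x in s:
                    brute.add(x)
            assert pooled == brute
            assert pooled == pool_unique(reversed(sets))
            assert pooled == pool_unique(sets + sets)
            assert max(len(s) for s in sets) <= len(pooled) <= sum(len(s) for s in sets)


def run_with_presence(n, last_present):
    presence = [i + 1 <= last_present for i in range(n)]
    return QueryRun("q", tuple(frozenset() for _ in range(n)), True, tuple(presence))


class TestRetentionTrace:
    @pytest.mark.parametrize("last, expected", [(16, 4), (12, 3), (8, 2), (7, 2), (4, 1), (1, 1)])
    def test_printed_bin_limits_for_sixteen_iterations(self, last, expected):
        assert retention_trace(run_with_presence(16, last)) == expected

    def test_ceil_rule_on_non_divisible_total(self):
        assert retention_trace(run_with_presence(5, 5)) == 4
        # N=5 limits: ceil(1.25)=2, ceil(2.5)=3, ceil(3.75)=4, 5
        assert retention_trace(run_with_presence(5, 2)) == 1
        assert retention_trace(run_with_presence(5, 3)) == 2
        assert retention_trace(run_with_presence(5, 4)) == 3

    def test_never_present_flags_immediate_drift(self):
        assert retention_trace(run_with_presence(8, 0)) == 0

    def test_bins_partition_every_iteration(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 25))
            last = int(rng.integers(1, n + 1))
            b = retention_trace(run_with_presence(n, last))
            lo = math.ceil((b - 1) * n / 4)
            hi = math.ceil(b * n / 4)
            assert lo < last <= hi

    def test_drift_schedule_controls_presence(self):
        fixture = two_member_fixture()
        member_id, seq = fixture.members[0]
        backend = MockSearchBackend(fixture.database, drift_after={member_id: 1})
        result = run_mq([(member_id, seq)], backend)
        run = result.runs[member_id]
        assert run.query_present_per_iteration[0] is True
        assert all(p is False for p in run.query_present_per_iteration[1:])


class TestDeterminism:
    def test_same_seed_same_results(self):
        a = two_member_fixture(seed=5)
        b = two_member_fixture(seed=5)
        assert a.members == b.members
        assert [r.gi for r in a.database] == [r.gi for r in b.database]
        ra = run_mq(a.members, MockSearchBackend(a.database))
        rb = run_mq(b.members, MockSearchBackend(b.database))
        assert ra.gi_sets() == rb.gi_sets()
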