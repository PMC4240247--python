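"""Column conservation scoring and motif extraction."""

from itertools import combinations

import numpy as np
import pytest

from mqsearch import (
    ExchangeMatrix,
    Msa,
    column_scores,
    extract_motifs,
    find_motifs,
    msa_from_sequences,
)
from mqsearch.matrices import AMINO_ACIDS, DEFAULT_GAP_SCORE


def _msa_from_columns(columns):
    """Build an Msa whose j-th column is columns[j] (one char per sequence)."""
    n_seqs = len(columns[0])
    return Msa(tuple(
        (f"s{i}", "".join(col[i] for col in columns)) for i in range(n_seqs)
    ))


def brute_force_column_score(column, matrix, gap_score=DEFAULT_GAP_SCORE):
    """Independent oracle: explicit loop over all unordered pairs."""
    scores = []
    for a, b in combinations(column, 2):
        scores.append(gap_score if "-" in (a, b) else matrix.score(a, b))
    return sum(scores) / len(scores)


class TestColumnScores:
    def test_identical_residues_force_self_score(self, pam250):
        msa = _msa_from_columns([["A"] * 4])
        (profile,) = column_scores(msa, pam250)
        assert profile.avg_pair_score == pam250.score("A", "A")

    def test_single_pair_is_the_pair_score(self, pam250):
        msa = _msa_from_columns([["A", "S"]])
        (profile,) = column_scores(msa, pam250)
        assert profile.avg_pair_score == pam250.score("A", "S")

    def test_four_sequence_column_mean_of_six_pairs(self, pam250):
        col = ["A", "A", "S", "T"]
        msa = _msa_from_columns([col])
        (profile,) = column_scores(msa, pam250)
        assert profile.avg_pair_score == pytest.approx(
            brute_force_column_score(col, pam250), abs=1e-12
        )

    def test_matches_brute_force_on_random_msas(self, pam250, rng):
        for _ in range(20):
            n_seqs = int(rng.integers(2, 11))
            n_cols = int(rng.integers(1, 51))
            alphabet = list(AMINO_ACIDS) + ["-"]
            cols = [
                [alphabet[k] for k in rng.integers(len(alphabet), size=n_seqs)]
                for _ in range(n_cols)
            ]
            msa = _msa_from_columns(cols)
            profiles = column_scores(msa, pam250)
            for col, prof in zip(cols, profiles):
                assert prof.avg_pair_score == pytest.approx(
                    brute_force_column_score(col, pam250), abs=1e-9
                )

    def test_gap_pairs_contribute_gap_score(self, pam250):
        msa = _msa_from_columns([["A", "-"]])
        (profile,) = column_scores(msa, pam250, gap_score=-7.5)
        assert profile.avg_pair_score == -7.5
        assert profile.has_gap and profile.gap_count == 1

    def test_uncovered_residue_names_column_and_symbol(self):
        tiny = ExchangeMatrix.from_pairs("tiny", {("A", "A"): 2.0, ("A", "S"): 1.0, ("S", "S"): 2.0})
        msa = msa_from_sequences([("a", "AW"), ("b", "SA")])
        with pytest.raises(ValueError, match=r"column 1.*'W'"):
            column_scores(msa, tiny)

    def test_sequence_order_does_not_change_scores(self, pam250, rng):
        cols = [
            [AMINO_ACIDS[k] for k in rng.integers(20, size=6)] for _ in range(15)
        ]
        msa = _msa_from_columns(cols)
        shuffled = _msa_from_columns([[c[i] for i in rng.permutation(6)] for c in cols])
        a = [p.avg_pair_score for p in column_scores(msa, pam250)]
        b = [p.avg_pair_score for p in column_scores(shuffled, pam250)]
        assert a == pytest.approx(b, abs=1e-12)


class TestFindMotifs:
    def test_minimum_length_fully_conserved_run(self, pam250):
        # columns 5-7 identical, everything else dissimilar (R/D/W mix on PAM250)
        bg = ["R", "D", "W", "G"]
        cols = [list(bg)] * 5 + [["A"] * 4, ["C"] * 4, ["L"] * 4] + [list(bg)] * 4
        msa = _msa_from_columns(cols)
        motifs = find_motifs(column_scores(msa, pam250), msa)
        assert len(motifs) == 1
        assert (motifs[0].start_col, motifs[0].end_col, motifs[0].length) == (5, 7, 3)

    def test_all_columns_identical_yield_single_spanning_motif(self, pam250):
        msa = msa_from_sequences([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL")])
        motifs = extract_motifs(msa, pam250)
        assert len(motifs) == 1
        assert (motifs[0].start_col, motifs[0].end_col) == (0, 9)
        assert motifs[0].query_anchor == 1

    def test_planted_runs_recovered_with_exact_coordinates(self, pam250, rng):
        """Two planted conserved runs (lengths 4 and 5) among dissimilar columns."""
        def background():
            while True:
                col = [AMINO_ACIDS[k] for k in rng.integers(20, size=6)]
                if len(set(col)) >= 4 and brute_force_column_score(col, pam250) < 0.5:
                    return col

        cols = [background() for _ in range(30)]
        for start, length in ((6, 4), (18, 5)):
            res = AMINO_ACIDS[rng.integers(20)]
            for j in range(start, start + length):
                cols[j] = [res] * 6
        msa = _msa_from_columns(cols)
        profiles = column_scores(msa, pam250)
        motifs = find_motifs(profiles, msa)
        assert [(m.start_col, m.end_col) for m in motifs] == [(6, 9), (18, 22)]
        # independent per-column scan: every inside column conserved, borders not
        for m in motifs:
            for j in range(m.start_col, m.end_col + 1):
                assert len(set(cols[j])) == 1
            for j in (m.start_col - 1, m.end_col + 1):
                assert brute_force_column_score(cols[j], pam250) < 1.0

    def test_maximality_no_conserved_column_adjacent(self, pam250, rng):
        from mqsearch.motifs import is_conserved

        from mqsearch import make_motif_msa
        from mqsearch.fixtures import FixtureSpec

        msa, _ = make_motif_msa(FixtureSpec(seed=7, planted_motifs=((5, 4), (20, 6))))
        profiles = column_scores(msa, pam250)
        for m in find_motifs(profiles, msa):
            for j in range(m.start_col, m.end_col + 1):
                assert is_conserved(profiles[j])
            if m.start_col > 0:
                assert not is_conserved(profiles[m.start_col - 1])
            if m.end_col < msa.n_cols - 1:
                assert not is_conserved(profiles[m.end_col + 1])

    def test_gap_column_breaks_a_run(self, pam250):
        msa = msa_from_sequences([("a", "AAAAAAA"), ("b", "AAA-AAA")])
        motifs = extract_motifs(msa, pam250)
        assert [(m.start_col, m.end_col) for m in motifs] == [(0, 2), (4, 6)]
        # anchors on the gap-stripped first sequence
        assert [m.query_anchor for m in motifs] == [1, 5]

    def test_sequence_permutation_leaves_motif_set_unchanged(self, pam250):
        from mqsearch import FixtureSpec, make_motif_msa

        msa, _ = make_motif_msa(FixtureSpec(seed=3, planted_motifs=((5, 4), (20, 6))))
        perm = Msa(tuple(reversed(msa.records)))
        a = [(m.start_col, m.end_col) for m in extract_motifs(msa, pam250)]
        b = [(m.start_col, m.end_col) for m in extract_motifs(perm, pam250)]
        assert a == b

    def test_min_len_below_one_rejected(self, pam250):
        msa = msa_from_sequences([("a", "AAA"), ("b", "AAA")])
        with pytest.raises(ValueError):
            find_motifs(column_scores(msa, pam250), msa, min_len=0)

    def test_profile_column_mismatch_rejected(self, pam250):
        msa = msa_from_sequences([("a", "AAA"), ("b", "AAA")])
        profiles = column_scores(msa, pam250)
        other = msa_from_sequences([("a", "AAAA"), ("b", "AAAA")])
        with pytest.raises(ValueError):
            find_motifs(profiles, other)


class TestMatrixAndMsaInvariants:
    def test_default_matrix_symmetric_with_self_scores_dominant(self, pam250):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert pam250.score(a, b) == pam250.score(b, a)
                assert pam250.score(a, a) >= pam250.score(a, b)

    def test_msa_rejects_ragged_and_duplicate_records(self):
        with pytest.raises(ValueError, match="'b'"):
            Msa((("a", "ACDE"), ("b", "ACD")))
        with pytest.raises(ValueError, match="duplicate"):
            Msa((("a", "ACDE"), ("a", "ACDE")))
        with pytest.raises(ValueError, match="at least 2"):
            Msa((("a", "ACDE"),))
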