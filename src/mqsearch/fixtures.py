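"""Synthetic study systems: superfamilies, databases and motif alignments.

Everything the toolkit consumes can be generated here under a single
integer seed: superfamilies built from per-family ancestors (so
cross-family identity stays near the random baseline while within-family
identity is controlled), databases with planted homologs at a controlled
identity ladder plus random decoys, and alignments with planted conserved
runs whose per-column residue-set sizes follow a schedule.

The mutation model is uniform residue substitution with no indels, so a
homolog generated at identity *t* sits at exactly *t* percent identity to
its member and sequences align column-for-column (the trivial aligner in
:mod:`mqsearch.msa`).  Spans listed in ``planted_motifs`` are protected
from mutation when homologs are generated, guaranteeing that the
pattern-generation pipeline finds a conserved stretch for every member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backends import DbRecord
from .matrices import AMINO_ACIDS, DEFAULT_CONSERVATION_THRESHOLD, default_matrix
from .motifs import Motif
from .msa import Msa

_RANDOM_IDENTITY_BASELINE = 100.0 / len(AMINO_ACIDS)  # expected identity of unrelated sequences

# Residue groups with favourable mutual PAM250 exchange, used for planted
# columns that must count as conserved despite carrying 2-4 distinct residues.
_SIMILAR_GROUPS = {
    2: (("I", "L"), ("A", "S"), ("Y", "F"), ("K", "R"), ("D", "E"), ("M", "L")),
    3: (("I", "L", "M"), ("I", "L", "V"), ("D", "E", "N")),
    4: (("I", "L", "M", "V"),),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic superfamily / alignment fixture."""

    seed: int = 0
    superfamily_id: str = "SF1"
    n_families: int = 2
    members_per_family: int = 3
    sequence_length: int = 120
    homologs_per_member: int = 5
    identity_ladder: tuple = (90.0, 80.0, 75.0, 70.0, 65.0)
    decoy_count: int = 20
    within_family_identity: float = 75.0
    include_members_in_db: bool = True
    #: (start, length) or (start, length, schedule) planted conserved spans;
    #: schedule lists per-column distinct-residue counts (1=fixed, 2-3=choice,
    #: 4=wildcard-to-be) and defaults to all-1 (fully conserved).
    planted_motifs: tuple = ((10, 8), (60, 10))
    msa_sequences: int = 6
    msa_columns: int = 40

    def __post_init__(self):
        for name in ("n_families", "members_per_family", "sequence_length",
                     "homologs_per_member", "decoy_count", "msa_sequences", "msa_columns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for pid in tuple(self.identity_ladder) + (self.within_family_identity,):
            if not 0 < pid <= 100:
                raise ValueError(f"identity {pid} outside (0, 100]")
            if pid <= 2 * _RANDOM_IDENTITY_BASELINE:
                raise ValueError(
                    f"identity {pid}% is at or below the random-match baseline "
                    f"(~{_RANDOM_IDENTITY_BASELINE:.0f}%); homologs would be indistinguishable from decoys"
                )
        spans = sorted((m[0], m[1]) for m in self.planted_motifs)
        prev_end = -2
        for start, length in spans:
            if start < 0 or length < 1 or start + length > self.sequence_length:
                raise ValueError(f"planted span ({start}, {length}) outside sequence of length {self.sequence_length}")
            if start <= prev_end + 1:  # adjacent runs would merge into one motif
                raise ValueError("planted spans must be separated by at least one background column")
            prev_end = start + length - 1
        for m in self.planted_motifs:
            if len(m) >= 3 and m[2] is not None:
                schedule = tuple(m[2])
                if len(schedule) != m[1]:
                    raise ValueError("schedule length must equal span length")
                for k in schedule:
                    if not 1 <= k <= 4:
                        raise ValueError("schedule column sizes must lie in 1..4")
                    if k > self.msa_sequences:
                        raise ValueError("schedule size exceeds number of alignment sequences")

    def protected_positions(self) -> frozenset:
        pos = set()
        for m in self.planted_motifs:
            pos.update(range(m[0], m[0] + m[1]))
        return frozenset(pos)


@dataclass
class SuperfamilyFixture:
    """A generated superfamily: members, labelled database, family map."""

    superfamily_id: str
    members: list  # of (member_id, seq)
    member_family: dict  # member_id -> family index
    database: list  # of DbRecord
    spec: FixtureSpec = field(repr=False, default=None)

    def homolog_gis(self, member_id: str) -> set:
        return {r.gi for r in self.database if r.label == "homolog" and r.member_id == member_id}

    def all_homolog_gis(self) -> set:
        return {r.gi for r in self.database if r.label == "homolog"}

    def decoy_gis(self) -> set:
        return {r.gi for r in self.database if r.label == "decoy"}

    def structural_gis(self) -> set:
        return {r.gi for r in self.database if r.is_structural}

    def member_gis(self) -> set:
        return {r.gi for r in self.database if r.gi in dict(self.members)}


def _random_seq(length: int, rng) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(seq: str, identity: float, rng, protected=frozenset()) -> str:
    """Substitute residues so the result has exactly ``identity``% identity."""
    length = len(seq)
    n_mut = round(length * (1.0 - identity / 100.0))
    eligible = [i for i in range(length) if i not in protected]
    if n_mut > len(eligible):
        raise ValueError(
            f"cannot place {n_mut} mutations with only {len(eligible)} unprotected positions"
        )
    sites = rng.choice(len(eligible), size=n_mut, replace=False)
    out = list(seq)
    for k in sites:
        i = eligible[k]
        alternatives = [a for a in AMINO_ACIDS if a != seq[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_superfamily(spec: FixtureSpec) -> SuperfamilyFixture:
    """Generate members and a labelled database, deterministically by seed.

    Each family descends from an independent random ancestor; members are
    mutated copies of their ancestor at ``within_family_identity``, so
    cross-family identity stays near the random baseline.  Homologs are
    mutated copies of their member at the identity-ladder values with the
    planted spans protected; the first homolog of every member is flagged
    structural.  Decoys are independent random sequences.
    """
    rng = np.random.default_rng(spec.seed)
    protected = spec.protected_positions()
    members = []
    member_family = {}
    database = []
    gi_counter = 0
    for f in range(spec.n_families):
        ancestor = _random_seq(spec.sequence_length, rng)
        for m in range(spec.members_per_family):
            member_id = f"{spec.superfamily_id}.f{f + 1}m{m + 1}"
            # spans stay ancestral, so the planted motif is a family signature
            member_seq = _mutate(ancestor, spec.within_family_identity, rng, protected=protected)
            members.append((member_id, member_seq))
            member_family[member_id] = f
            if spec.include_members_in_db:
                database.append(
                    DbRecord(
                        gi=member_id,
                        seq=member_seq,
                        label="homolog",
                        member_id=member_id,
                        superfamily_id=spec.superfamily_id,
                    )
                )
            for j in range(spec.homologs_per_member):
                identity = float(spec.identity_ladder[j % len(spec.identity_ladder)])
                seq = _mutate(member_seq, identity, rng, protected=protected)
                gi_counter += 1
                database.append(
                    DbRecord(
                        gi=f"hom{gi_counter:05d}",
                        seq=seq,
                        label="homolog",
                        member_id=member_id,
                        superfamily_id=spec.superfamily_id,
                        is_structural=(j == 0),
                    )
                )
    for j in range(spec.decoy_count):
        database.append(
            DbRecord(gi=f"dec{j + 1:05d}", seq=_random_seq(spec.sequence_length, rng), label="decoy")
        )
    return SuperfamilyFixture(
        superfamily_id=spec.superfamily_id,
        members=members,
        member_family=member_family,
        database=database,
        spec=spec,
    )


@dataclass(frozen=True)
class PlantedMotifTruth:
    """Expected outcome for one planted conserved run."""

    start_col: int
    end_col: int
    schedule: tuple  # per-column distinct-residue counts
    expected_kinds: tuple  # per-column pattern element kinds


def _kind_for_size(k: int) -> str:
    if k == 1:
        return "fixed"
    if k <= 3:
        return "choice"
    return "wildcard"


def make_motif_msa(spec: FixtureSpec, conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD):
    """Generate an alignment with planted conserved runs and its truth list.

    Planted columns follow the residue-set schedule (sizes 1-4, drawn from
    groups with favourable mutual exchange so the column passes the
    conservation predicate); background columns are resampled until they
    carry at least 4 distinct residues and score below the threshold, so
    the planted runs are exactly the motifs present.
    """
    rng = np.random.default_rng(spec.seed)
    matrix = default_matrix()
    n_seqs = spec.msa_sequences
    n_cols = spec.msa_columns
    if n_seqs < 4:
        raise ValueError("need at least 4 alignment sequences for high-entropy background columns")
    columns = [None] * n_cols
    truths = []
    for m in sorted(spec.planted_motifs):
        start, length = m[0], m[1]
        if start + length > n_cols:
            raise ValueError(f"planted span ({start}, {length}) outside {n_cols} alignment columns")
        schedule = tuple(m[2]) if len(m) >= 3 and m[2] is not None else (1,) * length
        for j, k in enumerate(schedule):
            columns[start + j] = _planted_column(k, n_seqs, rng, matrix, conservation_threshold)
        truths.append(
            PlantedMotifTruth(
                start_col=start,
                end_col=start + length - 1,
                schedule=schedule,
                expected_kinds=tuple(_kind_for_size(k) for k in schedule),
            )
        )
    for j in range(n_cols):
        if columns[j] is None:
            columns[j] = _background_column(n_seqs, rng, matrix, conservation_threshold)
    records = tuple(
        (f"seq{i + 1}", "".join(columns[j][i] for j in range(n_cols))) for i in range(n_seqs)
    )
    return Msa(records), truths


def _column_avg_score(col, matrix) -> float:
    from itertools import combinations

    pairs = list(combinations(col, 2))
    return sum(matrix.score(a, b) for a, b in pairs) / len(pairs)


def _planted_column(k: int, n_seqs: int, rng, matrix, threshold: float):
    """A column with exactly k distinct residues that counts as conserved."""
    if k == 1:
        residues = (AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))],)
    else:
        groups = _SIMILAR_GROUPS[k]
        residues = groups[rng.integers(len(groups))]
    # first k rows cover every residue, the rest draw from the set
    col = list(residues) + [residues[rng.integers(k)] for _ in range(n_seqs - k)]
    col = [col[i] for i in rng.permutation(n_seqs)]
    if len(set(col)) != k:
        raise AssertionError("planted column lost a residue")
    if k > 1 and _column_avg_score(col, matrix) < threshold:
        raise AssertionError("planted similar-group column fell below the conservation threshold")
    return col


def _background_column(n_seqs: int, rng, matrix, threshold: float):
    """A high-entropy column that can never be part of a motif."""
    for _ in range(1000):
        col = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=n_seqs)]
        if len(set(col)) >= 4 and _column_avg_score(col, matrix) <= threshold - 0.5:
            return col
    raise RuntimeError("failed to sample a high-entropy background column")


def make_random_motifs(
    n: int,
    seed: int,
    min_len: int = 3,
    max_len: int = 40,
    max_set_size: int = 8,
    n_seqs: int = 8,
    conserved_fraction: float = 0.1,
) -> list:
    """Randomized motif suite for exercising the pattern filter cascade.

    Motif lengths are uniform on [min_len, max_len]; each column carries
    between 1 and ``max_set_size`` distinct residues (arbitrary residues —
    these motifs exercise the cascade, not the conservation predicate).
    A ``conserved_fraction`` of the motifs is fully conserved (every column
    one residue), so long wildcard-free stretches up to ``max_len`` hit the
    maximum-length splitting rule.
    """
    if n_seqs < max_set_size:
        raise ValueError("need at least max_set_size sequences to realise every set size")
    rng = np.random.default_rng(seed)
    motifs = []
    aas = list(AMINO_ACIDS)
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        fully_conserved = rng.random() < conserved_fraction
        cols = []
        for _ in range(length):
            k = 1 if fully_conserved else int(rng.integers(1, max_set_size + 1))
            residues = list(rng.choice(aas, size=k, replace=False))
            col = residues + [residues[rng.integers(k)] for _ in range(n_seqs - k)]
            cols.append([col[i] for i in rng.permutation(n_seqs)])
        stretches = tuple(
            (f"seq{i + 1}", "".join(cols[j][i] for j in range(length))) for i in range(n_seqs)
        )
        motifs.append(
            Motif(start_col=0, end_col=length - 1, per_sequence_stretches=stretches, query_anchor=1)
        )
    return motifs


def build_validation_table(fixture: SuperfamilyFixture) -> dict:
    """Ground-truth HMM-verdict table: every homolog maps to its superfamily.

    Decoys map to nothing (they will come out unvalidated if they ever
    reach validation).  Use :func:`with_cross_association` to corrupt an
    entry for false-positive testing.
    """
    table = {}
    for rec in fixture.database:
        if rec.label == "homolog":
            evalue = 1e-8 if rec.gi == rec.member_id else 1e-6
            table[rec.gi] = [(rec.superfamily_id, evalue)]
    return table


def with_cross_association(table: dict, gi: str, other_superfamily: str, evalue: float = 1e-4) -> dict:
    """Copy of a verdict table with one extra cross-superfamily association."""
    out = {g: list(v) for g, v in table.items()}
    out.setdefault(gi, []).append((other_superfamily, evalue))
    return out
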