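# Methods

## The strategy

`mqsearch` models superfamily-level homolog mining as three composable
stages: (1) derive sequence patterns that are specific to each query,
(2) search from many start points — every superfamily member, optionally
constrained by each of its patterns — and (3) validate and pool the hits
into coverage statistics.  The underlying assumption is that a
structural superfamily's members occupy different neighbourhoods of
sequence space: a profile search seeded from one member saturates its
own family's neighbourhood, so the union over members (and over
member–pattern pairs) is what approaches full superfamily coverage.

## Column scoring and motif calling

A column of an alignment of n sequences is scored as the mean exchange
score over all C(n, 2) unordered sequence pairs.  The default matrix is
the Dayhoff PAM250 log-odds matrix (Biopython's copy), injected as data —
any symmetric 20×20 matrix can be substituted.  Pairs involving a gap
contribute a fixed gap score (default −10, below the PAM250 minimum of
−8, so a gapped pair can never look favourable).

A column is *conserved* when it is gap-free and either carries a single
residue or scores at or above the conservation threshold (default 1.0 on
PAM250 — the level of accepted substitutions such as A/S or I/L).  A
motif is a maximal run of ≥ 3 consecutive conserved columns; maximal
runs are disjoint by construction, so no tie-breaking is needed.  Gapped
columns never join a motif because a pattern must later map onto
contiguous residues of the query.  Motif positions are reported 0-based
in alignment coordinates internally and 1-based on the gap-stripped
first sequence (the query) externally.  No upper bound is placed on
motif length; long motifs are cut down at the pattern stage.

## Pattern rules and cascade order

Motif columns map to pattern elements by the number of distinct residues
observed: 1 → fixed, 2–3 → bracketed choice, ≥ 4 → wildcard `x`
(raw distinct counts, no weighting).  The filters are applied in a fixed
order: split at every run of ≥ 2 consecutive wildcards (the run itself
is dropped) → trim wildcard ends → split fragments longer than 15 into
greedy left-to-right chunks, re-trimming chunk ends → discard fragments
shorter than 3.  This is the only order under which every output
simultaneously satisfies all the rules (length 3–15, ≤ 3 preferences per
position, no double wildcard, no wildcard ends).  Greedy left-to-right
chunking was chosen over balanced splitting because it is deterministic
and preserves left context.  Choice residues are serialised
alphabetically for bit-exact reproducibility.  After trimming shifts a
fragment, its query anchor is recomputed from the fragment's column
offset and verified by matching against the source query — every emitted
pattern provably matches its own query at the reported position.

The PROSITE dialect supported is exactly what the generator emits
(fixed letters, `[..]` choices, `x`, `-`-joined); repetition counts,
exclusions and anchors are out of scope.

## Homolog selection

Patterns are deduced from homologs at 60–90% identity to the query —
close enough to align reliably, distant enough that conservation is
informative.  When fewer than 10 hits qualify, the window relaxes to
40–95%.  Both bounds are inclusive (the simplest contract; the window
definition is otherwise arbitrary at the boundary).  The stringent
pre-search that produces these hits uses the `pattern_prep` preset:
E-value and inclusion thresholds 1e-10, at most 10 iterations.

## Search orchestration and the mock backend

`run_mq` and `run_mpmq` orchestrate per-member (and per member–pattern)
searches over any object implementing the `SearchBackend` contract, and
pool unique hit identifiers by set union.  Pooling is therefore
idempotent and order-independent, and every pooled set is a superset of
any single run's set.

The shipped backend is a deterministic in-memory mock that reproduces
the qualitative dynamics of an iterative profile search: per iteration,
the included set grows by transitive identity neighbours of the current
profile; convergence is one iteration with no new inclusions;
pattern-constrained runs intersect the *first* iteration's candidates
with the sequences the pattern matches (later iterations are profile
driven, as in pattern-hit-initiated search).  Similarity is
alignment-free percent identity (matching positions over the longer
length — exact for the indel-free synthetic data) mapped to a pseudo
E-value by `log10 E = 11 − 0.35·pid`.  The calibration anchors ~40%
identity at the default 1e-3 threshold and 60% at the 1e-10 stringent
threshold, so the planted 60–90% homolog ladder passes the pattern
pre-search while random decoys (~5% identity, E ≈ 1e9) are excluded by
every threshold.  Query drift is modelled explicitly (`drift_after`
schedules the last iteration in which a query is retained); by default
queries are always retained.  Adapters for external engines implement
the same two-method contract; none are bundled — the mock is the
supported backend and the contract is the integration point.

Query retention is summarised by the quartile of the last iteration in
which the query was present: bin k covers iterations up to ⌈k·N/4⌉ of an
N-iteration run (for N = 16: iterations 4, 8, 12, 16).  A query never
present is bin 0, flagged as immediate drift.  Presence of a > 90%
identity proxy is not folded into the bin; the per-iteration hit sets in
each `QueryRun` allow computing it separately.

## Validation

A hit is a true positive when the verdict backend associates it with
exactly the target superfamily; *any* reported cross-superfamily
association makes it a false positive, even within the same fold.  The
backend applies its own library operating threshold when reporting
(hmmscan-style, E ≤ 0.01); the tunable `evalue` argument gates only
whether the target association is significant enough to validate.  This
makes labelling monotone — tightening the threshold can demote a TP to
unvalidated but never promote an FP.  Hits the superfamily-level library
cannot place are retried on an optional single-query-HMM fallback;
still-unplaced hits are tracked as `unvalidated`, a class of their own:
they depress PPV but are not cross-superfamily errors, and the three
labels always partition the pooled set.

## Coverage statistics

`All Hits` is defined as the unique-GI union of all hits across members;
a sum-of-hits denominator (which double-counts shared hits) can be
chosen in the report writer for comparison with legacy tables.  PPV and
PGC are reported to two decimals as percentages; the report writer can
emit PPV on a 0–1 scale.  `cum_tp ≥ brs_tp` is enforced as an invariant
of `SuperfamilyResult`.  BRS ties break by lexicographically smallest
member id.  Overlap accounting classifies every hit into the exclusive
region of exactly the approaches that found it (15 regions for four
sets).  PGC bins are 0–25, 26–50, 51–75, 76–100.

## Synthetic data: what it emulates and what it does not

The generator builds one superfamily from per-family random ancestors of
length 120 (2 families × 3 members by default).  Members are ancestors
mutated to 75% identity, giving mutual member identity around 58% —
remote-homology range, so family members reach each other's homologs
transitively while cross-family identity stays near the 5% random
baseline and cross-family hit sets are exclusive.  Each member gets 5
homologs at the identity ladder (90, 80, 75, 70, 65)% — inside the
60–90% pattern window — and the database adds 20 unrelated decoys; the
first homolog of each member is flagged as a structural entry.
Mutation is uniform substitution with no indels, so generated identities
are exact and sequences align column-for-column (the trivial aligner).
Planted conserved spans (two per member by default) are protected from
mutation in both the ancestor→member and member→homolog steps, making
the motif a family signature that guarantees the pattern pipeline
produces at least one pattern per member.

Planted motif alignments draw conserved columns from residue groups with
favourable mutual PAM250 exchange (e.g. {I,L,M,V}) so scheduled columns
of 2–4 distinct residues still pass the conservation predicate, and
resample background columns until they hold ≥ 4 distinct residues and
score at most 0.5 below the threshold — planted runs are exactly the
motifs present, which is what makes planted-truth tests exact.

What the fixtures do **not** emulate: indels (and hence alignment
uncertainty), compositional bias, rate heterogeneity across sites, and
databases large enough for E-value statistics to matter.  Passing tests
therefore demonstrate the correctness of the strategy's logic —
pooling, pattern rules, validation arithmetic, retention bookkeeping —
not engine-level sensitivity on real sequence databases.

## Numerical and scale choices

All randomness flows from a single integer seed per fixture; reports
embed the seed and configuration in a provenance block.  Column-score
oracle agreement is asserted to 1e-9.  Test and acceptance workloads use
desk-scale problems — 1000-motif pattern suites, 50 planted alignments,
superfamilies of ≤ 8 members over databases of ≤ 80 sequences — sizes
chosen so the full suite runs in seconds while every code path
(relaxation, splitting, fallback validation, drift) is exercised.

## Known limitations

- The mock backend's identity→E-value map is a calibration device, not a
  statistical model; absolute E-values are only meaningful relative to
  the configured thresholds.
- Alignment-free identity requires the no-indel mutation model; plugging
  in indel-bearing data requires a real aligner and search engine behind
  the backend contracts.
- The PROSITE dialect is the generator's subset; patterns from external
  sources may not parse.
- Retention bins follow the ⌈k·N/4⌉ rule exactly; for N < 4 the upper
  bins collapse (e.g. N = 3 full retention lands in bin 3).
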