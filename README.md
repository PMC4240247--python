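# mqsearch

A toolkit for **remote homology detection at the protein superfamily
level** using multiple queries and sequence-pattern constraints.

At low sequence identity (< 40%), a single query rarely recovers a whole
structural superfamily: different members reach different corners of
sequence space, and iterative profile searches can drift.  `mqsearch`
implements a search *strategy* rather than a search *engine*:

- **MQ (multiple query)** — run an iterative profile search
  (PSI-BLAST-style: E-value and inclusion thresholds 0.001, up to 20
  iterations) from *every* member of a superfamily and pool the unique
  hit identifiers (GIs).
- **MPMQ (multiple pattern, multiple query)** — additionally derive
  PROSITE patterns from each member's close homologs and run one
  pattern-constrained search (PHI-BLAST-style) per member–pattern pair,
  making the first iteration stringent and specific.

The supporting machinery is included end to end:

- **Motif extraction** (`mqsearch.motifs`) — score each alignment column
  by the average pairwise amino-acid exchange (Dayhoff-type PAM250 by
  default) and report maximal gap-free runs of ≥ 3 conserved columns.
- **Pattern generation** (`mqsearch.patterns`) — convert motif columns to
  pattern elements (1 residue → fixed, 2–3 → `[..]` choice, ≥ 4 → `x`)
  and enforce the rule cascade: split at double wildcards, trim wildcard
  ends, split fragments longer than 15, discard fragments shorter than 3.
- **Homolog selection** (`mqsearch.homologs`) — keep pre-search hits at
  60–90% identity for pattern deduction, relaxing to 40–95% when fewer
  than 10 qualify.
- **Validation** (`mqsearch.validation`) — label pooled hits TP/FP via an
  HMM-library verdict backend (E ≤ 0.01), with any cross-superfamily
  association counted as a false positive and a single-query-HMM
  fallback for hits the superfamily library cannot place.
- **Coverage statistics** (`mqsearch.coverage`) — with per-member
  validated TP sets `T_m`:

  - `Cum-TP = |∪_m T_m|` — cumulative true positives,
  - `BRS` — the best representing sequence, `argmax_m |T_m|`,
  - `PPV = 100 · Cum-TP / All Hits` — positive prediction value,
  - `PGC = 100 · (Cum-TP − BRS-TP) / Cum-TP` — percentage gain in
    coverage from using all members instead of the single best one,

  plus query-retention quartile bins, four-approach overlap (Venn)
  accounting and PGC-versus-member-count tables.
- **Synthetic fixtures** (`mqsearch.fixtures`) — seeded superfamilies
  with controlled family structure, identity ladders, planted conserved
  motifs and decoy databases, plus a deterministic mock search backend
  (`mqsearch.backends`) so the whole strategy runs without external
  engines.

Real search/validation engines plug in through the `SearchBackend` and
`ValidationBackend` contracts.

## Worked example

```sh
python examples/03_mq_vs_mpmq.py
```

generates a two-family superfamily (3 members per family, 5 planted
homologs per member at 65–90% identity, 20 decoys), derives patterns for
every member, runs both strategies and prints:

```
patterns per member:
  SF1.f1m1: 10 patterns, e.g. [DQ]-[MP]-[IS]
  ...
  MQ: Cum-TP=36  BRS=SF1.f1m1 (18 TP)  PPV=100.00%  PGC=50.00%
MPMQ: Cum-TP=36  BRS=SF1.f1m1 (18 TP)  PPV=100.00%  PGC=50.00%
query retention bins (MQ): {0: 0, 1: 0, 2: 0, 3: 6, 4: 0}
member coverage in Cum-TP: 100%
```

All 36 database homologs (30 planted + the 6 members) are recovered with
no decoy among them (PPV 100%).  The best single member only reaches its
own family — 18 of 36 true positives — so pooling all queries gains 50%
coverage (PGC); every member appears in the cumulative set even though
no single query spans both families.  The other examples walk through
motif extraction, the pattern filter cascade, and overlap/PGC trends.

The same workflow is available from the shell:

```sh
mqsearch run-all --seed 1 --outdir out/
mqsearch make-fixtures --seed 2 --outdir fx/
mqsearch search-mq --members fx/members.fasta --database fx/database.fasta --out hits.tsv
```

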