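"""Superfamily-level coverage statistics for multi-query searches.

Given per-member validated true-positive (TP) hit sets, this module
computes the cumulative TP count (Cum-TP, the size of the union), the best
representing sequence (BRS, the member with the most TPs), the positive
prediction value PPV = 100 * Cum-TP / All Hits, and the percentage gain in
coverage PGC = 100 * (Cum-TP - BRS-TP) / Cum-TP — the benefit of searching
from every member instead of only the single best one.  It also provides
multi-level coverage fractions, the four-approach overlap accounting used
to compare MPMQ/MQ/BRS strategies, quartile query-retention histograms and
PGC binning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .search import pool_unique, retention_trace


def compute_ppv(cum_tp: int, all_hits: int):
    """PPV = 100 * Cum-TP / All Hits; ``None`` (not applicable) if no hits."""
    if cum_tp < 0 or all_hits < cum_tp:
        raise ValueError("need all_hits >= cum_tp >= 0")
    if all_hits == 0:
        return None
    return 100.0 * cum_tp / all_hits

def compute_pgc(cum_tp: int, brs_tp: int):
    """PGC = 100 * (Cum-TP - BRS-TP) / Cum-TP; ``None`` if Cum-TP is zero."""
    if brs_tp < 0 or cum_tp < brs_tp:
        raise ValueError("need cum_tp >= brs_tp >= 0")
    if cum_tp == 0:
        return None
    return 100.0 * (cum_tp - brs_tp) / cum_tp


def identify_brs(per_member_tp_sets: dict):
    """Best representing sequence: the member with the largest TP set.

    Ties are broken by lexicographically smallest member id.
    """
    if not per_member_tp_sets:
        raise ValueError("at least one member is required")
    member = min(per_member_tp_sets, key=lambda m: (-len(per_member_tp_sets[m]), m))
    return member, len(per_member_tp_sets[member])


@dataclass(frozen=True)
class SuperfamilyResult:
    """Per-superfamily coverage statistics for one search approach."""

    superfamily_id: str
    per_member_tp_sets: dict
    all_hits: frozenset
    cum_tp: int
    brs_member: str
    brs_tp: int
    ppv: float  # percent, None when all_hits empty
    pgc: float  # percent, None when cum_tp zero

    @classmethod
    def from_tp_sets(cls, superfamily_id: str, per_member_tp_sets: dict, all_hits) -> "SuperfamilyResult":
        all_hits = frozenset(all_hits)
        union = pool_unique(per_member_tp_sets.values())
        if not union <= all_hits:
            raise ValueError("TP sets must be subsets of the all-hits set")
        brs_member, brs_tp = identify_brs(per_member_tp_sets)
        cum_tp = len(union)
        return cls(
            superfamily_id=superfamily_id,
            per_member_tp_sets={m: frozenset(s) for m, s in per_member_tp_sets.items()},
            all_hits=all_hits,
            cum_tp=cum_tp,
            brs_member=brs_member,
            brs_tp=brs_tp,
            ppv=compute_ppv(cum_tp, len(all_hits)),
            pgc=compute_pgc(cum_tp, brs_tp),
        )

    @property
    def cum_tp_set(self) -> frozenset:
        return frozenset(pool_unique(self.per_member_tp_sets.values()))


@dataclass(frozen=True)
class CoverageLevels:
    """Multi-level coverage of one superfamily search.

    ``member_coverage`` is the fraction of the superfamily's own members
    recovered in the cumulative TP set; ``reference_member_coverage`` is
    the fraction of a wider reference member list (e.g. all classified
    superfamily entries) recovered; ``tp_homolog_count`` counts validated
    sequence homologs.
    """

    member_coverage: float
    reference_member_coverage: float
    tp_homolog_count: int
    structural_report: object = None

    def __post_init__(self):
        for f in (self.member_coverage, self.reference_member_coverage):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError("coverage fractions must lie in [0, 1]")


def compute_coverage_levels(
    cum_tp_set,
    member_gis,
    reference_member_gis=None,
    structural_report=None,
) -> CoverageLevels:
    """Coverage fractions of member lists within the cumulative TP set."""
    cum = set(cum_tp_set)

    def frac(gis):
        gis = list(gis)
        if not gis:
            return None
        return sum(1 for g in gis if g in cum) / len(gis)

    return CoverageLevels(
        member_coverage=frac(member_gis),
        reference_member_coverage=frac(reference_member_gis or member_gis),
        tp_homolog_count=len(cum),
        structural_report=structural_report,
    )


def approach_overlap(named_sets: dict) -> dict:
    """Exclusive region counts for up to four named GI sets.

    Returns ``{frozenset(names): count}`` over every nonempty combination
    of set names (15 regions for four sets); an element is counted in the
    region of exactly the sets that contain it.
    """
    if not 1 <= len(named_sets) <= 4:
        raise ValueError("between 1 and 4 named sets are required")
    names = sorted(named_sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set().union(*(set(named_sets[n]) for n in names if n not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def percent_covered(named_sets: dict, target: str, by: str):
    """Percent of ``target``'s elements also present in ``by``."""
    t = set(named_sets[target])
    if not t:
        return None
    return 100.0 * len(t & set(named_sets[by])) / len(t)


PGC_BINS = ((0.0, 25.0), (25.0, 50.0), (50.0, 75.0), (75.0, 100.0))


def pgc_bin(pgc: float) -> int:
    """Quartile bin (1-4) of a PGC percentage: 0-25, 26-50, 51-75, 76-100."""
    if pgc is None or not 0.0 <= pgc <= 100.0:
        raise ValueError(f"PGC {pgc!r} outside [0, 100]")
    for k, (lo, hi) in enumerate(PGC_BINS, 1):
        if pgc <= hi:
            return k
    raise AssertionError("unreachable")


def retention_histogram(runs) -> dict:
    """Counts of queries per retention bin (0 = immediate drift, 1-4)."""
    hist = {b: 0 for b in range(5)}
    for run in runs:
        hist[retention_trace(run)] += 1
    return hist


def results_table(results: list, scale_ppv: bool = False) -> pd.DataFrame:
    """Per-superfamily statistics table.

    One row per (superfamily, member) mirroring per-member hit/TP counts
    with superfamily-level Cum-TP, PPV and PGC.  ``scale_ppv`` emits PPV on
    a 0-1 scale instead of percent.
    """
    rows = []
    for res in results:
        for member in sorted(res.per_member_tp_sets):
            tp = len(res.per_member_tp_sets[member])
            ppv = res.ppv
            if ppv is not None and scale_ppv:
                ppv = ppv / 100.0
            rows.append(
                {
                    "superfamily": res.superfamily_id,
                    "member": member,
                    "tp": tp,
                    "is_brs": member == res.brs_member,
                    "cum_tp": res.cum_tp,
                    "all_hits": len(res.all_hits),
                    "ppv": None if ppv is None else round(ppv, 2),
                    "pgc": None if res.pgc is None else round(res.pgc, 2),
                }
            )
    return pd.DataFrame(rows)


def coverage_report(
    results: list,
    levels: dict = None,
    retention_runs: dict = None,
    scale_ppv: bool = False,
) -> dict:
    """Aggregate report: per-superfamily table, retention bins, PGC bins.

    ``levels`` maps superfamily id to :class:`CoverageLevels`;
    ``retention_runs`` maps superfamily id to its members' QueryRuns.
    Returns a dict of pandas DataFrames keyed by report name.
    """
    report = {"superfamilies": results_table(results, scale_ppv=scale_ppv)}

    if retention_runs:
        rows = []
        for sf, runs in sorted(retention_runs.items()):
            hist = retention_histogram(runs)
            rows.append({"superfamily": sf, **{f"bin{b}": hist[b] for b in range(5)}})
        report["retention_bins"] = pd.DataFrame(rows)

    pgc_rows = []
    for res in results:
        pgc_rows.append(
            {
                "superfamily": res.superfamily_id,
                "n_members": len(res.per_member_tp_sets),
                "pgc": res.pgc,
                "pgc_bin": None if res.pgc is None else pgc_bin(res.pgc),
            }
        )
    report["pgc_vs_members"] = pd.DataFrame(pgc_rows)

    if levels:
        rows = []
        for sf, lv in sorted(levels.items()):
            rows.append(
                {
                    "superfamily": sf,
                    "member_coverage": lv.member_coverage,
                    "reference_member_coverage": lv.reference_member_coverage,
                    "tp_homolog_count": lv.tp_homolog_count,
                    "cross_superfamily_structural": (
                        None
                        if lv.structural_report is None
                        else lv.structural_report.cross_superfamily_count
                    ),
                }
            )
        report["coverage_levels"] = pd.DataFrame(rows)
    return report


def write_report(report: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
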