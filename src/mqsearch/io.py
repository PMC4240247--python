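"""Readers and writers for the formats the toolkit touches.

FASTA via Biopython, hit lists and reports as TSV, query-run traces as
JSON-lines, configuration as YAML.  Malformed records are rejected with
the offending line or record named.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .backends import DbRecord
from .search import HitRecord, QueryRun, SearchConfig

HITS_COLUMNS = ("gi", "evalue", "pct_identity", "qstart", "qend", "sstart", "send", "iteration")


def read_fasta(path) -> list:
    """Read ``(id, sequence)`` pairs; duplicate ids are rejected."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sequence ids {dupes}")
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def write_database_fasta(database, path) -> None:
    """Labelled database as FASTA; the truth labels ride in the description."""
    recs = []
    for r in database:
        desc = f"label={r.label}"
        if r.member_id:
            desc += f" member={r.member_id}"
        if r.superfamily_id:
            desc += f" superfamily={r.superfamily_id}"
        if r.is_structural:
            desc += " structural=1"
        recs.append(SeqRecord(Seq(r.seq), id=r.gi, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def read_database_fasta(path) -> list:
    """Inverse of :func:`write_database_fasta`."""
    database = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok)
        database.append(
            DbRecord(
                gi=rec.id,
                seq=str(rec.seq).upper(),
                label=fields.get("label", "decoy"),
                member_id=fields.get("member"),
                superfamily_id=fields.get("superfamily"),
                is_structural=fields.get("structural") == "1",
            )
        )
    if not database:
        raise ValueError(f"{path}: no database records found")
    return database


def write_hits_tsv(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.gi}\t{h.evalue:.6g}\t{h.percent_identity:.4f}\t"
                f"{h.query_range[0]}\t{h.query_range[1]}\t"
                f"{h.subject_range[0]}\t{h.subject_range[1]}\t{h.iteration_found}\n"
            )


def read_hits_tsv(path) -> list:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != HITS_COLUMNS:
            raise ValueError(f"{path}: unexpected hit-table header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(HITS_COLUMNS):
                raise ValueError(f"{path} line {lineno}: expected {len(HITS_COLUMNS)} fields")
            try:
                hits.append(
                    HitRecord(
                        gi=parts[0],
                        evalue=float(parts[1]),
                        percent_identity=float(parts[2]),
                        query_range=(int(parts[3]), int(parts[4])),
                        subject_range=(int(parts[5]), int(parts[6])),
                        iteration_found=int(parts[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
    return hits


def write_runs_jsonl(runs, path) -> None:
    """Query-run traces, one JSON object per line."""
    with open(path, "w") as fh:
        for run in runs:
            fh.write(
                json.dumps(
                    {
                        "query_id": run.query_id,
                        "converged": run.converged,
                        "iterations": [sorted(s) for s in run.iterations],
                        "query_present": list(run.query_present_per_iteration),
                    }
                )
                + "\n"
            )


def read_runs_jsonl(path) -> list:
    runs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                runs.append(
                    QueryRun(
                        query_id=obj["query_id"],
                        iterations=tuple(frozenset(s) for s in obj["iterations"]),
                        converged=bool(obj["converged"]),
                        query_present_per_iteration=tuple(obj["query_present"]),
                    )
                )
            except (KeyError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
    return runs


def load_search_config(path) -> SearchConfig:
    """Search thresholds from a YAML or flat ``key=value`` file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        data = yaml.safe_load(text) or {}
    else:
        data = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path} line {lineno}: expected key=value")
            k, v = line.split("=", 1)
            data[k.strip()] = v.strip()
    kwargs = {}
    for key, cast in (
        ("evalue_threshold", float),
        ("inclusion_threshold", float),
        ("max_iterations", int),
        ("preset", str),
    ):
        if key in data:
            kwargs[key] = cast(data[key])
    return SearchConfig(**kwargs)


def write_provenance(path, **fields) -> None:
    """Record how an output directory was produced (config, seed, version)."""
    from . import __version__

    payload = {"mqsearch_version": __version__, **fields}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
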