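"""Gold-standard evidence filtering and edge-list deduplication.

The filter keeps a record when either (a) it comes from an IMEx-style source
(``mitab`` or ``annotation_export``), which are treated as already curated,
or (b) it is a low-throughput record carrying at least one accepted
direct-binding assay (luciferase reporter or RNA immunoprecipitation by
default).  Western blot and qPCR alone are insufficient — they can reflect
indirect effects — but their presence alongside an accepted assay does not
disqualify a record.  Records whose throughput is ``unknown`` are treated
as high-throughput (conservative).
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .records import InteractionRecord

IMEX_SOURCES = frozenset({"mitab", "annotation_export"})

REASON_HIGH_THROUGHPUT = "high_throughput"
REASON_NO_DIRECT_BINDING = "no_direct_binding_evidence"


@dataclass(frozen=True)
class FilterPolicy:
    accepted_methods: frozenset[str] = frozenset({"luciferase_reporter", "rna_ip"})
    rejected_methods: frozenset[str] = frozenset({"western_blot", "qpcr"})
    require_low_throughput: bool = True
    imex_passthrough: bool = True

    def __post_init__(self) -> None:
        if self.accepted_methods & self.rejected_methods:
            raise ValueError("accepted and rejected method sets overlap")


@dataclass(frozen=True)
class Edge:
    """One unique miRNA-gene interaction with aggregated provenance."""

    mirna_id: str
    gene_id: str
    n_supporting_records: int
    sources: frozenset[str]
    pubmed_ids: frozenset[str]

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def filter_evidence(
    records: Sequence[InteractionRecord],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[InteractionRecord], list[tuple[InteractionRecord, str]]]:
    """Partition records into (kept, removed-with-reason).

    kept + removed always sums to the input count; the filter is idempotent.
    """
    kept: list[InteractionRecord] = []
    removed: list[tuple[InteractionRecord, str]] = []
    for r in records:
        if policy.imex_passthrough and r.source_db in IMEX_SOURCES:
            kept.append(r)
            continue
        if policy.require_low_throughput and r.throughput != "low":
            removed.append((r, REASON_HIGH_THROUGHPUT))
            continue
        if r.methods & policy.accepted_methods:
            kept.append(r)
        else:
            removed.append((r, REASON_NO_DIRECT_BINDING))
    return kept, removed


def deduplicate(records: Sequence[InteractionRecord]) -> list[Edge]:
    """Collapse records to one :class:`Edge` per (miRNA, gene) pair.

    Provenance (supporting-record count, source databases, PubMed ids) is
    aggregated.  Output is sorted by (mirna_id, gene_id) so the result is
    independent of input order.
    """
    groups: dict[tuple[str, str], list[InteractionRecord]] = defaultdict(list)
    for r in records:
        groups[(r.mirna_id, r.target_id)].append(r)
    edges = [
        Edge(
            mirna_id=m,
            gene_id=g,
            n_supporting_records=len(rs),
            sources=frozenset(r.source_db for r in rs),
            pubmed_ids=frozenset(r.pubmed_id for r in rs if r.pubmed_id),
        )
        for (m, g), rs in groups.items()
    ]
    edges.sort(key=lambda e: e.key)
    return edges


def write_edges(edges: Sequence[Edge], path: str | Path) -> None:
    """Write the pipeline's central artifact: the deduplicated edge TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["mirna_id", "gene_id", "n_supporting_records", "sources",
                    "pubmed_ids"])
        for e in edges:
            w.writerow([
                e.mirna_id, e.gene_id, e.n_supporting_records,
                ",".join(sorted(e.sources)), ",".join(sorted(e.pubmed_ids)),
            ])


def read_edges(path: str | Path) -> list[Edge]:
    edges: list[Edge] = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            edges.append(
                Edge(
                    mirna_id=row["mirna_id"],
                    gene_id=row["gene_id"],
                    n_supporting_records=int(row["n_supporting_records"]),
                    sources=frozenset(s for s in row["sources"].split(",") if s),
                    pubmed_ids=frozenset(p for p in row["pubmed_ids"].split(",") if p),
                )
            )
    return edges
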