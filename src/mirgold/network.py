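"""Bipartite miRNA-mRNA network: degrees, degree classes, hubs, overlaps.

A node's degree is its number of distinct partners on the other side.  The
*degree class* (abundance) of a degree value d is the number of nodes whose
degree is exactly d — e.g. two genes each bound by 94 miRNAs put degree 94
in degree class 2.  Genes with more than 20 distinct miRNA regulators are
called hubs.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .curation import Edge


@dataclass
class Network:
    edges: set[tuple[str, str]]
    mirna_degree: dict[str, int]
    gene_degree: dict[str, int]

    def degrees(self, side: str) -> dict[str, int]:
        if side == "mirna":
            return self.mirna_degree
        if side == "gene":
            return self.gene_degree
        raise ValueError(f"side must be 'mirna' or 'gene', got {side!r}")

    def targets_of(self, mirna_id: str) -> set[str]:
        if mirna_id not in self.mirna_degree:
            raise KeyError(f"unknown miRNA {mirna_id!r}")
        return {g for m, g in self.edges if m == mirna_id}


@dataclass
class DegreeAbundance:
    """Pairs (degree, abundance) sorted by increasing degree, for one side."""

    pairs: list[tuple[int, int]]
    side: str

    def degree_multiset(self) -> list[int]:
        """Reconstruct the degree sequence (each degree repeated abundance times)."""
        out: list[int] = []
        for d, a in self.pairs:
            out.extend([d] * a)
        return out

    def abundance_of(self, degree: int) -> int:
        for d, a in self.pairs:
            if d == degree:
                return a
        return 0


def build_network(edges: Sequence[Edge | tuple[str, str]]) -> Network:
    """Assemble the bipartite network from a deduplicated edge list."""
    pairs: list[tuple[str, str]] = [
        e.key if isinstance(e, Edge) else (str(e[0]), str(e[1])) for e in edges
    ]
    if len(pairs) != len(set(pairs)):
        dup = [k for k, c in Counter(pairs).items() if c > 1][:3]
        raise ValueError(f"duplicate edges in input (deduplicate first), e.g. {dup}")
    mirna_degree: Counter[str] = Counter()
    gene_degree: Counter[str] = Counter()
    for m, g in pairs:
        mirna_degree[m] += 1
        gene_degree[g] += 1
    return Network(set(pairs), dict(mirna_degree), dict(gene_degree))


def degree_abundance(network: Network, side: str) -> DegreeAbundance:
    counts = Counter(network.degrees(side).values())
    return DegreeAbundance(sorted(counts.items()), side)


def abundance_from_degrees(degrees: Iterable[int], side: str = "gene") -> DegreeAbundance:
    """Degree classes straight from a degree multiset (no network needed)."""
    return DegreeAbundance(sorted(Counter(degrees).items()), side)


def find_hubs(network: Network, side: str = "gene", threshold: int = 20) -> list[str]:
    """Nodes with degree strictly greater than ``threshold`` ("more than 20"),
    sorted by degree descending, then id."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    deg = network.degrees(side)
    hubs = [n for n, d in deg.items() if d > threshold]
    hubs.sort(key=lambda n: (-deg[n], n))
    return hubs


def target_overlap(
    network: Network, mirna_ids: Sequence[str], mode: str = "pairwise"
) -> dict:
    """Venn-style intersections of the target sets of the queried miRNAs.

    ``pairwise`` returns, per pair, the set sizes, intersection size and
    sorted members.  ``full`` returns counts (and members) per Venn region,
    keyed by the '&'-joined subset of miRNA ids belonging to that region.
    """
    if mode not in ("pairwise", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    sets = {m: network.targets_of(m) for m in mirna_ids}  # raises on unknown id
    if mode == "pairwise":
        out = []
        for a, b in combinations(mirna_ids, 2):
            inter = sets[a] & sets[b]
            out.append({
                "a": a, "b": b,
                "size_a": len(sets[a]), "size_b": len(sets[b]),
                "intersection_size": len(inter),
                "union_size": len(sets[a] | sets[b]),
                "members": sorted(inter),
            })
        return {"mode": "pairwise", "pairs": out}
    # full: assign every gene in the union to its exact membership region
    regions: dict[str, list[str]] = {}
    universe = set().union(*sets.values()) if sets else set()
    for g in universe:
        members = frozenset(m for m in mirna_ids if g in sets[m])
        key = "&".join(m for m in mirna_ids if m in members)
        regions.setdefault(key, []).append(g)
    return {
        "mode": "full",
        "regions": {k: {"count": len(v), "members": sorted(v)}
                    for k, v in sorted(regions.items())},
    }


# ---------------------------------------------------------------------------
# TSV writers

def write_degree_abundance(da: DegreeAbundance, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["degree", "abundance"])
        for d, a in da.pairs:
            w.writerow([d, a])


def write_hubs(hubs: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(hubs) + ("\n" if hubs else ""))


def write_overlap(overlap: dict, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if overlap["mode"] == "pairwise":
            w.writerow(["a", "b", "size_a", "size_b", "intersection_size",
                        "union_size", "members"])
            for p in overlap["pairs"]:
                w.writerow([p["a"], p["b"], p["size_a"], p["size_b"],
                            p["intersection_size"], p["union_size"],
                            ",".join(p["members"])])
        else:
            w.writerow(["region", "count", "members"])
            for k, v in overlap["regions"].items():
                w.writerow([k, v["count"], ",".join(v["members"])])
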