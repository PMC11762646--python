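"""Hypergeometric over-representation of annotation terms in a gene set.

For a term annotating K of the N universe genes, with k of the n query
genes carrying it, the enrichment p-value is the hypergeometric upper tail
P(X >= k).  One-sided over-representation only.  Both the raw-p threshold
(default 0.0005, against the whole-genome universe) and Benjamini-Hochberg
q-values are reported; a flag selects which drives the ``significant``
column.  An optional term-parent map lets each gene's annotations be closed
upward before counting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationSet:
    """Unique (gene_id, term_id) pairs plus an optional term parent map."""

    pairs: set[tuple[str, str]]
    parents: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   parents: dict[str, set[str]] | None = None) -> "AnnotationSet":
        return cls(set((str(g), str(t)) for g, t in pairs), dict(parents or {}))

    @classmethod
    def read(cls, path: str | Path,
             parents_path: str | Path | None = None) -> "AnnotationSet":
        pairs: set[tuple[str, str]] = set()
        with Path(path).open() as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                pairs.add((row["gene_id"].strip(), row["term_id"].strip()))
        parents: dict[str, set[str]] = {}
        if parents_path is not None:
            with Path(parents_path).open() as fh:
                reader = csv.DictReader(fh, delimiter="\t")
                for row in reader:
                    parents.setdefault(row["term_id"].strip(), set()).add(
                        row["parent_id"].strip())
        return cls(pairs, parents)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "term_id"])
            for g, t in sorted(self.pairs):
                w.writerow([g, t])

    def terms_of(self, gene: str, propagate: bool = False) -> set[str]:
        terms = {t for g, t in self.pairs if g == gene}
        if propagate:
            terms = self._close(terms)
        return terms

    def _close(self, terms: set[str]) -> set[str]:
        out = set(terms)
        frontier = list(terms)
        while frontier:
            t = frontier.pop()
            for p in self.parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    def gene_to_terms(self, propagate: bool = False) -> dict[str, set[str]]:
        g2t: dict[str, set[str]] = {}
        for g, t in self.pairs:
            g2t.setdefault(g, set()).add(t)
        if propagate:
            g2t = {g: self._close(ts) for g, ts in g2t.items()}
        return g2t


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    k: int   # query genes with term
    K: int   # universe genes with term
    n: int   # query set size
    N: int   # universe size
    p: float
    q: float
    significant: bool


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), log-space stable."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(gene_set: Sequence[str], universe: Sequence[str],
           annotations: AnnotationSet, alpha: float = 0.0005,
           propagate: bool = False,
           significance_by: str = "p") -> list[EnrichmentRow]:
    """Term over-representation of ``gene_set`` against ``universe``.

    Query genes outside the universe are dropped with a warning.  One row
    per term annotating at least one universe gene, sorted by p ascending;
    ``significance_by`` is ``"p"`` (raw threshold at ``alpha``) or ``"q"``
    (BH threshold at ``alpha``).
    """
    import logging

    if significance_by not in ("p", "q"):
        raise ValueError("significance_by must be 'p' or 'q'")
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty universe")
    query = set(map(str, gene_set))
    stray = query - uni
    if stray:
        logging.getLogger(__name__).warning(
            "%d query genes outside the universe dropped: %s",
            len(stray), sorted(stray)[:5])
        query &= uni

    g2t = annotations.gene_to_terms(propagate=propagate)
    term_universe: dict[str, int] = {}
    term_query: dict[str, int] = {}
    for g in uni:
        for t in g2t.get(g, ()):
            term_universe[t] = term_universe.get(t, 0) + 1
            if g in query:
                term_query[t] = term_query.get(t, 0) + 1

    N, n = len(uni), len(query)
    terms = sorted(term_universe)
    ps = [hypergeom_tail(term_query.get(t, 0), term_universe[t], n, N)
          for t in terms]
    qs = bh_adjust(ps) if terms else []
    rows = [
        EnrichmentRow(term_id=t, k=term_query.get(t, 0), K=term_universe[t],
                      n=n, N=N, p=p, q=q,
                      significant=(p if significance_by == "p" else q) < alpha)
        for t, p, q in zip(terms, ps, qs)
    ]
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def write_enrichment(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term_id", "k", "K", "n", "N", "p", "q", "significant"])
        for r in rows:
            w.writerow([r.term_id, r.k, r.K, r.n, r.N,
                        f"{r.p:.6g}", f"{r.q:.6g}", int(r.significant)])
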