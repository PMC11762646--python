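"""Parsing of miRNA-mRNA interaction records from four source dialects.

Supported dialects
------------------
``mitab``
    PSI-MITAB 2.7, tab-separated, >= 15 columns, no header. Interactor A is
    the miRNA and interactor B the target transcript by fixture convention;
    the detection method is read from column 7, taxa from columns 10/11.
``mirtarbase``
    TSV with header ``mirna, species_mirna, target_gene, species_target,
    experiments, support_type, pmid``; the ``experiments`` field holds
    ``//``-separated assay names, ``support_type`` encodes evidence strength
    ("Functional MTI" = low-throughput, "Functional MTI (Weak)" = weak /
    high-throughput).
``rnainter``
    TSV with header ``id1, id2, category1, category2, species1, species2,
    method, score, pmid, throughput``.
``annotation_export``
    GPAD/GAF-like TSV with header ``mirna, target, taxon, evidence_code,
    reference``.

Every reader returns a :class:`ParseResult` with well-formed records and a
list of rejected rows carrying machine-readable reasons; malformed rows are
never silently dropped.  Only human records (taxon 9606) are accepted.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

HUMAN_TAXON = 9606

SOURCE_DBS = ("mitab", "mirtarbase", "rnainter", "annotation_export")

#: controlled evidence-method vocabulary
METHODS = frozenset(
    {
        "luciferase_reporter",
        "rna_ip",
        "western_blot",
        "qpcr",
        "clip_seq",
        "clash",
        "microarray",
        "sequencing",
        "other",
    }
)

# ordered substring rules; first hit wins.  CLASH/CLIP come before the
# generic immunoprecipitation rule so that "CLIP-seq" is not classed as RNA-IP.
_METHOD_RULES: tuple[tuple[str, str], ...] = (
    ("clash", "clash"),
    ("clip", "clip_seq"),
    ("luciferase", "luciferase_reporter"),
    ("reporter assay", "luciferase_reporter"),
    ("reporter gene", "luciferase_reporter"),
    ("western", "western_blot"),
    ("immunoblot", "western_blot"),
    ("qpcr", "qpcr"),
    ("qrt-pcr", "qpcr"),
    ("rt-qpcr", "qpcr"),
    ("real-time pcr", "qpcr"),
    ("real time pcr", "qpcr"),
    ("microarray", "microarray"),
    ("sequencing", "sequencing"),
    ("rna-seq", "sequencing"),
    ("degradome", "sequencing"),
    ("rna-ip", "rna_ip"),
    ("rna ip", "rna_ip"),
    ("immunoprecip", "rna_ip"),
    ("pull-down", "rna_ip"),
    ("pull down", "rna_ip"),
)

_SPECIES_TO_TAXON = {
    "homo sapiens": HUMAN_TAXON,
    "human": HUMAN_TAXON,
    "hsa": HUMAN_TAXON,
    "9606": HUMAN_TAXON,
    "mus musculus": 10090,
    "mouse": 10090,
    "rattus norvegicus": 10116,
    "rat": 10116,
}


def normalize_method(label: str) -> str:
    """Map a free-text assay label onto the controlled vocabulary.

    Exact vocabulary tokens map to themselves; anything unrecognized becomes
    ``other`` (never an error: dirty exports are expected).
    """
    s = label.strip().lower()
    if s in METHODS:
        return s
    for needle, term in _METHOD_RULES:
        if needle in s:
            return term
    return "other"


@dataclass(frozen=True)
class InteractionRecord:
    """One source-database row, normalized."""

    source_db: str
    mirna_id: str
    target_id: str
    taxon: int
    methods: frozenset[str]
    throughput: str  # low | high | unknown
    pubmed_id: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        if self.throughput not in ("low", "high", "unknown"):
            raise ValueError(f"bad throughput {self.throughput!r}")


@dataclass(frozen=True)
class RejectedRow:
    line_no: int
    reason: str
    raw: str


@dataclass
class ParseResult:
    records: list[InteractionRecord]
    rejected: list[RejectedRow]


@dataclass
class MappingReport:
    mapped: int = 0
    unchanged: int = 0
    unmapped_kept: int = 0
    unmapped_dropped: int = 0


def _resolve_taxon(value: str) -> int | None:
    v = value.strip().lower()
    m = re.match(r"taxid:(-?\d+)", v)
    if m:
        return int(m.group(1))
    if v in _SPECIES_TO_TAXON:
        return _SPECIES_TO_TAXON[v]
    try:
        return int(v)
    except ValueError:
        return None


def _species_check(
    raw_a: str, raw_b: str, line_no: int, raw_line: str
) -> tuple[int | None, RejectedRow | None]:
    """Both interactors must be human; disagreement is rejected outright.

    An unresolvable species string cannot be verified as human, so the row
    is rejected as non-human rather than waved through.
    """
    ta, tb = _resolve_taxon(raw_a), _resolve_taxon(raw_b)
    if ta is not None and tb is not None and ta != tb:
        return None, RejectedRow(line_no, "species_conflict", raw_line)
    if ta is None or tb is None or ta <= 0 or ta != HUMAN_TAXON:
        return None, RejectedRow(line_no, "non-human", raw_line)
    return ta, None


def _basic_checks(
    mirna: str, target: str, methods: frozenset[str], line_no: int, raw: str
) -> RejectedRow | None:
    if not mirna.strip():
        return RejectedRow(line_no, "empty mirna_id", raw)
    if not target.strip():
        return RejectedRow(line_no, "empty target_id", raw)
    if not methods:
        return RejectedRow(line_no, "no_evidence_method", raw)
    return None


_PAREN = re.compile(r"\(([^()]*)\)")


def _mitab_free_text(fieldval: str) -> str:
    """Pull the human-readable part out of a ``psi-mi:"MI:0045"(text)`` field."""
    m = _PAREN.search(fieldval)
    return m.group(1) if m else fieldval


def _mitab_id(fieldval: str) -> str:
    # "mirbase:hsa-miR-155-5p" -> "hsa-miR-155-5p"; bare ids pass through
    part = fieldval.split("|")[0].strip()
    if ":" in part:
        part = part.split(":", 1)[1]
    return part.strip().strip('"')


def _read_mitab(lines: Iterable[str]) -> ParseResult:
    records: list[InteractionRecord] = []
    rejected: list[RejectedRow] = []
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            rejected.append(RejectedRow(i, "malformed_row", line))
            continue
        mirna = _mitab_id(cols[0])
        target = _mitab_id(cols[1])
        method = normalize_method(_mitab_free_text(cols[6]))
        methods = frozenset({method})
        pmid = ""
        for tok in cols[8].split("|"):
            if tok.lower().startswith("pubmed:"):
                pmid = tok.split(":", 1)[1]
                break
        taxon, rej = _species_check(cols[9], cols[10], i, line)
        if rej is not None:
            rejected.append(rej)
            continue
        bad = _basic_checks(mirna, target, methods, i, line)
        if bad is not None:
            rejected.append(bad)
            continue
        records.append(
            InteractionRecord(
                source_db="mitab",
                mirna_id=mirna,
                target_id=target,
                taxon=taxon,
                methods=methods,
                throughput="low",  # IMEx-consistent records are curated
                pubmed_id=pmid,
            )
        )
    return ParseResult(records, rejected)


def _require_columns(header: Sequence[str], needed: Sequence[str], dialect: str) -> None:
    missing = [c for c in needed if c not in header]
    if missing:
        raise ValueError(f"{dialect} file missing required columns: {missing}")


def _read_tsv_dialect(lines: Iterable[str], dialect: str) -> ParseResult:
    reader = csv.DictReader(lines, delimiter="\t")
    needed = {
        "mirtarbase": ["mirna", "species_mirna", "target_gene", "species_target",
                       "experiments", "support_type", "pmid"],
        "rnainter": ["id1", "id2", "category1", "category2", "species1",
                     "species2", "method", "score", "pmid", "throughput"],
        "annotation_export": ["mirna", "target", "taxon", "evidence_code",
                              "reference"],
    }[dialect]
    _require_columns(reader.fieldnames or [], needed, dialect)

    records: list[InteractionRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        raw = "\t".join("" if row.get(c) is None else row[c] for c in needed)
        if dialect == "mirtarbase":
            mirna, target = row["mirna"].strip(), row["target_gene"].strip()
            methods = frozenset(
                normalize_method(t) for t in row["experiments"].split("//") if t.strip()
            )
            st = row["support_type"].strip().lower()
            if "weak" in st:
                throughput = "high"
            elif "functional mti" in st:
                throughput = "low"
            else:
                throughput = "unknown"
            taxon, rej = _species_check(row["species_mirna"], row["species_target"], i, raw)
            pmid, score = row["pmid"].strip(), None
        elif dialect == "rnainter":
            mirna, target = row["id1"].strip(), row["id2"].strip()
            methods = frozenset(
                normalize_method(t)
                for t in re.split(r"//|;", row["method"])
                if t.strip()
            )
            tp = row["throughput"].strip().lower()
            throughput = tp if tp in ("low", "high") else "unknown"
            taxon, rej = _species_check(row["species1"], row["species2"], i, raw)
            pmid = row["pmid"].strip()
            try:
                score = float(row["score"])
            except (TypeError, ValueError):
                score = None
        else:  # annotation_export
            mirna, target = row["mirna"].strip(), row["target"].strip()
            methods = frozenset({normalize_method(row["evidence_code"])})
            throughput = "low"  # curated GO-style annotation
            taxon, rej = _species_check(row["taxon"], row["taxon"], i, raw)
            pmid, score = row["reference"].strip(), None
            if pmid.lower().startswith("pmid:"):
                pmid = pmid.split(":", 1)[1]

        if rej is not None:
            rejected.append(rej)
            continue
        bad = _basic_checks(mirna, target, methods, i, raw)
        if bad is not None:
            rejected.append(bad)
            continue
        records.append(
            InteractionRecord(
                source_db=dialect,
                mirna_id=mirna,
                target_id=target,
                taxon=taxon,
                methods=methods,
                throughput=throughput,
                pubmed_id=pmid,
                score=score,
            )
        )
    return ParseResult(records, rejected)


def read_interactions(path: str | Path, dialect: str) -> ParseResult:
    """Parse one source file into normalized records plus rejected rows."""
    if dialect not in SOURCE_DBS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {SOURCE_DBS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        if dialect == "mitab":
            return _read_mitab(fh)
        return _read_tsv_dialect(fh, dialect)


# ---------------------------------------------------------------------------
# writers (used by the synthetic-data generator and for round-trip checks)

_DEFAULT_MI = {
    "luciferase_reporter": "MI:2285",
    "rna_ip": "MI:1017",
    "western_blot": "MI:0113",
    "qpcr": "MI:1195",
}


def write_interactions(records: Sequence[InteractionRecord], path: str | Path,
                       dialect: str) -> None:
    """Serialize records in one of the four dialects (inverse of the reader)."""
    path = Path(path)
    lines: list[str] = []
    if dialect == "mitab":
        for r in records:
            method = sorted(r.methods)[0]
            mi = _DEFAULT_MI.get(method, "MI:0045")
            cols = [
                f"mirbase:{r.mirna_id}",
                f"ensembl:{r.target_id}",
                "-", "-", "-", "-",
                f'psi-mi:"{mi}"({method})',
                "-",
                f"pubmed:{r.pubmed_id}" if r.pubmed_id else "-",
                f"taxid:{r.taxon}(Homo sapiens)",
                f"taxid:{r.taxon}(Homo sapiens)",
                'psi-mi:"MI:0915"(physical association)',
                'psi-mi:"MI:0469"(IntAct)',
                "-", "-",
            ]
            lines.append("\t".join(cols))
    elif dialect == "mirtarbase":
        lines.append("mirna\tspecies_mirna\ttarget_gene\tspecies_target\t"
                     "experiments\tsupport_type\tpmid")
        st = {"low": "Functional MTI", "high": "Functional MTI (Weak)", "unknown": ""}
        for r in records:
            lines.append("\t".join([
                r.mirna_id, "Homo sapiens", r.target_id, "Homo sapiens",
                "//".join(sorted(r.methods)), st[r.throughput], r.pubmed_id,
            ]))
    elif dialect == "rnainter":
        lines.append("id1\tid2\tcategory1\tcategory2\tspecies1\tspecies2\t"
                     "method\tscore\tpmid\tthroughput")
        for r in records:
            lines.append("\t".join([
                r.mirna_id, r.target_id, "miRNA", "mRNA",
                "Homo sapiens", "Homo sapiens",
                "//".join(sorted(r.methods)),
                "" if r.score is None else f"{r.score:g}",
                r.pubmed_id, r.throughput,
            ]))
    elif dialect == "annotation_export":
        lines.append("mirna\ttarget\ttaxon\tevidence_code\treference")
        for r in records:
            lines.append("\t".join([
                r.mirna_id, r.target_id, str(r.taxon),
                sorted(r.methods)[0],
                f"PMID:{r.pubmed_id}" if r.pubmed_id else "",
            ]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# identifier mapping

def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a 2-column (alias, canonical) TSV with header.

    Duplicate aliases pointing at different canonicals are a hard error:
    an ambiguous mapping would silently corrupt the edge list.
    """
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader.fieldnames or [], ["alias", "canonical"], "id mapping")
        for row in reader:
            alias, canonical = row["alias"].strip(), row["canonical"].strip()
            if not alias:
                continue
            if alias in mapping and mapping[alias] != canonical:
                raise ValueError(
                    f"conflicting mapping for alias {alias!r}: "
                    f"{mapping[alias]!r} vs {canonical!r}"
                )
            mapping[alias] = canonical
    return mapping


def map_identifiers(
    records: Sequence[InteractionRecord],
    mapping: dict[str, str],
    policy: str = "keep_unmapped",
) -> tuple[list[InteractionRecord], MappingReport]:
    """Canonicalize target identifiers through an alias table.

    ``policy`` is ``keep_unmapped`` (identifiers absent from the table pass
    through unchanged) or ``drop_unmapped``.  A target already equal to a
    canonical value counts as ``unchanged``.  Idempotent as long as the
    mapping's canonical values are not themselves aliases of something else.
    """
    if policy not in ("keep_unmapped", "drop_unmapped"):
        raise ValueError(f"unknown policy {policy!r}")
    canonicals = set(mapping.values())
    out: list[InteractionRecord] = []
    report = MappingReport()
    for r in records:
        if r.target_id in mapping:
            new = mapping[r.target_id]
            if new == r.target_id:
                report.unchanged += 1
                out.append(r)
            else:
                report.mapped += 1
                out.append(replace(r, target_id=new))
        elif r.target_id in canonicals or policy == "keep_unmapped":
            if r.target_id in canonicals:
                report.unchanged += 1
            else:
                report.unmapped_kept += 1
            out.append(r)
        else:
            report.unmapped_dropped += 1
    return out, report
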