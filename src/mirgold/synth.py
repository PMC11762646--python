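"""Synthetic pipeline inputs with known ground truth.

The generator emulates the statistical structure of curated miRNA-target
resources: a bipartite network whose miRNA degrees follow a (truncated)
zeta power law, heavy-tailed gene in-degrees induced by preferential
partner choice, multi-source interaction records with mixed evidence codes,
duplicated and aliased entries, a planted enriched term among hub genes, a
transcription-factor table with tunable dependence between miRNA in-degree
and regulon size, and a UTR table with planted correlations.  Every output
is a pure function of the configuration (seed included), so each pipeline
stage has a recovery test with an exact expected answer and no downloads.

Defaults mirror the scale of curated human data: 962 miRNAs and 3842
target genes, zeta exponent 1.8 on the miRNA side (chosen to reproduce the
heavy tail of curated collections, where roughly 1% of miRNAs exceed 100
validated targets), 20% noise edges supported only by weak or
high-throughput evidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .curation import Edge
from .enrichment import AnnotationSet
from .network import Network, build_network
from .records import InteractionRecord, write_interactions

logger = logging.getLogger(__name__)

ACCEPTED_SYNTH_METHODS = ("luciferase_reporter", "rna_ip")
REJECTED_SYNTH_METHODS = ("western_blot", "qpcr")


@dataclass
class SynthConfig:
    seed: int                      # mandatory; every draw derives from it
    n_mirna: int = 962
    n_gene: int = 3842
    alpha_mirna: float = 1.8
    gene_weight_alpha: float = 2.0
    noise_edge_fraction: float = 0.2
    dup_rate: float = 0.1
    alias_rate: float = 0.1
    n_terms: int = 50
    planted_term_odds: float = 5.0
    mi_link_strength: float = 1.0
    utr_rho_pred: float = 0.7
    utr_rho_verified: float = 0.3

    def __post_init__(self) -> None:
        if self.alpha_mirna <= 1 or self.gene_weight_alpha <= 1:
            raise ValueError("power-law exponents must be > 1")
        if not 0 <= self.noise_edge_fraction < 1:
            raise ValueError("noise_edge_fraction must be in [0, 1)")
        if not 0 <= self.alias_rate < 1:
            raise ValueError("alias_rate must be in [0, 1)")
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be >= 0")


def sample_zeta_degrees(n: int, alpha: float, d_max: int, seed) -> np.ndarray:
    """i.i.d. draws from the zeta distribution truncated at d_max.

    Inverse-CDF sampling on the precomputed mass table; the truncation is a
    sampling device only (likelihoods elsewhere use the full support).
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    rng = np.random.default_rng(seed)
    support = np.arange(1, d_max + 1, dtype=float)
    cdf = np.cumsum(support ** (-alpha))
    cdf /= cdf[-1]
    return (np.searchsorted(cdf, rng.random(n)) + 1).astype(int)


def _mirna_name(i: int) -> str:
    return f"hsa-miR-SIM-{i + 1}"


def _gene_name(j: int) -> str:
    return f"GENE{j + 1:05d}"


def build_true_network(config: SynthConfig) -> tuple[Network, dict[tuple[str, str], str]]:
    """Bipartite network plus per-edge truth labels ('gold' / 'noise').

    Each miRNA draws its degree from the truncated zeta law and picks that
    many distinct gene partners with probability proportional to per-gene
    Pareto-tailed weights (weighted sampling without replacement via the
    Gumbel-top-k trick), which induces a right-skewed gene degree
    distribution.  Noise edges are extra pairs, disjoint from the gold set,
    that will later receive only weak or high-throughput evidence.
    """
    rng = np.random.default_rng(config.seed)
    degrees = sample_zeta_degrees(config.n_mirna, config.alpha_mirna,
                                  d_max=config.n_gene,
                                  seed=rng.integers(2**31))
    if np.any(degrees > config.n_gene):
        logger.warning("capping %d miRNA degrees at n_gene=%d",
                       int(np.sum(degrees > config.n_gene)), config.n_gene)
        degrees = np.minimum(degrees, config.n_gene)

    # Pareto-tailed attractiveness: P(W > t) = t^-(gene_weight_alpha - 1)
    u = rng.random(config.n_gene)
    weights = (1.0 - u) ** (-1.0 / (config.gene_weight_alpha - 1.0))
    logw = np.log(weights)

    gold: set[tuple[str, str]] = set()
    for i, d in enumerate(degrees):
        keys = logw + rng.gumbel(size=config.n_gene)
        partners = np.argpartition(keys, -d)[-d:]
        for j in partners:
            gold.add((_mirna_name(i), _gene_name(int(j))))

    labels = {e: "gold" for e in gold}
    f = config.noise_edge_fraction
    n_noise = int(round(f / (1.0 - f) * len(gold)))
    attempts = 0
    while n_noise > 0 and attempts < 50 * n_noise:
        i = int(rng.integers(config.n_mirna))
        j = int(rng.integers(config.n_gene))
        e = (_mirna_name(i), _gene_name(j))
        attempts += 1
        if e not in labels:
            labels[e] = "noise"
            n_noise -= 1
    net = build_network(sorted(labels))
    return net, labels


def emit_records(network: Network, labels: dict[tuple[str, str], str],
                 config: SynthConfig, outdir: str | Path) -> dict:
    """Write the pre-filter state: record files in all four dialects, the
    alias mapping table, and a ground-truth manifest.

    Gold edges get at least one low-throughput record with an accepted
    direct-binding assay; noise edges get only weak-method or
    high-throughput records (and only in the non-IMEx dialects, which the
    filter actually tests).  ``dup_rate`` adds duplicate records;
    ``alias_rate`` writes an extra record per selected edge under an alias
    identifier, with the matching mapping file emitted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)

    by_dialect: dict[str, list[InteractionRecord]] = {
        "mitab": [], "mirtarbase": [], "rnainter": [], "annotation_export": []
    }
    aliases: dict[str, str] = {}
    edges = sorted(labels)

    def gold_record(m: str, g: str, dialect: str) -> InteractionRecord:
        method = ACCEPTED_SYNTH_METHODS[int(rng.random() < 0.2)]
        methods = {method}
        if rng.random() < 0.3:  # mixed evidence: accepted + insufficient assay
            methods.add(REJECTED_SYNTH_METHODS[int(rng.random() < 0.5)])
        return InteractionRecord(
            source_db=dialect, mirna_id=m, target_id=g, taxon=9606,
            methods=frozenset(methods), throughput="low",
            pubmed_id=str(int(rng.integers(10_000_000, 40_000_000))),
        )

    def noise_record(m: str, g: str) -> tuple[str, InteractionRecord]:
        dialect = ("mirtarbase", "rnainter")[int(rng.random() < 0.5)]
        if rng.random() < 0.5:  # weak assay, low throughput
            methods, throughput = {REJECTED_SYNTH_METHODS[int(rng.random() < 0.5)]}, "low"
        else:                   # strong assay but high-throughput screen
            methods, throughput = {"clip_seq"}, "high"
        return dialect, InteractionRecord(
            source_db=dialect, mirna_id=m, target_id=g, taxon=9606,
            methods=frozenset(methods), throughput=throughput,
            pubmed_id=str(int(rng.integers(10_000_000, 40_000_000))),
            score=round(float(rng.random()), 3) if dialect == "rnainter" else None,
        )

    dialect_names = list(by_dialect)
    for m, g in edges:
        if labels[(m, g)] == "gold":
            dialect = dialect_names[int(rng.integers(4))]
            rec = gold_record(m, g, dialect)
            by_dialect[dialect].append(rec)
            if rng.random() < config.dup_rate:
                by_dialect[dialect].append(rec)
            if rng.random() < config.alias_rate:
                alias = f"ALIAS:{g}"
                aliases[alias] = g
                extra_dialect = dialect_names[int(rng.integers(4))]
                extra = gold_record(m, alias, extra_dialect)
                by_dialect[extra_dialect].append(extra)
        else:
            dialect, rec = noise_record(m, g)
            by_dialect[dialect].append(rec)
            if rng.random() < config.dup_rate:
                by_dialect[dialect].append(rec)

    paths = {}
    for dialect, recs in by_dialect.items():
        suffix = "mitab.txt" if dialect == "mitab" else f"{dialect}.tsv"
        p = outdir / f"records_{suffix}"
        write_interactions(recs, p, dialect)
        paths[dialect] = p.name  # names, not paths: manifests stay
        # byte-identical across output directories

    mapping_path = outdir / "id_mapping.tsv"
    lines = ["alias\tcanonical"] + [f"{a}\t{c}" for a, c in sorted(aliases.items())]
    mapping_path.write_text("\n".join(lines) + "\n")

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "files": {**paths, "id_mapping": mapping_path.name},
        "n_records": {d: len(rs) for d, rs in by_dialect.items()},
        "edges": [{"mirna_id": m, "gene_id": g, "label": labels[(m, g)]}
                  for m, g in edges],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def plant_enrichment(genes, hubs, config: SynthConfig,
                     seed: int | None = None) -> AnnotationSet:
    """Annotation table with one term over-represented among hub genes.

    The planted term T0000 annotates hubs at odds ``planted_term_odds``
    times the background odds (background rate 10%, large enough that an
    odds-5 planted signal is identifiable in hub sets of a few dozen
    genes); the remaining terms annotate genes uniformly at 2% each.
    """
    hubs = set(hubs)
    if not hubs:
        raise ValueError("empty hub set: nothing to plant enrichment in")
    rng = np.random.default_rng(
        (np.random.default_rng(config.seed).integers(2**31) + 2)
        if seed is None else seed)
    q_bg = 0.10
    odds_hub = config.planted_term_odds * q_bg / (1 - q_bg)
    q_hub = odds_hub / (1 + odds_hub)
    pairs: set[tuple[str, str]] = set()
    for g in sorted(map(str, genes)):
        if rng.random() < (q_hub if g in hubs else q_bg):
            pairs.add((g, "T0000"))
        for t in range(1, config.n_terms):
            if rng.random() < 0.02:
                pairs.add((g, f"T{t:04d}"))
    return AnnotationSet(pairs)


def plant_tf_table(n_tf: int, mi_link_strength: float, seed: int,
                   alpha: float = 1.8):
    """Transcription-factor table (n_mirna_regulators, n_regulated_genes).

    The miRNA in-degree x comes from the zeta sampler; the regulon size y is
    Poisson with log-mean  a + strength * ln(1 + x) + noise, so strength 0
    gives exact independence and larger strengths a monotone link.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    x = sample_zeta_degrees(n_tf, alpha, d_max=500, seed=rng.integers(2**31))
    log_mu = 0.7 + mi_link_strength * np.log1p(x) + rng.normal(0, 0.4, n_tf)
    y = rng.poisson(np.exp(log_mu))
    return pd.DataFrame({
        "tf_id": [f"TF{i + 1:04d}" for i in range(n_tf)],
        "n_mirna_regulators": x.astype(int),
        "n_regulated_genes": y.astype(int),
    })


def plant_utr_table(n_genes: int, utr_rho_pred: float, utr_rho_verified: float,
                    seed: int):
    """Per-gene UTR table with planted correlation structure.

    A Gaussian copula ties (utr3_length, n_pred_A, n_pred_B, n_verified)
    with latent correlations rho_pred between UTR length and each predictor
    count and rho_verified between UTR length and verified interactors;
    marginals are mapped to realistic positive scales (log-normal UTR
    length around 1.2 kb, Poisson counts) by quantile transform.
    """
    import pandas as pd

    if not (-1 < utr_rho_pred < 1 and -1 < utr_rho_verified < 1):
        raise ValueError("planted correlations must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    rp, rv = utr_rho_pred, utr_rho_verified
    corr = np.array([
        [1.0, rp, rp, rv],
        [rp, 1.0, min(0.95, rp * rp + 0.2), rp * rv],
        [rp, min(0.95, rp * rp + 0.2), 1.0, rp * rv],
        [rv, rp * rv, rp * rv, 1.0],
    ])
    # nudge to the nearest PSD matrix if the requested structure is not
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-8:
        corr = (v * np.maximum(w, 1e-8)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(4), corr, size=n_genes,
                                method="cholesky")
    u_cdf = stats.norm.cdf(z)
    utr3 = np.exp(7.0 + 0.5 * z[:, 0]).round(0)          # median ~1.1 kb
    n_pred_a = stats.poisson.ppf(u_cdf[:, 1], mu=50.0)
    n_pred_b = stats.poisson.ppf(u_cdf[:, 2], mu=70.0)
    n_verified = stats.poisson.ppf(u_cdf[:, 3], mu=6.0)
    cds = np.exp(7.6 + 0.4 * rng.normal(size=n_genes)).round(0)
    return pd.DataFrame({
        "gene_id": [f"GENE{i + 1:05d}" for i in range(n_genes)],
        "utr3_length": utr3,
        "transcript_length": utr3 + cds,
        "n_verified": n_verified.astype(int),
        "n_pred_A": n_pred_a.astype(int),
        "n_pred_B": n_pred_b.astype(int),
    })
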