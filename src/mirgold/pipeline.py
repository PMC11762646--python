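"""End-to-end pipeline: ingest -> map -> filter -> dedup -> analyses.

The single entry point :func:`run_pipeline` takes a validated configuration
(YAML-friendly dict), executes the enabled stages, writes every artifact
into the output directory, and returns a machine-readable run report.  All
randomness flows from one top-level seed through fixed per-stage offsets,
so identical configurations produce byte-identical artifacts; wall-clock
timings go to a separate ``timing.json`` so the analytical outputs carry no
timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

from . import abundance, association, curation, enrichment, network, records, synth

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (all derived seeds stay below 2**31)
_STAGE_OFFSET = {"simulate": 0, "mi": 101, "enrich": 202, "utr": 303, "tf": 404}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},            # SynthConfig overrides; remove to use `inputs`
    "inputs": None,            # {mitab, mirtarbase, rnainter, annotation_export, id_mapping}
    "mapping_policy": "keep_unmapped",
    "filter": {"enabled": True},
    "network": {"hub_threshold": 20},
    "fit": {"models": list(abundance.MODELS)},
    "mi": {"bins": 10, "n_boot": 1000, "n_perm": 1000, "n_tf": 300,
           "link_strength": 1.0},
    "enrich": {"alpha": 0.0005, "propagate": False, "significance_by": "p"},
    "overlap": {"top": 3, "mode": "pairwise"},
    "utrcorr": {"n_genes": 500},
}


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 9973 + _STAGE_OFFSET[stage]) % (2**31)


def validate_config(config: dict) -> dict:
    """Merge user config over defaults; reject unknown top-level keys."""
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {}
    for key, default in DEFAULT_CONFIG.items():
        val = config.get(key, default)
        if isinstance(default, dict) and isinstance(val, dict):
            bad = set(val) - set(default) if default else set()
            if key == "simulate":
                bad = set(val) - set(synth.SynthConfig.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
            val = {**default, **val}
        merged[key] = val
    if merged["simulate"] is None and not merged["inputs"]:
        raise ValueError("config needs either a `simulate` section or `inputs`")
    if not isinstance(merged["seed"], int):
        raise ValueError("seed must be an integer")
    return merged


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages and return the run report (also written to
    ``run_report.json``).  Raises on any hard error, with the stage named."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    report: dict = {"config": cfg, "seed": seed, "stages": {}, "files": {}}
    timing: dict[str, float] = {}

    def _stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timing[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    # -- simulate ----------------------------------------------------------
    labels = None
    if cfg["simulate"] is not None:
        with _stage("simulate"):
            sim_kwargs = dict(cfg["simulate"])
            sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
            scfg = synth.SynthConfig(**sim_kwargs)
            net_true, labels = synth.build_true_network(scfg)
            simdir = outdir / "synthetic"
            manifest = synth.emit_records(net_true, labels, scfg, simdir)
            inputs = {k: str(simdir / v) for k, v in manifest["files"].items()}
            report["stages"]["simulate"] = {
                "n_edges_total": len(labels),
                "n_gold": sum(1 for v in labels.values() if v == "gold"),
                "n_records": manifest["n_records"],
            }
    else:
        inputs = dict(cfg["inputs"])

    # -- integrate: ingest, map, filter, dedup -----------------------------
    with _stage("integrate"):
        all_records, n_read, n_rejected = [], 0, 0
        rejected_rows = []
        for dialect in records.SOURCE_DBS:
            if dialect not in inputs or inputs[dialect] is None:
                continue
            res = records.read_interactions(inputs[dialect], dialect)
            n_read += len(res.records) + len(res.rejected)
            n_rejected += len(res.rejected)
            rejected_rows += [(dialect, r.line_no, r.reason) for r in res.rejected]
            all_records += res.records

        mapping = (records.read_id_mapping(inputs["id_mapping"])
                   if inputs.get("id_mapping") else {})
        mapped, map_report = records.map_identifiers(
            all_records, mapping, policy=cfg["mapping_policy"])

        if cfg["filter"]["enabled"]:
            policy_kwargs = {k: (frozenset(v) if isinstance(v, (list, set)) else v)
                             for k, v in cfg["filter"].items() if k != "enabled"}
            policy = curation.FilterPolicy(**policy_kwargs)
            kept, removed = curation.filter_evidence(mapped, policy)
        else:
            kept, removed = list(mapped), []
        removed_by_reason: dict[str, int] = {}
        for _, reason in removed:
            removed_by_reason[reason] = removed_by_reason.get(reason, 0) + 1

        edges = curation.deduplicate(kept)
        edges_path = outdir / "edges.tsv"
        curation.write_edges(edges, edges_path)
        report["files"]["edges"] = edges_path.name
        report["stages"]["integrate"] = {
            "records_read": n_read,
            "rejected": n_rejected,
            "rejected_reasons": sorted({r for _, _, r in rejected_rows}),
            "mapping": asdict(map_report),
            "kept": len(kept),
            "removed": len(removed),
            "removed_by_reason": removed_by_reason,
            "edges": len(edges),
        }

    # -- network -----------------------------------------------------------
    with _stage("network"):
        net = network.build_network(edges)
        hubs = network.find_hubs(net, side="gene",
                                 threshold=cfg["network"]["hub_threshold"])
        for side in ("mirna", "gene"):
            da = network.degree_abundance(net, side)
            p = outdir / f"degree_abundance_{side}.tsv"
            network.write_degree_abundance(da, p)
            report["files"][f"degree_abundance_{side}"] = p.name
        hub_path = outdir / "hubs.tsv"
        network.write_hubs(hubs, hub_path)
        report["files"]["hubs"] = hub_path.name
        report["stages"]["network"] = {
            "n_mirna": len(net.mirna_degree),
            "n_gene": len(net.gene_degree),
            "n_edges": len(net.edges),
            "n_hubs": len(hubs),
            "hub_threshold": cfg["network"]["hub_threshold"],
        }
        if labels is not None:
            gold = {e for e, lab in labels.items() if lab == "gold"}
            tp = len(net.edges & gold)
            report["stages"]["network"]["recovery"] = {
                "precision": tp / len(net.edges) if net.edges else 1.0,
                "recall": tp / len(gold) if gold else 1.0,
            }

    # -- abundance-model fitting ------------------------------------------
    with _stage("fit"):
        fit_out = {}
        for side in ("mirna", "gene"):
            degs = list(net.degrees(side).values())
            try:
                table = abundance.select_model(degs, cfg["fit"]["models"])
            except abundance.FitError as exc:
                fit_out[side] = {"error": str(exc)}
                continue
            fit_out[side] = {
                "best": table.best,
                "fits": table.as_records(),
                "failures": table.failures,
            }
        _dump_json(fit_out, outdir / "model_selection.json")
        report["files"]["model_selection"] = "model_selection.json"
        report["stages"]["fit"] = {s: v.get("best", "unfittable")
                                   for s, v in fit_out.items()}

    # -- mutual information (TF cross-talk) --------------------------------
    with _stage("mi"):
        mi_cfg = cfg["mi"]
        if mi_cfg.get("pairs"):
            import pandas as pd

            tf = pd.read_csv(mi_cfg["pairs"], sep="\t")
        else:
            tf = synth.plant_tf_table(mi_cfg["n_tf"], mi_cfg["link_strength"],
                                      seed=stage_seed(seed, "tf"))
        tf = tf[tf["n_regulated_genes"] > 0]  # TFs regulating zero genes deleted
        tf = tf[tf["n_mirna_regulators"] > 0]
        mi_res = association.resample_mi(
            tf["n_mirna_regulators"].to_numpy(float),
            tf["n_regulated_genes"].to_numpy(float),
            bins_x=mi_cfg["bins"], bins_y=mi_cfg["bins"],
            n_boot=mi_cfg["n_boot"], n_perm=mi_cfg["n_perm"],
            seed=stage_seed(seed, "mi"))
        _dump_json(asdict(mi_res), outdir / "mi_result.json")
        report["files"]["mi_result"] = "mi_result.json"
        report["stages"]["mi"] = {"mi_nats": mi_res.mi_nats, "rmi": mi_res.rmi,
                                  "p_perm": mi_res.p_perm, "n": int(len(tf))}

    # -- enrichment of hub genes ------------------------------------------
    with _stage("enrich"):
        en_cfg = cfg["enrich"]
        universe = sorted(net.gene_degree)
        if hubs:
            if en_cfg.get("annotations"):
                ann = enrichment.AnnotationSet.read(en_cfg["annotations"],
                                                    en_cfg.get("parents"))
            else:
                sim_kwargs = dict(cfg["simulate"] or {})
                sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
                ann = synth.plant_enrichment(universe, hubs,
                                             synth.SynthConfig(**sim_kwargs),
                                             seed=stage_seed(seed, "enrich"))
            rows = enrichment.enrich(hubs, universe, ann,
                                     alpha=en_cfg["alpha"],
                                     propagate=en_cfg["propagate"],
                                     significance_by=en_cfg["significance_by"])
            enrichment.write_enrichment(rows, outdir / "enrichment.tsv")
            report["files"]["enrichment"] = "enrichment.tsv"
            report["stages"]["enrich"] = {
                "n_terms": len(rows),
                "n_significant": sum(r.significant for r in rows),
                "top_term": rows[0].term_id if rows else None,
            }
        else:
            report["stages"]["enrich"] = {"n_terms": 0, "n_significant": 0,
                                          "top_term": None}

    # -- target overlap of the most connected miRNAs -----------------------
    with _stage("overlap"):
        ov_cfg = cfg["overlap"]
        if ov_cfg.get("mirnas"):
            chosen = list(ov_cfg["mirnas"])
        else:
            ranked = sorted(net.mirna_degree,
                            key=lambda m: (-net.mirna_degree[m], m))
            chosen = ranked[: ov_cfg["top"]]
        if len(chosen) >= 2:
            ov = network.target_overlap(net, chosen, mode=ov_cfg["mode"])
            network.write_overlap(ov, outdir / "target_overlap.tsv")
            report["files"]["target_overlap"] = "target_overlap.tsv"
            report["stages"]["overlap"] = {"mirnas": chosen}

    # -- UTR-length correlations ------------------------------------------
    with _stage("utrcorr"):
        utr_cfg = cfg["utrcorr"]
        if utr_cfg.get("table"):
            import pandas as pd

            utr = pd.read_csv(utr_cfg["table"], sep="\t")
        else:
            sim = cfg["simulate"] or {}
            utr = synth.plant_utr_table(
                utr_cfg["n_genes"],
                sim.get("utr_rho_pred", 0.7),
                sim.get("utr_rho_verified", 0.3),
                seed=stage_seed(seed, "utr"))
        ct = association.correlation_table(utr)
        import pandas as pd

        pd.DataFrame(ct.r, index=ct.columns, columns=ct.columns).to_csv(
            outdir / "utr_correlations.tsv", sep="\t",
            float_format="%.6f", index_label="variable")
        report["files"]["utr_correlations"] = "utr_correlations.tsv"
        report["stages"]["utrcorr"] = {
            "r_utr3_n_pred_A": round(ct.cell("utr3_length", "n_pred_A").r, 4),
            "r_utr3_n_pred_B": round(ct.cell("utr3_length", "n_pred_B").r, 4),
            "r_utr3_n_verified": round(ct.cell("utr3_length", "n_verified").r, 4),
            "n": int(ct.cell("utr3_length", "n_pred_A").n),
        }

    _dump_json(report, outdir / "run_report.json")
    _dump_json(timing, outdir / "timing.json")
    return report
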