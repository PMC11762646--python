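#!/usr/bin/env python
"""Fit abundance models to the degree data and compare gene subgroups.

Fits zeta power-law, log-series and geometric models to each side's degree
observations by maximum likelihood and ranks them by AIC.  Then designates
a subset of genes as the transcription-factor catalogue, subtracts it from
the remaining mRNAs, and asks whether the two groups' degree distributions
select the same model.
"""

import argparse
import json
from pathlib import Path

from mirgold import abundance, curation, network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--tf-fraction", type=float, default=0.15,
                    help="fraction of genes designated as the TF catalogue")
    args = ap.parse_args()

    net = network.build_network(curation.read_edges(args.out / "edges.tsv"))
    out = {}
    for side in ("mirna", "gene"):
        table = abundance.select_model(list(net.degrees(side).values()))
        out[side] = {"best": table.best, "fits": table.as_records()}
        best = table.fits[0]
        print(f"{side:>6}: best model {table.best} "
              f"(params {best.params}, AIC {best.aic:.1f}; "
              f"runner-up dAIC {table.fits[1].aic - best.aic:.1f})")

    # TF catalogue: a deterministic slice of the gene universe
    genes = sorted(net.gene_degree)
    n_tf = int(len(genes) * args.tf_fraction)
    tf_set = set(genes[:n_tf])
    tf_deg = [net.gene_degree[g] for g in genes if g in tf_set]
    rest_deg = [net.gene_degree[g] for g in genes if g not in tf_set]
    ta, tb, same = abundance.compare_groups(tf_deg, rest_deg)
    out["tf_vs_rest"] = {"tf_best": ta.best, "rest_best": tb.best,
                         "same_best_model": same,
                         "tf_aic": ta.fits[0].aic, "rest_aic": tb.fits[0].aic}
    print(f"TF subgroup ({len(tf_deg)} genes) best: {ta.best} "
          f"(AIC {ta.fits[0].aic:.1f}); other mRNAs ({len(rest_deg)}): "
          f"{tb.best} (AIC {tb.fits[0].aic:.1f}); same model: {same}")

    (args.out / "model_selection.json").write_text(
        json.dumps(out, indent=1, sort_keys=True) + "\n")
    print(f"wrote {args.out / 'model_selection.json'}")


if __name__ == "__main__":
    main()
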