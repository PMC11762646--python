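#!/usr/bin/env python
"""Build the bipartite network; compute degree classes and hub genes.

Reports the size of the smallest degree class on each side (how many nodes
have exactly one partner), the most connected nodes, and the genes
regulated by more than 20 miRNAs (the network hubs).
"""

import argparse
from pathlib import Path

from mirgold import curation, network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--hub-threshold", type=int, default=20)
    args = ap.parse_args()

    net = network.build_network(curation.read_edges(args.out / "edges.tsv"))
    print(f"network: {len(net.mirna_degree)} miRNAs, "
          f"{len(net.gene_degree)} genes, {len(net.edges)} edges")

    for side in ("mirna", "gene"):
        da = network.degree_abundance(net, side)
        network.write_degree_abundance(da, args.out / f"degree_abundance_{side}.tsv")
        deg = net.degrees(side)
        top = max(deg, key=deg.get)
        frac1 = da.abundance_of(1) / len(deg)
        print(f"{side:>6}: degree class 1 holds {da.abundance_of(1)} nodes "
              f"({frac1:.0%}); max degree {deg[top]} ({top}); "
              f"{sum(1 for d in deg.values() if d > 100)} nodes above degree 100")

    hubs = network.find_hubs(net, "gene", args.hub_threshold)
    network.write_hubs(hubs, args.out / "hubs.tsv")
    print(f"hubs (genes with > {args.hub_threshold} miRNA regulators): "
          f"{len(hubs)} = {len(hubs) / len(net.gene_degree):.1%} of genes")


if __name__ == "__main__":
    main()
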