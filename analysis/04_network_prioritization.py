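#!/usr/bin/env python
"""Disease interactome, DEG overlap, reduction, dual-centrality hubs.

Builds the disease-gene neighborhood of the interaction network,
quantifies its overlap with the DEG list, reduces the network around
the overlapping DEGs, and prioritizes the union of the top-100 nodes
by degree and bottleneck centrality.

Outputs: results/centrality.tsv, results/prioritized_genes.txt
"""

from pathlib import Path

from adiposcan import io as aio
import pandas as pd

from adiposcan.network import (
    PrioritizationParams,
    centrality_table,
    disease_neighborhood,
    overlap_stats,
    prioritize_union,
    reduce_to_overlap_neighborhood,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    net = aio.read_network(COHORT / "network.tsv")
    disease = aio.read_gene_list(COHORT / "disease_genes.txt")
    degs = list(pd.read_csv(RESULTS / "degs.tsv", sep="\t")["gene"].astype(str))

    hood = disease_neighborhood(net, disease)
    print(f"disease interactome: {hood.network.n_nodes} nodes / "
          f"{hood.network.n_edges} edges "
          f"({len(hood.seeds_present)} of {len(disease)} seeds present, "
          f"attrition {hood.attrition})")

    n_overlap, pct = overlap_stats(degs, hood.network)
    print(f"DEG overlap: {n_overlap} of {len(set(degs))} DEGs in the "
          f"interactome ({pct:.1f}%)")

    overlap_genes = sorted(g for g in set(degs) if hood.network.has_node(g))
    reduced = reduce_to_overlap_neighborhood(hood.network, overlap_genes)
    print(f"reduced subnetwork (overlap DEGs + neighbors): "
          f"{reduced.network.n_nodes} nodes / {reduced.network.n_edges} edges")

    pri = prioritize_union(reduced.network, PrioritizationParams(k=100))
    cent = centrality_table(reduced.network)
    cent["in_union"] = cent["node"].isin(set(pri.union))
    cent.to_csv(RESULTS / "centrality.tsv", sep="\t", index=False)
    aio.write_gene_list(pri.union, RESULTS / "prioritized_genes.txt")
    print(f"prioritized hub set: |top100_degree U top100_bottleneck| = "
          f"{len(pri.union)} genes")


if __name__ == "__main__":
    main()
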