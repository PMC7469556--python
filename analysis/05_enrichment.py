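#!/usr/bin/env python
"""Over-representation analysis of the prioritized hub genes.

Scores each gene set against the reference universe with the one-sided
hypergeometric tail, reporting size, expected overlap, enrichment
ratio, p and BH-FDR.  On the synthetic cohort the planted module sets
should dominate the decoys.

Output: results/enrichment.tsv
"""

from pathlib import Path

from adiposcan import io as aio
from adiposcan.enrichment import enrichment_table, ora

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    sets = aio.read_gene_sets(COHORT / "gene_sets.gmt")
    inputs = aio.read_gene_list(RESULTS / "prioritized_genes.txt")
    rows = ora(inputs, sets)
    tab = enrichment_table(rows)
    tab.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    print(f"tested {len(tab)} gene sets against {len(inputs)} input genes")
    show = tab.head(5).copy()
    for c in ("expect", "ratio"):
        show[c] = show[c].round(3)
    print(show.drop(columns="description").to_string(index=False))


if __name__ == "__main__":
    main()
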