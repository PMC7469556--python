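#!/usr/bin/env python
"""Non-specific filtering and moderated-t differential expression.

Filters low-intensity / low-IQR genes, fits the empirical-Bayes
moderated two-sample t, selects DEGs at unadjusted p < 0.05, and
intersects them with the disease gene list, split by direction.

Outputs: results/differential_expression.tsv, results/degs.tsv,
results/disease_degs.tsv
"""

from pathlib import Path

import pandas as pd

from adiposcan import io as aio
from adiposcan.diffexpr import (
    DiffExprParams,
    intersect_disease_genes,
    moderated_t,
    nonspecific_filter,
    select_degs,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    expr = aio.read_expression_matrix(COHORT / "expression.tsv")
    samples = aio.read_sample_table(COHORT / "samples.tsv")
    disease = aio.read_gene_list(COHORT / "disease_genes.txt")

    params = DiffExprParams()
    filtered = nonspecific_filter(expr, params)
    print(f"non-specific filter: {expr.n_genes} -> {filtered.n_genes} genes")

    res = moderated_t(filtered, samples, params)
    d0 = "inf" if res.d0 == float("inf") else f"{res.d0:.1f}"
    print(f"moderated t: prior df d0 = {d0}, prior SD s0 = {res.s0_squared**0.5:.3f}")
    res.table.to_csv(RESULTS / "differential_expression.tsv", sep="\t", index=False)

    degs = select_degs(res, params.alpha)
    degs.to_csv(RESULTS / "degs.tsv", sep="\t", index=False)
    print(f"{len(degs)} DEGs at p < {params.alpha} "
          f"({(degs['direction'] == 'up').sum()} up, "
          f"{(degs['direction'] == 'down').sum()} down)")

    up, down, counts = intersect_disease_genes(degs, disease)
    pd.DataFrame(
        {"gene": up + down, "direction": ["up"] * len(up) + ["down"] * len(down)}
    ).to_csv(RESULTS / "disease_degs.tsv", sep="\t", index=False)
    print(f"disease-gene DEGs: {counts['up']} up, {counts['down']} down "
          f"(of {len(disease)} disease genes)")
    print("  up:  ", ", ".join(up))
    print("  down:", ", ".join(down))


if __name__ == "__main__":
    main()
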