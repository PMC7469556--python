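#!/usr/bin/env python
"""Generate the default synthetic cohort used by the downstream analyses.

Emulates the study conditions: 30 control / 30 case adipose expression
profiles (log2 scale), a 138-gene disease list containing 7 up- and 9
down-regulated planted DEGs and two 30-gene co-expression blocks
coupled to "Cell size" and "LDL", a scale-free interaction network,
and planted per-patient outliers in 25 of 30 cases.

Writes the five input artifacts plus the ground-truth record under
scratch/cohort/ (large, regenerable; not part of the repository).
"""

import argparse
from pathlib import Path

from adiposcan import io as aio
from adiposcan.synthetic import SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    expr, samples, net, sets, truth = simulate_dataset(cfg)
    COHORT.mkdir(parents=True, exist_ok=True)
    aio.write_expression_matrix(expr, COHORT / "expression.tsv")
    aio.write_sample_table(samples, COHORT / "samples.tsv")
    aio.write_network(net, COHORT / "network.tsv")
    aio.write_gene_sets(sets, COHORT / "gene_sets.gmt")
    aio.write_gene_list(truth.disease_genes, COHORT / "disease_genes.txt")
    truth.to_json(COHORT / "truth.json")

    print(f"cohort: {expr.n_genes} genes x {expr.n_samples} samples "
          f"({len(samples.controls)} control / {len(samples.cases)} case)")
    print(f"disease genes: {len(truth.disease_genes)} "
          f"({cfg.n_disease_de_up} planted up-DE, {cfg.n_disease_de_down} down-DE, "
          f"{cfg.n_modules} x {cfg.module_size} module genes)")
    print(f"network: {net.n_nodes} nodes, {net.n_edges} edges")
    print(f"planted outliers: {len(truth.outliers)} cells in "
          f"{len({s for _, s, _ in truth.outliers})} patients")
    print(f"written to {COHORT}")


if __name__ == "__main__":
    main()
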