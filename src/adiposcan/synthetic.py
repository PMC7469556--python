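"""Synthetic case-control adipose cohort generator with a truth record.

Emulates the statistical structure the downstream analysis assumes:

* two groups of configurable size (default 30 controls / 30 cases,
  sex-balanced), log2-scale expression with per-gene Gaussian noise;
* planted differentially expressed genes, half shifted up and half
  down in cases by ``de_effect`` log2 units;
* planted co-expression blocks driven by latent factors, each factor
  coupled to one named intermediate trait;
* a scale-free (preferential-attachment) interaction network in which
  the disease genes are injected as early, high-degree-prone nodes;
* per-patient outlier genes shifted by a multiple of the control SD,
  mimicking the individualization signal;
* gene sets: one set per planted module plus random decoy sets.

The disease gene list contains all planted module genes, a configurable
number of planted DE genes split by direction (defaults mirror the
seven up- / nine down-regulated disease genes the analysis is built
around), and random filler genes.  Every planted feature is recorded in
:class:`SimulationTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    CASE,
    CONTROL,
    STANDARD_TRAITS,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    SampleTable,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 30/30 samples, sex ratio
    1:1, log2 baseline near 8, per-gene noise SD 0.5, DE shift of one
    log2 unit, two 30-gene co-expression blocks with within-block correlation 0.8
    coupled to "Cell size" and "LDL" at 0.6, a 138-gene disease list
    containing 7 up- and 9 down-regulated planted DE genes, and planted
    outliers (+/-3 control SDs) in 25 of the 30 cases.
    """

    n_control: int = 30
    n_case: int = 30
    n_genes: int = 5000
    n_de: int = 200
    de_effect: float = 1.0
    sigma_gene: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 0.8
    n_modules: int = 2
    module_size: int = 30
    # latent-factor loading; 0.8**0.5 gives within-module pairwise correlation 0.8
    module_cor: float = 0.8**0.5
    trait_coupling: float = 0.6
    coupled_traits: tuple[str, ...] = ("Cell size", "LDL")
    n_disease_genes: int = 138
    n_disease_de_up: int = 7
    n_disease_de_down: int = 9
    network_attachment: int = 2
    n_decoy_sets: int = 10
    outlier_spec: list[tuple[str, str, float]] | None = None
    n_outlier_patients: int = 25
    max_outlier_genes_per_patient: int = 4
    outlier_shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_case", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de < 0 or self.n_de > self.n_genes:
            raise ValueError("need 0 <= n_de <= n_genes")
        if not 0.0 < self.module_cor < 1.0:
            raise ValueError("module_cor must be in (0,1)")
        if not 0.0 < self.trait_coupling < 1.0:
            raise ValueError("trait_coupling must be in (0,1)")
        if len(self.coupled_traits) < self.n_modules:
            raise ValueError("need one coupled trait per module")
        n_module_genes = self.n_modules * self.module_size
        if n_module_genes + self.n_de > self.n_genes:
            raise ValueError("module blocks plus DE genes exceed n_genes")
        n_overlap = self.n_disease_de_up + self.n_disease_de_down
        if self.n_disease_de_up > (self.n_de + 1) // 2 or self.n_disease_de_down > self.n_de // 2:
            raise ValueError("disease-gene DE overlap exceeds planted DE counts")
        if self.n_disease_genes < n_module_genes + n_overlap:
            raise ValueError(
                "n_disease_genes must cover the module genes and the DE overlap"
            )
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes exceeds n_genes")
        if self.n_outlier_patients > self.n_case:
            raise ValueError("n_outlier_patients exceeds n_case")


@dataclass
class SimulationTruth:
    """Ground-truth bookkeeping for every planted feature."""

    de_genes: dict[str, float]            # gene -> signed log2 shift in cases
    module_membership: dict[str, int]     # gene -> 1-based module index
    coupled_traits: dict[str, int]        # trait name -> module index
    trait_factors: pd.DataFrame           # samples x modules latent factors
    disease_genes: list[str]
    outliers: list[tuple[str, str, float]]  # (gene, case sample, shift in control SDs)
    config: SimulationConfig

    @property
    def up_genes(self) -> list[str]:
        return sorted(g for g, d in self.de_genes.items() if d > 0)

    @property
    def down_genes(self) -> list[str]:
        return sorted(g for g, d in self.de_genes.items() if d < 0)

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_membership.items() if m == module)

    def to_json(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        cfg["coupled_traits"] = list(self.config.coupled_traits)
        obj = {
            "de_genes": self.de_genes,
            "module_membership": self.module_membership,
            "coupled_traits": self.coupled_traits,
            "trait_factors": {
                c: self.trait_factors[c].tolist() for c in self.trait_factors.columns
            },
            "trait_factor_samples": list(self.trait_factors.index),
            "disease_genes": self.disease_genes,
            "outliers": [list(o) for o in self.outliers],
            "config": cfg,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, InteractionNetwork, GeneSetCollection, SimulationTruth]:
    """Generate one cohort; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    c = config

    genes = [f"G{i:05d}" for i in range(1, c.n_genes + 1)]
    controls = [f"ctrl_{i:02d}" for i in range(1, c.n_control + 1)]
    cases = [f"case_{i:02d}" for i in range(1, c.n_case + 1)]
    samples = controls + cases
    n_samples = len(samples)

    # --- gene role assignment (module blocks disjoint, DE genes disjoint from modules)
    perm = rng.permutation(c.n_genes)
    module_membership: dict[str, int] = {}
    pos = 0
    for b in range(1, c.n_modules + 1):
        for _ in range(c.module_size):
            module_membership[genes[perm[pos]]] = b
            pos += 1
    n_up = (c.n_de + 1) // 2
    de_genes: dict[str, float] = {}
    for j in range(c.n_de):
        g = genes[perm[pos]]
        de_genes[g] = c.de_effect if j < n_up else -c.de_effect
        pos += 1

    # --- background expression on log2 scale
    baseline = rng.normal(c.baseline_mean, c.baseline_sd, size=c.n_genes)
    X = baseline[:, None] + rng.normal(0.0, c.sigma_gene, size=(c.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    case_cols = np.arange(c.n_control, n_samples)

    for g, delta in de_genes.items():
        X[gene_index[g], case_cols] += delta

    # --- planted co-expression blocks: x = mu + sigma*(r*F_b + sqrt(1-r^2)*eps)
    factors = rng.normal(0.0, 1.0, size=(n_samples, c.n_modules))
    r = c.module_cor
    for g, b in module_membership.items():
        i = gene_index[g]
        eps = rng.normal(0.0, 1.0, size=n_samples)
        X[i, :] = baseline[i] + c.sigma_gene * (r * factors[:, b - 1] + np.sqrt(1 - r * r) * eps)

    # --- disease gene list: module genes + DE overlap + random filler
    up_pool = [g for g, d in de_genes.items() if d > 0]
    down_pool = [g for g, d in de_genes.items() if d < 0]
    disease = sorted(module_membership)
    disease += list(rng.choice(up_pool, size=c.n_disease_de_up, replace=False)) if c.n_disease_de_up else []
    disease += list(rng.choice(down_pool, size=c.n_disease_de_down, replace=False)) if c.n_disease_de_down else []
    filler_pool = [g for g in genes if g not in set(disease) and g not in de_genes]
    n_filler = c.n_disease_genes - len(disease)
    disease += list(rng.choice(filler_pool, size=n_filler, replace=False))
    disease_genes = sorted(disease)

    # --- intermediate traits: coupled ones load on the module factors
    coupled = {c.coupled_traits[b - 1]: b for b in range(1, c.n_modules + 1)}
    trait_cols: dict[str, np.ndarray] = {}
    for trait in STANDARD_TRAITS:
        noise = rng.normal(0.0, 1.0, size=n_samples)
        if trait in coupled:
            b = coupled[trait]
            a = c.trait_coupling
            trait_cols[trait] = a * factors[:, b - 1] + np.sqrt(1 - a * a) * noise
        else:
            trait_cols[trait] = noise

    # --- scale-free network; disease genes added first so they attract edges
    nx_seed = int(rng.integers(2**31))
    others = [g for g in genes if g not in set(disease_genes)]
    order = disease_genes + others
    m = min(c.network_attachment, c.n_genes - 1)
    ba = nx.barabasi_albert_graph(c.n_genes, m, seed=nx_seed)
    relabel = {i: order[i] for i in range(c.n_genes)}
    net = InteractionNetwork(nx.relabel_nodes(ba, relabel))

    # --- planted per-patient outliers in control-SD units
    if c.outlier_spec is not None:
        outliers = [(str(g), str(s), float(sh)) for g, s, sh in c.outlier_spec]
    else:
        outliers = []
        k = min(c.n_outlier_patients, c.n_case)
        chosen = sorted(rng.choice(cases, size=k, replace=False))
        pool = [
            g
            for g in disease_genes
            if g not in de_genes and g not in module_membership
        ]
        for s in chosen:
            n_g = int(rng.integers(1, c.max_outlier_genes_per_patient + 1))
            picked = sorted(rng.choice(pool, size=n_g, replace=False))
            for g in picked:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                outliers.append((g, s, sign * c.outlier_shift))
    # outlier cells are PLACED at control_mean + shift*control_SD (sample SD,
    # n-1) so the planted deviation is exact in control-SD units
    ctrl_cols = np.arange(c.n_control)
    mu_c = X[:, ctrl_cols].mean(axis=1)
    sd_c = X[:, ctrl_cols].std(axis=1, ddof=1)
    col_index = {s: j for j, s in enumerate(samples)}
    for g, s, shift in outliers:
        if g not in gene_index or s not in col_index:
            raise ValueError(f"outlier_spec refers to unknown gene/sample ({g}, {s})")
        gi = gene_index[g]
        X[gi, col_index[s]] = mu_c[gi] + shift * sd_c[gi]

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))

    sex = ["M" if i % 2 == 0 else "F" for i in range(c.n_control)] + [
        "M" if i % 2 == 0 else "F" for i in range(c.n_case)
    ]
    sdf = pd.DataFrame(
        {"group": [CONTROL] * c.n_control + [CASE] * c.n_case, "sex": sex},
        index=samples,
    )
    for trait, vals in trait_cols.items():
        sdf[trait] = vals
    sample_table = SampleTable(sdf)

    # --- gene sets: one per planted module + random decoys
    sets: dict[str, list[str]] = {}
    for b in range(1, c.n_modules + 1):
        sets[f"PLANTED_MODULE_{b}"] = sorted(
            g for g, mb in module_membership.items() if mb == b
        )
    for d in range(1, c.n_decoy_sets + 1):
        size = int(rng.integers(max(3, c.module_size // 2), c.module_size * 2))
        sets[f"DECOY_{d:02d}"] = sorted(rng.choice(genes, size=size, replace=False))
    gene_sets = GeneSetCollection.from_lists(
        sets,
        descriptions={k: ("planted co-expression block" if k.startswith("PLANTED") else "random decoy set") for k in sets},
    )

    truth = SimulationTruth(
        de_genes=de_genes,
        module_membership=module_membership,
        coupled_traits=coupled,
        trait_factors=pd.DataFrame(
            factors, index=samples, columns=[f"module_{b}" for b in range(1, c.n_modules + 1)]
        ),
        disease_genes=disease_genes,
        outliers=outliers,
        config=c,
    )
    return expr, sample_table, net, gene_sets, truth
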