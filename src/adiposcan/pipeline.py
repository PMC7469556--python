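"""End-to-end orchestration: simulate/load -> traits -> DE -> network ->
ORA -> co-expression -> individualization, with a machine-readable report.

A run is configured either with input file paths or with a simulation
block (never both).  Stage outputs are written as TSV under the output
directory; the JSON run report collects the headline quantities of
every stage (DEG counts, disease-gene DEG split, interactome overlap,
reduced-subnetwork size, prioritized hub set, top enrichment rows,
modules and module-trait correlations per group, and the per-patient
individualization summary).  Identical config and seed give a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as aio
from .coexpression import CoexpressionParams, run_coexpression
from .datamodel import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    SampleTable,
)
from .diffexpr import (
    DiffExprParams,
    intersect_disease_genes,
    moderated_t,
    nonspecific_filter,
    select_degs,
)
from .enrichment import enrichment_table, ora
from .individualize import (
    IndividualizationParams,
    control_envelope,
    flag_patient_genes,
    frequency_summary,
)
from .network import (
    PrioritizationParams,
    centrality_table,
    disease_neighborhood,
    overlap_stats,
    prioritize_union,
    reduce_to_overlap_neighborhood,
)
from .synthetic import SimulationConfig, simulate_dataset
from .traits import trait_table

log = logging.getLogger(__name__)

REPORT_VERSION = 1
ALL_STAGES = ("traits", "dge", "network", "ora", "wgcna", "individualize")


@dataclass
class RunConfig:
    """One pipeline run: data source, stage parameters, output location."""

    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None  # expression, samples, disease_genes, network, gene_sets
    stages: tuple[str, ...] = ALL_STAGES
    diffexpr: DiffExprParams = field(default_factory=DiffExprParams)
    prioritization: PrioritizationParams = field(default_factory=PrioritizationParams)
    coexpression: CoexpressionParams = field(default_factory=CoexpressionParams)
    individualization: IndividualizationParams = field(default_factory=IndividualizationParams)
    min_confidence: float = 0.0
    log2_transform: bool = False
    force: bool = False

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' or 'inputs' must be given")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if self.simulation is not None:
            self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {
            "outdir": raw["outdir"],
            "seed": int(raw.get("seed", 0)),
            "min_confidence": float(raw.get("min_confidence", 0.0)),
            "log2_transform": bool(raw.get("log2_transform", False)),
            "force": bool(raw.get("force", False)),
        }
        if "stages" in raw:
            stages = raw["stages"]
            if isinstance(stages, str):
                stages = [s.strip() for s in stages.split(",") if s.strip()]
            kwargs["stages"] = tuple(stages)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "coupled_traits" in sim:
                sim["coupled_traits"] = tuple(sim["coupled_traits"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "inputs" in raw and raw["inputs"] is not None:
            kwargs["inputs"] = dict(raw["inputs"])
        for key, cls_ in (
            ("diffexpr", DiffExprParams),
            ("prioritization", PrioritizationParams),
            ("coexpression", CoexpressionParams),
            ("individualization", IndividualizationParams),
        ):
            if key in raw and raw[key] is not None:
                kwargs[key] = cls_(**raw[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of everything that affects the computed results.

        The output directory and the force flag do not change results
        and are excluded.
        """
        d = asdict(self)
        d.pop("force", None)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(
    cfg: RunConfig,
) -> tuple[ExpressionMatrix, SampleTable, InteractionNetwork, GeneSetCollection, list[str], Any]:
    if cfg.simulation is not None:
        expr, samples, net, sets, truth = simulate_dataset(cfg.simulation)
        return expr, samples, net, sets, truth.disease_genes, truth
    paths = cfg.inputs or {}
    required = ("expression", "samples", "disease_genes", "network", "gene_sets")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"missing input path(s): {missing}")
    expr = aio.read_expression_matrix(paths["expression"], log2_transform=cfg.log2_transform)
    samples = aio.read_sample_table(paths["samples"])
    net = aio.read_network(paths["network"], min_confidence=cfg.min_confidence)
    sets = aio.read_gene_sets(paths["gene_sets"])
    disease = aio.read_gene_list(paths["disease_genes"])
    return expr, samples, net, sets, disease, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run report.

    Stages not listed in ``cfg.stages`` still execute in memory when a
    selected downstream stage depends on them, but their outputs and
    report sections are omitted.  An unchanged config hash with an
    existing report skips the run unless ``force``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "run_report.json"
    chash = cfg.config_hash()
    if report_path.exists() and not cfg.force:
        try:
            prev = json.loads(report_path.read_text())
        except json.JSONDecodeError:
            prev = None
        if prev and prev.get("config_hash") == chash:
            log.info("config unchanged (%s); reusing existing report", chash)
            return prev

    expr, samples, net, sets, disease_genes, truth = _load_inputs(cfg)
    selected = set(cfg.stages)
    report: dict[str, Any] = {
        "report_version": REPORT_VERSION,
        "config_hash": chash,
        "seed": cfg.seed,
        "stages": sorted(selected),
        "n_genes_input": expr.n_genes,
        "n_samples": expr.n_samples,
        "n_controls": len(samples.controls),
        "n_cases": len(samples.cases),
        "n_disease_genes": len(disease_genes),
    }
    if cfg.simulation is not None and truth is not None:
        truth.to_json(outdir / "simulation_truth.json")
        aio.write_expression_matrix(expr, outdir / "expression.tsv")
        aio.write_sample_table(samples, outdir / "samples.tsv")
        aio.write_network(net, outdir / "network.tsv")
        aio.write_gene_sets(sets, outdir / "gene_sets.gmt")
        aio.write_gene_list(disease_genes, outdir / "disease_genes.txt")

    if "traits" in selected:
        ttab = trait_table(samples, stratify_by_sex="sex" in samples.data.columns)
        ttab.to_csv(outdir / "trait_comparison.tsv", sep="\t", index=False)
        sig = ttab[ttab["p"] < 0.05]
        report["traits"] = {
            "n_traits": int(ttab["trait"].nunique()),
            "n_significant_rows": int(len(sig)),
        }

    need_dge = bool({"dge", "network", "ora", "individualize"} & selected)
    degs = None
    de_res = None
    if need_dge:
        filtered = nonspecific_filter(expr, cfg.diffexpr)
        de_res = moderated_t(filtered, samples, cfg.diffexpr)
        degs = select_degs(de_res, cfg.diffexpr.alpha)
        up, down, counts = intersect_disease_genes(degs, disease_genes)
        if "dge" in selected:
            de_res.table.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
            degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
            report["dge"] = {
                "n_genes_after_filter": filtered.n_genes,
                "n_degs": int(len(degs)),
                "d0": de_res.d0,
                "s0_squared": de_res.s0_squared,
                "disease_deg_up": up,
                "disease_deg_down": down,
                "disease_deg_counts": counts,
            }

    prioritized = None
    if {"network", "ora"} & selected:
        hood = disease_neighborhood(net, disease_genes)
        deg_list = list(degs["gene"]) if degs is not None else []
        n_overlap, pct = overlap_stats(deg_list, hood.network)
        overlap_genes = sorted(g for g in set(deg_list) if hood.network.has_node(g))
        if overlap_genes:
            reduced = reduce_to_overlap_neighborhood(hood.network, overlap_genes)
            prioritized = prioritize_union(reduced.network, cfg.prioritization)
        if "network" in selected:
            aio.write_network(hood.network, outdir / "disease_interactome.tsv")
            net_report = {
                "seed_attrition": hood.attrition,
                "n_seeds_in_network": len(hood.seeds_present),
                "interactome_nodes": hood.network.n_nodes,
                "interactome_edges": hood.network.n_edges,
                "deg_overlap_count": n_overlap,
                "deg_overlap_pct": pct,
            }
            if prioritized is not None:
                aio.write_network(reduced.network, outdir / "reduced_subnetwork.tsv")
                cent = centrality_table(reduced.network)
                cent["in_union"] = cent["node"].isin(set(prioritized.union))
                cent.to_csv(outdir / "centrality.tsv", sep="\t", index=False)
                net_report.update(
                    reduced_subnetwork_nodes=reduced.network.n_nodes,
                    reduced_subnetwork_edges=reduced.network.n_edges,
                    prioritized_set_size=len(prioritized.union),
                )
            report["network"] = net_report

    if "ora" in selected:
        input_genes = prioritized.union if prioritized is not None else sorted(disease_genes)
        try:
            rows = ora(input_genes, sets)
        except ValueError as err:
            log.warning("ORA skipped: %s", err)
            rows = []
        tab = enrichment_table(rows)
        tab.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["ora"] = {
            "n_sets_tested": int(len(tab)),
            "input_size": len(input_genes),
            "top_rows": [
                {k: r[k] for k in ("name", "size", "overlap", "expect", "ratio", "p", "fdr")}
                for r in tab.head(10).to_dict("records")
            ],
        }

    if "wgcna" in selected:
        wg_report = {}
        frames_assign, frames_me, frames_mt = [], [], []
        genes_present = [g for g in expr.gene_ids if g in set(disease_genes)]
        for group, ids in ((CONTROL, samples.controls), (CASE, samples.cases)):
            res = run_coexpression(expr, samples, genes_present, cfg.coexpression, sample_ids=ids)
            a = res.assignment.rename("module").to_frame()
            a.insert(0, "gene", a.index)
            a["group"] = group
            frames_assign.append(a.reset_index(drop=True))
            me = res.eigengenes.copy()
            me.insert(0, "sample_id", me.index)
            me["group"] = group
            frames_me.append(me.reset_index(drop=True))
            mt = res.module_trait.copy()
            mt["group"] = group
            frames_mt.append(mt)
            non_grey = sorted(set(res.assignment) - {"grey"})
            sig = res.module_trait[(res.module_trait["p"] < 0.05)]
            wg_report[group] = {
                "modules": non_grey + (["grey"] if "grey" in set(res.assignment) else []),
                "n_genes": int(len(res.assignment)),
                "scale_free_r2": res.scale_free["r_squared"],
                "significant_module_traits": [
                    {k: r[k] for k in ("module", "trait", "r", "p")}
                    for r in sig.sort_values(["p", "module", "trait"]).to_dict("records")
                ],
            }
        pd.concat(frames_assign).to_csv(outdir / "module_assignment.tsv", sep="\t", index=False)
        pd.concat(frames_me).to_csv(outdir / "module_eigengenes.tsv", sep="\t", index=False)
        pd.concat(frames_mt).to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        report["wgcna"] = wg_report

    if "individualize" in selected:
        env = control_envelope(expr, samples, disease_genes, cfg.individualization.min_control_sd)
        flags = flag_patient_genes(expr, samples, env, cfg.individualization)
        freq, with_any = frequency_summary(flags)
        flags.to_frame().to_csv(outdir / "patient_flags.tsv", sep="\t", index=False)
        freq.to_csv(outdir / "gene_flag_frequency.tsv", sep="\t", index=False)
        report["individualize"] = {
            "mode": cfg.individualization.mode,
            "threshold": cfg.individualization.threshold,
            "patients_with_any": with_any,
            "n_cases": len(samples.cases),
            "n_flagged_genes": int(len(freq)),
            "top_genes": freq.head(10).to_dict("records"),
        }

    aio.write_json(report, report_path)
    return report
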