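"""Core domain containers shared by every stage of the pipeline.

The pipeline operates on four kinds of objects: a log2 expression matrix
(genes x samples), a sample annotation table (group, sex, intermediate
traits), gene-set collections (including the disease gene list as a
single-set collection), and an undirected protein-interaction network.
Each container validates its invariants at construction so that
downstream stages can assume clean inputs.

Expression values are log2-scale by contract throughout the package;
ingest offers an optional log2(x+1) transform for raw-scale files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

#: group label aliases accepted at ingest (study labels NGT / T2D included)
GROUP_ALIASES: Mapping[str, str] = {
    "control": CONTROL,
    "ngt": CONTROL,
    "normal": CONTROL,
    "case": CASE,
    "t2d": CASE,
    "diabetic": CASE,
}

#: the 16 intermediate traits measured alongside the expression profiles
STANDARD_TRAITS: tuple[str, ...] = (
    "Cell size",
    "HOMA-IR",
    "HOMA-B",
    "HbA1c",
    "Triglycerides",
    "Cholesterol",
    "NEFA",
    "VLDL",
    "LDL",
    "HDL",
    "Leptin",
    "Adiponectin",
    "TNF-alpha",
    "hsCRP",
    "Serum creatinine",
    "Insulin",
)


class DataModelError(ValueError):
    """Raised when a domain invariant is violated."""


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            raise DataModelError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities, genes in rows and samples in columns.

    Wraps a pandas DataFrame indexed by gene symbol with sample
    identifiers as columns.  All values must be finite; identifiers
    must be unique; at least one gene and two samples are required.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise DataModelError(
                f"expression matrix needs >=1 gene and >=2 samples, got {df.shape}"
            )
        _check_unique(list(df.index), "gene ID")
        _check_unique(list(df.columns), "sample ID")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataModelError(
                f"non-finite expression value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.data = df.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.data.loc[keep])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleTable:
    """Per-sample annotations: group, sex, and numeric trait values.

    ``data`` is indexed by sample identifier with a ``group`` column
    (values ``control``/``case``), an optional ``sex`` column
    (``M``/``F``), and one numeric column per trait.  Trait values may
    be missing (NaN) but must be finite where present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "sample ID")
        if "group" not in df.columns:
            raise DataModelError("sample table requires a 'group' column")
        groups = df["group"].astype(str).str.strip().str.lower()
        unknown = sorted(set(groups) - set(GROUP_ALIASES))
        if unknown:
            raise DataModelError(f"unknown group labels: {unknown}")
        df = df.copy()
        df["group"] = groups.map(GROUP_ALIASES)
        if "sex" in df.columns:
            sex = df["sex"].astype(str).str.strip().str.upper()
            bad = sorted(set(sex) - {"M", "F"})
            if bad:
                raise DataModelError(f"unknown sex labels: {bad}")
            df["sex"] = sex
        for col in self.trait_names_from(df):
            vals = pd.to_numeric(df[col], errors="coerce")
            inf = np.isinf(vals.to_numpy(dtype=float))
            if inf.any():
                raise DataModelError(f"non-finite trait value in {col!r}")
            df[col] = vals
        df.index = df.index.astype(str)
        self.data = df

    @staticmethod
    def trait_names_from(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in ("group", "sex")]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return self.trait_names_from(self.data)

    def group_samples(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])

    @property
    def controls(self) -> list[str]:
        return self.group_samples(CONTROL)

    @property
    def cases(self) -> list[str]:
        return self.group_samples(CASE)

    def traits(self, sample_id: str) -> dict[str, float]:
        return self.data.loc[sample_id, self.trait_names].to_dict()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataModelError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"member of gene set {self.name!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit reference universe."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    reference: tuple[str, ...] | None = None

    @classmethod
    def from_lists(
        cls,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
        reference: Sequence[str] | None = None,
    ) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "")
            deduped = tuple(dict.fromkeys(str(m) for m in members))
            out[name] = GeneSet(name, desc, deduped)
        return cls(out, tuple(reference) if reference is not None else None)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name].genes

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out.update(s.genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass
class InteractionNetwork:
    """Undirected simple protein-interaction graph over gene symbols.

    No self-loops, no parallel edges; optional per-edge confidence
    score in [0, 1] stored as the ``confidence`` edge attribute.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise DataModelError(f"self-loops not allowed: {loops[:3]}")
        for u, v, d in g.edges(data=True):
            c = d.get("confidence")
            if c is not None and not (0.0 <= c <= 1.0):
                raise DataModelError(f"confidence out of [0,1] on edge ({u},{v}): {c}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] | None = None,
    ) -> "InteractionNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(str(n) for n in nodes)
        for e in edges:
            u, v = str(e[0]), str(e[1])
            if u == v:
                continue
            if len(e) > 2 and e[2] is not None:
                g.add_edge(u, v, confidence=float(e[2]))
            else:
                g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def neighbors(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node))

    def induced(self, nodes: Iterable[str]) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.subgraph(set(nodes)).copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and {frozenset(e) for e in self.graph.edges}
            == {frozenset(e) for e in other.graph.edges}
        )
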