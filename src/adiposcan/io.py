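"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: TSV expression matrix (first column gene ID, header row of
sample IDs), TSV sample annotation table, GMT gene-set collections,
SIF or 2-3 column TSV edge lists, one-symbol-per-line gene lists, and
JSON run summaries.  All readers enforce the domain invariants of
:mod:`adiposcan.datamodel` and fail loudly with file coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DataModelError,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    SampleTable,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file."""


def read_expression_matrix(
    path: str | Path, log2_transform: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples TSV of log2 intensities.

    ``log2_transform`` applies log2(x+1) for raw-scale inputs; the
    in-memory contract is always log2 scale.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.index.name = None
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate gene ID {dup[0]!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[int(np.argmax(vals.isna().to_numpy()))]
            raise ParseError(
                f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
            )
        out[col] = vals
    if log2_transform:
        if (out.to_numpy() < 0).any():
            raise ParseError(f"{path}: negative values cannot be log2(x+1) transformed")
        out = np.log2(out + 1.0)
    return ExpressionMatrix(out)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.index.name = None
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if not sym or sym.startswith("#"):
            continue
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        name, desc = fields[0].strip(), fields[1].strip()
        members = [f.strip() for f in fields[2:] if f.strip()]
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = list(dict.fromkeys(members))
        descriptions[name] = desc
    return GeneSetCollection.from_lists(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_network(path: str | Path, min_confidence: float = 0.0) -> InteractionNetwork:
    """Read an edge list: ``nodeA TAB nodeB [TAB score]`` or 3-column SIF.

    SIF lines (``nodeA interaction nodeB``) are detected by a
    non-numeric middle field.  Edges scoring below ``min_confidence``
    are dropped; self-loops are dropped with a logged count.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0,1], got {min_confidence}")
    edges: list[tuple[str, str, float | None]] = []
    n_selfloops = 0
    n_below = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if len(fields) == 2:
            u, v, score = fields[0], fields[1], None
        elif len(fields) == 3:
            try:
                score = float(fields[2])
                u, v = fields[0], fields[1]
            except ValueError:
                # SIF: source  interaction-type  target
                u, v, score = fields[0], fields[2], None
        else:
            raise ParseError(f"{path}:{lineno}: expected 2-3 fields, got {len(fields)}")
        if not u or not v:
            raise ParseError(f"{path}:{lineno}: empty node identifier")
        if score is not None and not np.isfinite(score):
            raise ParseError(f"{path}:{lineno}: non-finite edge score")
        if u == v:
            n_selfloops += 1
            continue
        if score is not None and score < min_confidence:
            n_below += 1
            continue
        if score is not None:
            score = min(max(score, 0.0), 1.0)
        edges.append((u, v, score))
    if n_selfloops:
        log.info("dropped %d self-loop edge(s) from %s", n_selfloops, path)
    if n_below:
        log.info("dropped %d edge(s) below confidence %.3g", n_below, min_confidence)
    return InteractionNetwork.from_edges(edges)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write a TSV edge list (nodeA, nodeB[, confidence]), sorted for determinism."""
    rows = []
    for u, v, d in net.graph.edges(data=True):
        a, b = sorted((u, v))
        c = d.get("confidence")
        rows.append((a, b, c))
    rows.sort()
    with open(path, "w") as fh:
        for a, b, c in rows:
            if c is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{c:g}\n")
    if net.n_nodes and not rows:
        # preserve isolated-node-only graphs as a node list comment
        with open(path, "a") as fh:
            for n in net.nodes:
                fh.write(f"# node\t{n}\n")


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic strict JSON: sorted keys, non-finite floats -> null."""
    Path(path).write_text(
        json.dumps(_definite(obj), indent=2, sort_keys=True, default=_jsonable, allow_nan=False)
        + "\n"
    )


def _definite(x):
    if isinstance(x, dict):
        return {k: _definite(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_definite(v) for v in x]
    if isinstance(x, (float, np.floating)) and not np.isfinite(x):
        return None
    return x


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x) if isinstance(x, (set, frozenset)) else list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
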