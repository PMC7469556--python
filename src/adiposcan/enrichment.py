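"""Hypergeometric over-representation analysis (ORA).

For an input gene list and a gene-set collection, each set is scored
against a reference universe with the one-sided hypergeometric tail:
with N reference genes, K of them in the set and n input genes in the
reference, the overlap k is tested via P(X >= k), X ~ Hypergeom(N, K, n).
Reported per set: size K, expect = n*K/N, enrichment ratio k/expect,
p, and Benjamini-Hochberg FDR across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSetCollection

log = logging.getLogger(__name__)

#: minimum in-reference set size; smaller sets give degenerate expect values
MIN_SET_SIZE = 3


@dataclass(frozen=True)
class EnrichmentRow:
    name: str
    description: str
    size: int       # K: set members in the reference
    overlap: int    # k
    expect: float   # n*K/N
    ratio: float    # k / expect
    p: float
    fdr: float


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    input_genes: Iterable[str],
    sets: GeneSetCollection,
    reference: Iterable[str] | None = None,
) -> list[EnrichmentRow]:
    """One-sided over-representation analysis of ``input_genes``.

    ``reference`` defaults to the collection's own universe (its
    explicit reference if set, otherwise the union of all members).
    Input genes outside the reference are dropped with a logged count;
    sets with fewer than ``MIN_SET_SIZE`` members in the reference are
    skipped.  Rows are sorted by p ascending, then name.
    """
    if reference is None:
        reference = sets.reference if sets.reference is not None else sets.all_members()
    universe = set(reference)
    if not universe:
        raise ValueError("reference universe is empty")
    N = len(universe)

    inputs = set(input_genes)
    in_ref = inputs & universe
    dropped = len(inputs) - len(in_ref)
    if dropped:
        log.info("ORA: dropped %d input gene(s) outside the reference", dropped)
    if not in_ref:
        raise ValueError("no input genes in the reference universe")
    n = len(in_ref)

    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for gs in sets:
        members = set(gs.genes) & universe
        K = len(members)
        if K < MIN_SET_SIZE:
            log.info("ORA: skipped set %r (K=%d < %d in reference)", gs.name, K, MIN_SET_SIZE)
            continue
        k = len(members & in_ref)
        expect = n * K / N
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentRow(
                name=gs.name,
                description=gs.description,
                size=K,
                overlap=k,
                expect=expect,
                ratio=k / expect,
                p=min(p, 1.0),
                fdr=np.nan,
            )
        )
        pvals.append(min(p, 1.0))

    if not rows:
        return []
    q = bh_fdr(pvals)
    rows = [
        EnrichmentRow(r.name, r.description, r.size, r.overlap, r.expect, r.ratio, r.p, float(qv))
        for r, qv in zip(rows, q)
    ]
    rows.sort(key=lambda r: (r.p, r.name))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view with the conventional ORA column order."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "description": r.description,
                "size": r.size,
                "overlap": r.overlap,
                "expect": r.expect,
                "ratio": r.ratio,
                "p": r.p,
                "fdr": r.fdr,
            }
            for r in rows
        ]
    )
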