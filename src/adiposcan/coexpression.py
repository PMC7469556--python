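"""Weighted co-expression analysis of the disease-gene submatrix.

Follows the weighted gene co-expression network analysis (WGCNA)
recipe, run separately per group on the disease-gene expression
submatrix:

1. unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta
   (default beta = 15, chosen to approximate scale-free topology);
2. topological overlap similarity
   TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
   l_ij = sum_u a_iu * a_uj, TOM_ii = 1;
3. average-linkage hierarchical clustering of the dissimilarity
   1 - TOM, cut at a fixed height; clusters below the minimum size are
   left unassigned ("grey");
4. module eigengenes: first principal component of each module's
   standardized expression, sign-oriented to the module mean profile;
5. Pearson eigengene-trait correlations with Student-t p-values.

Modules are labeled with the conventional color sequence by
descending size (largest = turquoise).  A static height cut replaces
the dynamic tree cut algorithm; on cleanly separated blocks the two
agree, and the simplification keeps the procedure deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datamodel import ExpressionMatrix, SampleTable

log = logging.getLogger(__name__)

#: conventional module color order; index 0 = largest module
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
)
GREY = "grey"


@dataclass
class CoexpressionParams:
    """Parameters of the co-expression pipeline.

    ``beta`` = 15 follows the scale-free-topology choice of the
    analysis this package implements.  ``cut_height`` applies to the
    1 - TOM dissimilarity: raising correlations to the 15th power
    compresses TOM toward zero, so genuine clusters sit just below
    dissimilarity 1 and a static cut must be placed close to 1
    (dynamic tree cutting adapts to this automatically; a fixed cut
    needs 0.995).
    """

    beta: float = 15.0         # soft-threshold power
    cut_height: float = 0.995  # dendrogram cut on 1 - TOM dissimilarity
    min_module_size: int = 10

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must be in (0,1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def soft_adjacency(X: ExpressionMatrix, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal.

    Genes with zero variance across samples are excluded with a
    warning (correlation undefined).
    """
    if X.n_samples < 3:
        raise ValueError("soft adjacency needs >= 3 samples")
    vals = X.values()
    sd = vals.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(X.gene_ids, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s) from adjacency",
            RuntimeWarning,
            stacklevel=2,
        )
    genes = [g for g, k in zip(X.gene_ids, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with positive variance")
    cor = np.corrcoef(vals[keep])
    cor = np.clip(cor, -1.0, 1.0)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> dict:
    """R^2 of the log-log connectivity-distribution regression.

    Connectivity k_i = sum_j a_ij is binned (equal width); the log10
    bin frequency is regressed on the log10 mean connectivity per bin.
    Returns {"r_squared", "slope", "defined"}; degenerate inputs (all
    connectivities equal, or fewer than 3 occupied bins) are flagged
    undefined.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] < 10:
        raise ValueError("scale-free fit needs >= 10 genes")
    k = a.sum(axis=1)
    if np.ptp(k) == 0:
        return {"r_squared": float("nan"), "slope": float("nan"), "defined": False}
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return {"r_squared": float("nan"), "slope": float("nan"), "defined": False}
    fit = stats.linregress(xs, ys)
    return {"r_squared": float(fit.rvalue**2), "slope": float(fit.slope), "defined": True}


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix; symmetric, entries in [0,1], unit diagonal."""
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1)
    l = a @ a  # a_ii = 0, so terms u = i or u = j vanish automatically
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, params: CoexpressionParams) -> pd.Series:
    """Color label per gene from average-linkage clustering of 1 - TOM.

    Flat clusters are extracted at ``cut_height``; clusters smaller
    than ``min_module_size`` become grey.  Colors are assigned by
    descending module size (ties broken by first gene index) starting
    at turquoise.
    """
    genes = list(tom.index)
    if len(genes) < params.min_module_size:
        raise ValueError("fewer genes than min_module_size")
    d = 1.0 - tom.to_numpy(dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=params.cut_height, criterion="distance")

    sizes: dict[int, int] = {}
    first_idx: dict[int, int] = {}
    for i, lab in enumerate(labels):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_idx.setdefault(lab, i)
    kept = [lab for lab, n in sizes.items() if n >= params.min_module_size]
    kept.sort(key=lambda lab: (-sizes[lab], first_idx[lab]))
    color_of = {
        lab: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, lab in enumerate(kept)
    }
    colors = [color_of.get(lab, GREY) for lab in labels]
    return pd.Series(colors, index=genes, name="module")


def module_eigengenes(X: ExpressionMatrix, assignment: pd.Series) -> pd.DataFrame:
    """Samples x modules eigengene matrix (grey included).

    Each gene is standardized across samples; the eigengene is the
    first right-singular vector of the module's standardized matrix,
    scaled to unit sample variance and sign-oriented to correlate
    positively with the module's mean standardized profile.
    """
    vals = X.values()
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        sd = np.where(sd == 0, 1.0, sd)
    zmat = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    gene_idx = {g: i for i, g in enumerate(X.gene_ids)}

    out = {}
    for color in _ordered_colors(assignment):
        members = [g for g in assignment.index if assignment[g] == color]
        rows = [gene_idx[g] for g in members if g in gene_idx]
        if not rows:
            continue
        sub = zmat[rows, :]  # genes x samples
        if len(rows) == 1:
            warnings.warn(
                f"module {color!r} has a single gene; eigengene = that gene",
                RuntimeWarning,
                stacklevel=2,
            )
            me = sub[0]
        else:
            # first PC over samples
            u, s, vt = np.linalg.svd(sub - sub.mean(axis=1, keepdims=True), full_matrices=False)
            me = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.dot(me, mean_profile - mean_profile.mean()) < 0:
            me = -me
        me_sd = me.std(ddof=1)
        if me_sd > 0:
            me = (me - me.mean()) / me_sd
        out[color] = me
    return pd.DataFrame(out, index=X.sample_ids)


def _ordered_colors(assignment: pd.Series) -> list[str]:
    present = list(dict.fromkeys(assignment))
    rank = {c: i for i, c in enumerate(MODULE_COLORS)}
    return sorted(present, key=lambda c: (c == GREY, rank.get(c, len(rank)), c))


def module_trait_relationships(
    eigengenes: pd.DataFrame, samples: SampleTable
) -> pd.DataFrame:
    """Pearson r and p for every (module eigengene, trait) pair.

    Missing trait values are handled pairwise-complete; the p-value
    uses the per-pair n in the Student-t degrees of freedom.  Constant
    traits (or fewer than 4 complete pairs) yield NaN.
    """
    rows = []
    traits = samples.data.loc[eigengenes.index, samples.trait_names]
    for color in eigengenes.columns:
        me = eigengenes[color].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            ok = ~np.isnan(tv) & ~np.isnan(me)
            n = int(ok.sum())
            if n < 4 or np.std(tv[ok]) == 0 or np.std(me[ok]) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(me[ok], tv[ok])
            rows.append({"module": color, "trait": trait, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


@dataclass
class CoexpressionResult:
    assignment: pd.Series
    eigengenes: pd.DataFrame
    module_trait: pd.DataFrame
    scale_free: dict


def run_coexpression(
    X: ExpressionMatrix,
    samples: SampleTable,
    genes: list[str],
    params: CoexpressionParams,
    sample_ids: list[str] | None = None,
) -> CoexpressionResult:
    """Full per-group pipeline on the given gene subset (e.g. disease genes)."""
    sub = X.subset_genes(genes)
    if sample_ids is not None:
        sub = sub.subset_samples(sample_ids)
    adj = soft_adjacency(sub, params.beta)
    sfree = scale_free_fit(adj) if adj.shape[0] >= 10 else {"r_squared": float("nan"), "slope": float("nan"), "defined": False}
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, params)
    me = module_eigengenes(sub.subset_genes(list(assignment.index)), assignment)
    mt = module_trait_relationships(me, samples)
    return CoexpressionResult(assignment, me, mt, sfree)
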