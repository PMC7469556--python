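"""Non-specific filtering and moderated-t differential expression.

The case-control comparison uses an empirical-Bayes moderated
two-sample t-statistic: per-gene pooled variances s_g^2 (d_g residual
df) are shrunk toward a global prior variance s0^2 with prior df d0,

    s_post^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
    t~_g     = (mean_case - mean_ctrl) / (s_post * sqrt(1/n1 + 1/n2))

with p-values from a Student t on d0 + d_g degrees of freedom.  The
hyperparameters (d0, s0^2) are estimated by closed-form moment
matching on log s_g^2: since d_g*s_g^2/sigma_g^2 is chi-squared, the
mean and variance of log s_g^2 identify a scaled F distribution whose
second parameter is recovered by Newton inversion of the trigamma
function.  With d0 -> 0 the statistic reduces to the ordinary t; with
d0 -> infinity every gene uses s0.

Before testing, a non-specific filter removes probes with low
intensity or negligible variation (interquartile range), the standard
pre-filtering applied to microarray matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special

from .datamodel import CASE, CONTROL, ExpressionMatrix, SampleTable
from .enrichment import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class DiffExprParams:
    """Filtering and testing parameters.

    Filter defaults follow common microarray practice: keep genes with
    log2 intensity above 6 in at least a quarter of samples and an
    interquartile range of at least 0.5.  ``alpha`` is the unadjusted
    DEG p-value threshold; BH-FDR q-values are reported alongside.
    """

    filter_min_intensity: float = 6.0
    filter_min_fraction: float = 0.25
    filter_min_iqr: float = 0.5
    alpha: float = 0.05
    use_moderation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 <= self.filter_min_fraction <= 1.0:
            raise ValueError("filter_min_fraction must be in [0,1]")


@dataclass
class DEResult:
    """Per-gene differential expression table plus global hyperparameters.

    ``table`` columns: gene, logFC (case - control), s (ordinary
    residual SD), s_post, t, df, p, q, direction.
    """

    table: pd.DataFrame
    d0: float
    s0_squared: float


def nonspecific_filter(X: ExpressionMatrix, params: DiffExprParams) -> ExpressionMatrix:
    """Drop genes failing the intensity or the IQR criterion."""
    vals = X.values()
    frac_above = (vals > params.filter_min_intensity).mean(axis=1)
    iqr = stats.iqr(vals, axis=1)
    keep = (frac_above >= params.filter_min_fraction) & (iqr >= params.filter_min_iqr)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("non-specific filter removed every gene")
    log.info(
        "non-specific filter: kept %d / %d genes (removed %d)",
        int(keep.sum()), X.n_genes, n_removed,
    )
    return ExpressionMatrix(X.data.loc[keep])


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma target must be positive")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from pooled variances with ``df`` residual df.

    Works on e_g = log(s_g^2) - digamma(df/2) + log(df/2); the excess
    variance of e over trigamma(df/2) identifies trigamma(d0/2).
    Returns (inf, geometric mean variance) when there is no excess
    variance (all s_g effectively equal).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def moderated_t(
    X: ExpressionMatrix, samples: SampleTable, params: DiffExprParams
) -> DEResult:
    """Empirical-Bayes moderated (or ordinary) two-sample t per gene."""
    ctrl = [s for s in X.sample_ids if s in set(samples.controls)]
    case = [s for s in X.sample_ids if s in set(samples.cases)]
    n1, n2 = len(ctrl), len(case)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got control={n1}, case={n2}")
    x1 = X.data[ctrl].to_numpy(dtype=float)
    x2 = X.data[case].to_numpy(dtype=float)

    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    d_g = n1 + n2 - 2
    s2 = (ss1 + ss2) / d_g
    logfc = m2 - m1
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    if params.use_moderation:
        d0, s0_2 = fit_variance_prior(s2, d_g)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
            df_total = d0 + d_g
    else:
        d0, s0_2 = 0.0, float("nan")
        s2_post = s2
        df_total = float(d_g)

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = logfc / (np.sqrt(s2_post) * scale)
    tstat = np.where(np.isnan(tstat), 0.0, tstat)  # 0/0: no change, no evidence
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)

    table = pd.DataFrame(
        {
            "gene": X.gene_ids,
            "logFC": logfc,
            "s": np.sqrt(s2),
            "s_post": np.sqrt(s2_post),
            "t": tstat,
            "df": df_total,
            "p": p,
            "q": q,
            "direction": np.where(logfc >= 0, "up", "down"),
        }
    )
    return DEResult(table=table, d0=float(d0), s0_squared=float(s0_2))


def select_degs(res: DEResult, alpha: float) -> pd.DataFrame:
    """Genes with p < alpha, tagged up/down, sorted by p then gene."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0,1]")
    mask = res.table["p"] < alpha if alpha < 1.0 else np.ones(len(res.table), dtype=bool)
    out = res.table[mask].copy()
    return out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


def intersect_disease_genes(
    degs: pd.DataFrame, disease_genes: list[str]
) -> tuple[list[str], list[str], dict[str, int]]:
    """Split disease-gene DEGs by direction; lists are alphabetical."""
    disease = set(disease_genes)
    hit = degs[degs["gene"].isin(disease)]
    up = sorted(hit.loc[hit["direction"] == "up", "gene"])
    down = sorted(hit.loc[hit["direction"] == "down", "gene"])
    return up, down, {"up": len(up), "down": len(down), "total": len(up) + len(down)}
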