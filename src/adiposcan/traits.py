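"""Group-comparison statistics for the intermediate phenotypic traits.

The cohort's anthropometric and biochemical traits (weight, fasting
glucose, HOMA indices, lipids, adipokines, ...) are compared between
controls and cases with a Welch (unequal-variance) two-sample t-test,
either from raw per-sample vectors or from published summary statistics
(mean, SD, n per group).  Welch rather than pooled-variance t is used
because recomputation of the study's published male-column summaries
matches the printed p-values only under Welch degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CASE, CONTROL, SampleTable


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> WelchResult:
    """Welch two-sample t-test from per-group summary statistics.

    t = (mean2 - mean1) / sqrt(sd1^2/n1 + sd2^2/n2), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value
    from the Student-t survival function.

    Degenerate inputs: both SDs zero and equal means gives t = 0,
    p = 1; both SDs zero and unequal means gives p = 0 with a warning.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        if mean1 == mean2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
        warnings.warn(
            "zero variance in both groups with unequal means: p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.inf if mean2 > mean1 else -np.inf
        return WelchResult(float(t), float(n1 + n2 - 2), 0.0)
    t = (mean2 - mean1) / np.sqrt(se2)
    df = se2 * se2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def welch_t_from_vectors(x1: np.ndarray, x2: np.ndarray) -> WelchResult:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2 non-missing values")
    return welch_t_from_summary(
        float(np.mean(x1)), float(np.std(x1, ddof=1)), len(x1),
        float(np.mean(x2)), float(np.std(x2, ddof=1)), len(x2),
    )


def trait_table(samples: SampleTable, stratify_by_sex: bool = False) -> pd.DataFrame:
    """Per-trait group summaries and Welch p-values.

    Returns one row per trait (per sex stratum when requested) with
    mean, SD and n in each group plus t, df and two-sided p.  A trait
    entirely missing in one group yields a row with NaN test columns.
    """
    strata: list[tuple[str | None, SampleTable]]
    if stratify_by_sex:
        if "sex" not in samples.data.columns:
            raise ValueError("sample table has no 'sex' column to stratify by")
        strata = [
            (sex, SampleTable(samples.data[samples.data["sex"] == sex]))
            for sex in ("F", "M")
            if (samples.data["sex"] == sex).any()
        ]
    else:
        strata = [(None, samples)]

    rows = []
    for sex, tab in strata:
        df = tab.data
        ctrl = df[df["group"] == CONTROL]
        case = df[df["group"] == CASE]
        for trait in tab.trait_names:
            x1 = ctrl[trait].dropna().to_numpy(dtype=float)
            x2 = case[trait].dropna().to_numpy(dtype=float)
            row = {
                "trait": trait,
                "sex": sex if sex is not None else "all",
                "control_mean": np.mean(x1) if len(x1) else np.nan,
                "control_sd": np.std(x1, ddof=1) if len(x1) > 1 else np.nan,
                "control_n": len(x1),
                "case_mean": np.mean(x2) if len(x2) else np.nan,
                "case_sd": np.std(x2, ddof=1) if len(x2) > 1 else np.nan,
                "case_n": len(x2),
            }
            if len(x1) >= 2 and len(x2) >= 2:
                res = welch_t_from_vectors(x1, x2)
                row.update(t=res.t, df=res.df, p=res.p)
            else:
                row.update(t=np.nan, df=np.nan, p=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
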