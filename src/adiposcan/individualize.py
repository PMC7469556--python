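"""Per-patient flagging of disease genes outside a control envelope.

For each disease gene a control envelope (mean mu_c, SD sigma_c over
control samples) is computed; a case sample is flagged for a gene when
its log2 expression deviates from mu_c beyond the threshold:

* ``sd`` mode (default): |x - mu_c| > threshold * sigma_c;
* ``fold`` mode: |x - mu_c| > log2(threshold), i.e. a +/-threshold-fold
  change on the raw scale.

The per-case up/down gene lists and the population frequency of each
flagged gene summarize how individual patients deviate on the disease
gene set.  Both modes exist because the source analysis describes the
rule both ways; with threshold 2 and sigma_c = 0.5 they coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleTable

log = logging.getLogger(__name__)


@dataclass
class IndividualizationParams:
    mode: str = "sd"          # "sd" or "fold"
    threshold: float = 2.0    # +/-2 SD, or +/-2-fold (|delta log2| > 1)
    min_control_sd: float = 1e-6  # floor for degenerate control SDs

    def __post_init__(self) -> None:
        if self.mode not in ("sd", "fold"):
            raise ValueError(f"mode must be 'sd' or 'fold', got {self.mode!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.mode == "fold" and self.threshold <= 1:
            raise ValueError("fold threshold must exceed 1")


@dataclass
class ControlEnvelope:
    stats: pd.DataFrame  # index gene, columns mean/sd
    missing_genes: list[str]


@dataclass
class PatientFlagTable:
    up: dict[str, list[str]]    # case sample -> alphabetical up-flagged genes
    down: dict[str, list[str]]  # case sample -> alphabetical down-flagged genes

    def flags(self, sample: str) -> tuple[list[str], list[str]]:
        return self.up.get(sample, []), self.down.get(sample, [])

    @property
    def patients(self) -> list[str]:
        return sorted(self.up)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient": s,
                "up_regulated": ",".join(self.up[s]),
                "down_regulated": ",".join(self.down[s]),
            }
            for s in self.patients
        ]
        return pd.DataFrame(rows)


def control_envelope(
    X: ExpressionMatrix,
    samples: SampleTable,
    genes: list[str],
    min_control_sd: float = 1e-6,
) -> ControlEnvelope:
    """Per-gene control mean and sample SD (n-1), restricted to ``genes``.

    Genes absent from the matrix are excluded and logged; a zero
    control SD is floored to ``min_control_sd`` with a warning.
    """
    controls = [s for s in samples.controls if s in set(X.sample_ids)]
    if len(controls) < 2:
        raise ValueError(f"need >= 2 control samples, got {len(controls)}")
    present = [g for g in X.gene_ids if g in set(genes)]
    missing = sorted(set(genes) - set(present))
    if missing:
        log.info("%d disease gene(s) absent from the expression matrix", len(missing))
    sub = X.data.loc[present, controls]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    n_floored = int((sd < min_control_sd).sum())
    if n_floored:
        log.warning("floored %d degenerate control SD(s) to %g", n_floored, min_control_sd)
    sd = sd.clip(lower=min_control_sd)
    return ControlEnvelope(pd.DataFrame({"mean": mu, "sd": sd}), missing)


def flag_patient_genes(
    X: ExpressionMatrix,
    samples: SampleTable,
    envelope: ControlEnvelope,
    params: IndividualizationParams,
) -> PatientFlagTable:
    """Flag each case sample's genes outside the control envelope."""
    cases = samples.cases
    absent = [s for s in cases if s not in set(X.sample_ids)]
    if absent:
        raise ValueError(f"case sample(s) missing from expression matrix: {absent}")
    genes = list(envelope.stats.index)
    mu = envelope.stats["mean"].to_numpy(dtype=float)
    if params.mode == "sd":
        margin = params.threshold * envelope.stats["sd"].to_numpy(dtype=float)
    else:
        margin = np.full(len(genes), np.log2(params.threshold))
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    for s in cases:
        x = X.data.loc[genes, s].to_numpy(dtype=float)
        delta = x - mu
        up[s] = sorted(g for g, d, m in zip(genes, delta, margin) if d > m)
        down[s] = sorted(g for g, d, m in zip(genes, delta, margin) if d < -m)
    return PatientFlagTable(up=up, down=down)


def frequency_summary(flags: PatientFlagTable) -> tuple[pd.DataFrame, int]:
    """Gene flag frequencies (up and down pooled) and patients_with_any.

    Frequencies are sorted by descending count then alphabetically.
    """
    counts: dict[str, int] = {}
    patients_with_any = 0
    for s in flags.patients:
        u, d = flags.flags(s)
        if u or d:
            patients_with_any += 1
        for g in set(u) | set(d):
            counts[g] = counts.get(g, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "frequency"],
    )
    return table, patients_with_any
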