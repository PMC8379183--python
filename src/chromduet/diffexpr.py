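"""Differential-expression filtering, BH FDR, and qPCR relative expression.

The cutoff presets reproduce the study-style gene-set definitions: a gene is
"up" when log2 ratio >= threshold (inclusive), p < 0.05 and FDR < 0.05
(both strict), "down" symmetrically at <= -threshold.  Two presets are
provided: 0.27 (human knockdown contrast) and 0.58 (mouse hyperplastic
contrast).

``simple_de`` is a deliberately small stand-in test for synthetic count
tables (CPM + Welch t on log2(CPM+1)); externally computed result tables
(e.g. from a negative-binomial GLM tool) are first-class inputs via the
same TSV schema: gene_id, log2_ratio, p_value, fdr, mean_expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CutoffPreset",
    "PRESETS",
    "bh_fdr",
    "simple_de",
    "filter_de",
    "relative_expression",
]

DE_COLUMNS = ["gene_id", "log2_ratio", "p_value", "fdr", "mean_expression"]


@dataclass(frozen=True)
class CutoffPreset:
    name: str
    min_abs_log2: float
    max_p: float = 0.05
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_log2 <= 0 or self.max_p <= 0 or self.max_fdr <= 0:
            raise ValueError("thresholds must be positive")


PRESETS: dict[str, CutoffPreset] = {
    "human_sisall4": CutoffPreset("human_sisall4", 0.27),
    "mouse_hyperplastic": CutoffPreset("mouse_hyperplastic", 0.58),
}


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simple_de(counts: pd.DataFrame, group_labels: Sequence[str]) -> pd.DataFrame:
    """Two-group test on a genes x samples count table.

    Counts are normalised to CPM; the reported log2 ratio is
    log2(mean CPM_B + 1) - log2(mean CPM_A + 1) where B is the second group
    label in order of appearance, and the p-value is a Welch t-test on
    log2(CPM + 1).  All-zero genes get ratio 0 and p 1.
    """
    labels = list(group_labels)
    if len(labels) != counts.shape[1]:
        raise ValueError("one group label per sample column required")
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    idx_a = [i for i, g in enumerate(labels) if g == groups[0]]
    idx_b = [i for i, g in enumerate(labels) if g == groups[1]]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need >=2 samples per group")

    mat = counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("sample with zero total counts")
    cpm = mat / libsize * 1e6
    log_cpm = np.log2(cpm + 1.0)

    mean_a = cpm[:, idx_a].mean(axis=1)
    mean_b = cpm[:, idx_b].mean(axis=1)
    log2_ratio = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(
            log_cpm[:, idx_b], log_cpm[:, idx_a], axis=1, equal_var=False
        )
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    all_zero = mat.sum(axis=1) == 0
    log2_ratio[all_zero] = 0.0
    p[all_zero] = 1.0

    return pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "log2_ratio": log2_ratio,
            "p_value": p,
            "fdr": bh_fdr(p),
            "mean_expression": cpm.mean(axis=1),
        }
    ).reset_index(drop=True)


def filter_de(
    records: pd.DataFrame, preset: CutoffPreset | str
) -> tuple[set[str], set[str]]:
    """Split DE records into (up, down) gene sets under a cutoff preset.

    Boundary semantics follow the printed cutoffs exactly: the log2-ratio
    bound is inclusive, the p and FDR bounds strict.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    sig = (records["p_value"] < preset.max_p) & (records["fdr"] < preset.max_fdr)
    up = set(records.loc[sig & (records["log2_ratio"] >= preset.min_abs_log2), "gene_id"])
    down = set(
        records.loc[sig & (records["log2_ratio"] <= -preset.min_abs_log2), "gene_id"]
    )
    return up, down


def relative_expression(
    ct: pd.DataFrame,
    housekeeping_gene: str,
    sample_condition: Mapping[str, str],
    reference_condition: str,
) -> pd.DataFrame:
    """ddCt-style relative expression from a genes x samples Ct table.

    Per sample, dCt = Ct_gene - Ct_housekeeping; per gene and condition the
    log2 ratio is -(mean dCt_condition - mean dCt_reference), so one PCR
    cycle less in the treated condition reads as +1.
    """
    if housekeeping_gene not in ct.index:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} not in table")
    if ct.loc[housekeeping_gene].isna().any():
        raise ValueError("missing housekeeping Ct value")
    missing = set(ct.columns) - set(sample_condition)
    if missing:
        raise ValueError(f"samples without condition label: {sorted(missing)}")
    conditions = pd.Series({s: sample_condition[s] for s in ct.columns})
    if reference_condition not in set(conditions):
        raise ValueError(f"reference condition {reference_condition!r} absent")

    dct = ct.sub(ct.loc[housekeeping_gene], axis=1)
    mean_dct = dct.T.groupby(conditions).mean().T
    ratios = -(mean_dct.sub(mean_dct[reference_condition], axis=0))
    return ratios.drop(index=housekeeping_gene)
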