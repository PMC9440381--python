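"""Count normalization and the volcano-style marginal comparison.

TPM divides each gene's length-scaled read rate by the sample's total rate,
times 1e6, so every column sums to a million and values are comparable
across samples.  Network fitting downstream uses standardized log2(TPM+1):
spline regressors on raw TPM scales (which span five orders of magnitude)
are numerically fragile, and standardization puts every gene on the same
footing for the BIC score.  The raw-TPM path is retained behind the
``standardize`` config switch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    TPM_TOTAL,
    CountMatrix,
    ExpressionMatrix,
    FormatError,
    SampleLabels,
    TPMMatrix,
)


def compute_tpm(counts: CountMatrix) -> TPMMatrix:
    """Transcripts per million from counts and gene lengths.

    rate_g = count_g / length_g(kb); TPM_g = rate_g / sum_h rate_h * 1e6.
    """
    values = counts.counts.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if np.any(totals == 0):
        dead = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
        raise FormatError(f"all-zero sample column(s): {dead}")
    kb = counts.gene_lengths.to_numpy() / 1e3
    rates = values / kb[:, None]
    tpm = rates / rates.sum(axis=0, keepdims=True) * TPM_TOTAL
    frame = pd.DataFrame(tpm, index=counts.counts.index, columns=counts.counts.columns)
    return TPMMatrix(frame, column_sum_rtol=1e-9)


def log_transform(tpm: TPMMatrix, pseudo_count: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(TPM + pseudo_count); strictly monotone in TPM."""
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    return ExpressionMatrix(np.log2(tpm.tpm + pseudo_count), scale="log_tpm")


def standardize(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Zero-mean unit-sd rows; constant genes are dropped (and returned)."""
    values = expr.frame.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    constant = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
    if constant:
        warnings.warn(f"{len(constant)} constant gene(s) excluded from standardization",
                      stacklevel=2)
    keep = expr.frame.loc[[g for g in expr.gene_ids if g not in set(constant)]]
    z = keep.sub(keep.mean(axis=1), axis=0).div(keep.std(axis=1, ddof=0), axis=0)
    return ExpressionMatrix(z, scale="standardized"), constant


def filter_genes(counts: CountMatrix, min_total: int) -> CountMatrix:
    """Keep genes whose total count over all samples is STRICTLY > min_total."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = counts.counts.sum(axis=1)
    keep = totals.index[totals > min_total]
    if len(keep) < 2:
        warnings.warn("count filter leaves fewer than 2 genes", stacklevel=2)
        raise FormatError(f"count filter (> {min_total}) leaves {len(keep)} gene(s)")
    return CountMatrix(counts.counts.loc[keep], counts.gene_lengths.loc[keep])


def simple_de(tpm: TPMMatrix, labels: SampleLabels, counts: CountMatrix,
              min_total: int, pseudo_count: float = 1.0) -> pd.DataFrame:
    """Volcano-style marginal comparison on filter-passing genes.

    Welch two-sample t on log2(TPM+pseudo), fold change = difference of group
    means (case - control), Benjamini-Hochberg adjustment; sorted by p.  A
    deliberately simple baseline against which the edge-level analysis is
    contrasted - not a replacement for a count-model DE package.
    """
    if labels.n_case < 2 or labels.n_control < 2:
        raise ValueError("simple_de needs >= 2 samples per group")
    totals = counts.counts.sum(axis=1)
    kept_ids = [g for g in counts.gene_ids if totals[g] > min_total]
    if not kept_ids:
        raise FormatError(f"count filter (> {min_total}) removed every gene")
    log = np.log2(tpm.tpm.loc[kept_ids] + pseudo_count)
    case = log[labels.case_ids].to_numpy()
    ctrl = log[labels.control_ids].to_numpy()
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({
        "gene_id": kept_ids,
        "log2_fold_change": lfc,
        "t_statistic": stat,
        "p_value": p,
        "p_adjusted": p_adj,
        "passed_count_filter": True,
    })
    return table.sort_values(["p_value", "gene_id"], kind="mergesort").reset_index(drop=True)
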