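"""Expression-array processing: filtering, log2 + quantile normalization,
signed fold change, t-tests and Benjamini-Hochberg adjustment.

Differential expression between tumor and normal columns is reported as a
signed fold change on linear-scale group means (ratio r if r >= 1 else
-1/r), called up/down at |FC| >= 2 with an inclusive boundary.  t-test p
values and BH q values are computed for completeness, but with two patients
per group the selection rule is purely threshold-based.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, InputError, SampleDesign
from .methylation import FilterLog, filter_probes, quantile_normalize

FC_THRESHOLD = 2.0

UP = "up"
DOWN = "down"
NONE = "none"

# same detection-fraction contract as the methylation filter
filter_expression_probes = filter_probes


def signed_fold_change(tumor_mean_linear: float, normal_mean_linear: float) -> float:
    """Signed expression ratio: r if r >= 1 else -1/r, so |FC| >= 1 always."""
    if tumor_mean_linear <= 0 or normal_mean_linear <= 0:
        raise InputError("group means must be positive for fold change")
    r = tumor_mean_linear / normal_mean_linear
    return float(r if r >= 1 else -1.0 / r)


def two_group_t_test(group_a: np.ndarray, group_b: np.ndarray, welch: bool = False) -> float:
    """Two-sided independent two-sample t-test p value.

    Equal-variance (classic Student) by default; Welch via ``welch=True``.
    Degenerate zero-variance input: p = 1 when the means agree, 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted q values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise InputError("p values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential_expression(signed_fc: float, fc_threshold: float = FC_THRESHOLD) -> str:
    """up if FC >= threshold, down if FC <= -threshold, else none (inclusive)."""
    if signed_fc >= fc_threshold:
        return UP
    if signed_fc <= -fc_threshold:
        return DOWN
    return NONE


def process_expression_matrix(
    expr: ExpressionMatrix, alpha: float = 0.05, min_fraction: float = 0.5
) -> tuple[ExpressionMatrix, FilterLog]:
    """Filter undetected probes, log2-transform, then quantile-normalize."""
    kept, log = filter_expression_probes(
        expr.detection_p, alpha=alpha, min_fraction=min_fraction
    )
    signal = expr.signal.loc[kept]
    if (signal.values <= 0).any():
        raise InputError("non-positive signals cannot be log-transformed")
    out = ExpressionMatrix(
        signal=np.log2(signal),
        detection_p=expr.detection_p.loc[kept],
        annotation=expr.annotation.loc[kept],
        state="log2",
    )
    out.signal = quantile_normalize(out.signal)
    out.advance_state("normalized")
    return out, log


def expression_calls(
    expr: ExpressionMatrix,
    design: SampleDesign,
    group: str,
    fc_threshold: float = FC_THRESHOLD,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-probe differential-expression calls within one disease group.

    Fold change uses linear-scale group means of the normalized data; the
    t-test runs on log2 values.  Returns columns: gene_symbol, signed_fc,
    log2_fc, t_p, bh_q, status (indexed by probe_id).
    """
    if expr.state != "normalized":
        raise InputError("expression_calls expects a normalized matrix")
    tumor = design.samples(group=group, tissue="tumor")
    normal = design.samples(group=group, tissue="normal")
    if not tumor or not normal:
        raise InputError(f"design has no paired samples for group {group!r}")
    linear = expr.linear
    t_mean = linear[tumor].mean(axis=1)
    n_mean = linear[normal].mean(axis=1)
    fc = pd.Series(
        [signed_fold_change(t, n) for t, n in zip(t_mean, n_mean)], index=linear.index
    )
    log2_fc = np.log2(t_mean / n_mean)
    log2v = expr.signal
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows (planted noise-free profiles) trip scipy's
        # catastrophic-cancellation warning; the degenerate path below covers them
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(
            log2v[tumor].values, log2v[normal].values, axis=1, equal_var=not welch
        )
    t_p = pd.Series(t_res.pvalue, index=log2v.index)
    # rows with zero variance in both groups: p=1 when the means agree, else 0
    degenerate = t_p.isna()
    if degenerate.any():
        same = (
            log2v.loc[degenerate, tumor].mean(axis=1)
            == log2v.loc[degenerate, normal].mean(axis=1)
        )
        t_p.loc[degenerate] = np.where(same, 1.0, 0.0)
    bh_q = pd.Series(benjamini_hochberg(t_p.values), index=t_p.index)
    status = fc.apply(call_differential_expression, fc_threshold=fc_threshold)
    return pd.DataFrame(
        {
            "gene_symbol": expr.annotation.loc[linear.index, "gene_symbol"],
            "signed_fc": fc,
            "log2_fc": log2_fc,
            "t_p": t_p,
            "bh_q": bh_q,
            "status": status,
        }
    )
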