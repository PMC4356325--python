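"""Two-channel methylation processing: beta values, detection p, filtering,
quantile normalization and differential-methylation calls.

The beta value of a CpG probe is the background-subtracted methylated
intensity over the sum of background-subtracted methylated and unmethylated
intensities, clamped to [0, 1].  Differential methylation between groups is
the difference of group-mean beta (case minus control), called hyper- or
hypomethylated at |delta| >= 0.2 with an inclusive boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, InputError, MethylationArraySet, SampleDesign

DELTA_THRESHOLD = 0.2

HYPER = "hyper"
HYPO = "hypo"
NONE = "none"


def compute_beta(
    meth: np.ndarray | float,
    unmeth: np.ndarray | float,
    background: np.ndarray | float,
    offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted methylation fraction.

    beta = max(M - bg, 0) / (max(M - bg, 0) + max(U - bg, 0) + offset).

    ``offset`` (default 0) is the optional stabilising constant some array
    workflows add to the denominator; it is off by default because the beta
    definition used here has none.

    Returns ``(beta, zero_denominator)`` where the flag marks entries whose
    denominator (before offset) was zero; their beta is reported as 0.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise InputError("raw intensities must be non-negative")
    m = np.maximum(meth - background, 0.0)
    u = np.maximum(unmeth - background, 0.0)
    denom = m + u
    zero = denom == 0
    beta = np.where(zero, 0.0, m / np.where(zero, 1.0, denom + offset))
    return np.clip(beta, 0.0, 1.0), zero


def detection_p(signal: np.ndarray | float, negative_controls: np.ndarray) -> np.ndarray:
    """Empirical-rank detection p of a signal against negative-control probes.

    p = (#{controls >= signal} + 1) / (#controls + 1): the add-one rank
    estimate of the probability that background alone reaches the signal.
    Monotone non-increasing in the signal.
    """
    controls = np.sort(np.asarray(negative_controls, dtype=float).ravel())
    n = controls.size
    if n == 0:
        raise InputError("empty negative-control set")
    signal = np.asarray(signal, dtype=float)
    n_ge = n - np.searchsorted(controls, signal, side="left")
    return (n_ge + 1) / (n + 1)


@dataclass
class FilterLog:
    total: int
    kept: int
    removed: int
    alpha: float
    min_fraction: float


def filter_probes(
    detection_p_matrix: pd.DataFrame, alpha: float = 0.05, min_fraction: float = 0.5
) -> tuple[pd.Index, FilterLog]:
    """Keep probes detected (p < alpha) in at least ``min_fraction`` of samples."""
    frac = (detection_p_matrix.values < alpha).mean(axis=1)
    keep = frac >= min_fraction
    kept = detection_p_matrix.index[keep]
    log = FilterLog(
        total=len(detection_p_matrix),
        kept=int(keep.sum()),
        removed=int((~keep).sum()),
        alpha=alpha,
        min_fraction=min_fraction,
    )
    return kept, log


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (row-mean of sorted columns) distribution.

    Within-column ranks are preserved; tied values receive the mean of the
    reference values at their tied ranks.  A single-column matrix is returned
    unchanged.
    """
    if matrix.shape[1] < 2:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the reference over tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def delta_mean(beta_case: np.ndarray, beta_control: np.ndarray) -> float:
    """Group-mean beta difference, case minus control."""
    case = np.asarray(beta_case, dtype=float)
    control = np.asarray(beta_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise InputError("empty group in delta_mean")
    return float(case.mean() - control.mean())


def call_differential_methylation(delta: float, threshold: float = DELTA_THRESHOLD) -> str:
    """hyper if delta >= threshold, hypo if delta <= -threshold, else none.

    The boundary is inclusive: loci printed exactly at the threshold count as
    differentially methylated.
    """
    if delta >= threshold:
        return HYPER
    if delta <= -threshold:
        return HYPO
    return NONE


def betas_from_arrayset(arrays: MethylationArraySet, offset: float = 0.0) -> BetaMatrix:
    """Compute beta and detection p for every probe/sample of an array set.

    Background per sample is the mean of that sample's negative-control
    intensities.  Detection p is computed on the total (methylated +
    unmethylated) intensity against the sample's negative controls.
    """
    background = arrays.negative_controls.mean(axis=0)
    beta, zero = compute_beta(
        arrays.meth.values, arrays.unmeth.values, background.values[None, :], offset=offset
    )
    total = arrays.meth.values + arrays.unmeth.values
    pvals = np.empty_like(total, dtype=float)
    for j, sample in enumerate(arrays.sample_ids):
        pvals[:, j] = detection_p(total[:, j], arrays.negative_controls[sample].values)
    idx, cols = arrays.meth.index, arrays.meth.columns
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=cols),
        detection_p=pd.DataFrame(pvals, index=idx, columns=cols),
        zero_denominator=pd.DataFrame(zero, index=idx, columns=cols),
    )


def process_beta_matrix(
    betas: BetaMatrix, alpha: float = 0.05, min_fraction: float = 0.5
) -> tuple[BetaMatrix, FilterLog]:
    """Filter undetected probes, then quantile-normalize the beta matrix."""
    kept, log = filter_probes(betas.detection_p, alpha=alpha, min_fraction=min_fraction)
    beta = quantile_normalize(betas.beta.loc[kept])
    return (
        BetaMatrix(
            beta=beta,
            detection_p=betas.detection_p.loc[kept],
            zero_denominator=betas.zero_denominator.loc[kept],
            normalized=True,
        ),
        log,
    )


def methylation_calls(
    betas: BetaMatrix,
    design: SampleDesign,
    annotation: pd.DataFrame,
    group: str,
    threshold: float = DELTA_THRESHOLD,
) -> pd.DataFrame:
    """Per-locus differential-methylation calls within one disease group.

    Delta is computed from the group's tumor columns versus its normal
    columns.  Returns columns: locus_id, gene_symbol, delta, status
    (indexed by probe_id).
    """
    tumor = design.samples(group=group, tissue="tumor")
    normal = design.samples(group=group, tissue="normal")
    if not tumor or not normal:
        raise InputError(f"design has no paired samples for group {group!r}")
    delta = betas.beta[tumor].mean(axis=1) - betas.beta[normal].mean(axis=1)
    status = delta.apply(call_differential_methylation, threshold=threshold)
    ann = annotation.loc[betas.beta.index]
    return pd.DataFrame(
        {
            "locus_id": ann["locus_id"],
            "gene_symbol": ann["gene_symbol"],
            "delta": delta,
            "status": status,
        }
    )
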