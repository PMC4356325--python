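"""Integration of methylation and expression calls into a candidate-gene list.

The selection logic: join differentially-methylated CpG loci with
differentially-expressed probes by gene symbol, keep only sign-opposed
pairs (hypermethylated + downregulated, or hypomethylated + upregulated —
the assumption that promoter methylation represses its target), drop genes
whose effect is not reproduced in every patient of the group, and report one
record per gene carrying all of its qualifying loci with the largest-|delta|
locus shown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import expression as ex
from . import methylation as me
from .containers import (
    CATEGORIES,
    DOWN_BY_HYPER,
    GROUPS,
    UP_BY_HYPO,
    BetaMatrix,
    ExpressionMatrix,
    InputError,
    SampleDesign,
    SelectionReport,
)


@dataclass(frozen=True)
class IntegrationThresholds:
    """Selection thresholds; the per-patient minima operationalize the
    requirement that neither patient of a group shows "no change"."""

    delta_threshold: float = 0.2
    fc_threshold: float = 2.0
    patient_delta_min: float = 0.1
    patient_fc_min: float = 1.5


@dataclass
class IntegrationLog:
    loci_without_expression: int = 0
    probes_without_methylation: int = 0
    pairs_total: int = 0
    pairs_negative: int = 0
    genes_after_pairing: int = 0
    genes_removed_consistency: list[str] = field(default_factory=list)


def map_loci_to_genes(
    methylation_calls: pd.DataFrame, expression_calls: pd.DataFrame
) -> tuple[pd.DataFrame, IntegrationLog]:
    """Join CpG loci with expression probes sharing a gene symbol.

    One row per (locus, probe) pair; loci or probes whose gene has no
    counterpart in the other data type are dropped and counted in the log.
    """
    mc = methylation_calls.reset_index(names="meth_probe_id")
    xc = expression_calls.reset_index(names="expr_probe_id")
    pairs = mc.merge(xc, on="gene_symbol", suffixes=("_meth", "_expr"))
    log = IntegrationLog(
        loci_without_expression=int(
            (~mc["gene_symbol"].isin(xc["gene_symbol"])).sum()
        ),
        probes_without_methylation=int(
            (~xc["gene_symbol"].isin(mc["gene_symbol"])).sum()
        ),
        pairs_total=len(pairs),
    )
    if pairs.empty:
        meth_only = sorted(set(mc["gene_symbol"]) - set(xc["gene_symbol"]))[:10]
        expr_only = sorted(set(xc["gene_symbol"]) - set(mc["gene_symbol"]))[:10]
        raise InputError(
            "no gene symbols shared between methylation and expression "
            f"annotations (methylation-only e.g. {meth_only}; expression-only e.g. {expr_only})"
        )
    return pairs, log


def select_negative_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep sign-opposed (methylation, expression) pairs and tag the category.

    hyper + down -> down_by_hyper; hypo + up -> up_by_hypo; everything else
    (concordant, or either call 'none') is discarded.
    """
    hyper_down = (pairs["status_meth"] == me.HYPER) & (pairs["status_expr"] == ex.DOWN)
    hypo_up = (pairs["status_meth"] == me.HYPO) & (pairs["status_expr"] == ex.UP)
    out = pairs[hyper_down | hypo_up].copy()
    out["category"] = np.where(
        out["status_meth"] == me.HYPER, DOWN_BY_HYPER, UP_BY_HYPO
    )
    return out


def consistency_filter(
    per_patient_delta: pd.DataFrame,
    per_patient_fc: pd.DataFrame,
    categories: pd.Series,
    patient_delta_min: float = 0.1,
    patient_fc_min: float = 1.5,
) -> tuple[list[str], list[str]]:
    """Keep genes whose effect holds in every patient of the group.

    ``per_patient_delta``/``per_patient_fc`` are genes x patients frames of
    the per-patient beta difference and signed fold change; ``categories``
    gives each gene's group-level category.  A gene is kept iff every
    patient shows |delta| >= patient_delta_min, |FC| >= patient_fc_min, and
    per-patient signs agreeing with the group-level call.  Genes with
    missing patient data are removed.

    Returns (kept_genes, removed_genes).
    """
    kept, removed = [], []
    for gene in per_patient_delta.index:
        deltas = per_patient_delta.loc[gene]
        fcs = per_patient_fc.loc[gene]
        if deltas.isna().any() or fcs.isna().any():
            removed.append(gene)
            continue
        cat = categories.loc[gene]
        d_sign, f_sign = (1, -1) if cat == DOWN_BY_HYPER else (-1, 1)
        ok = (
            (deltas.abs() >= patient_delta_min).all()
            and (fcs.abs() >= patient_fc_min).all()
            and (np.sign(deltas) == d_sign).all()
            and (np.sign(fcs) == f_sign).all()
        )
        (kept if ok else removed).append(gene)
    return kept, removed


def build_selection_report(records: pd.DataFrame) -> SelectionReport:
    """Tally selected genes per (group x category) and order the table.

    Ordering: cancer before pre-cancer, down_by_hyper before up_by_hypo,
    then |delta| descending, then gene symbol.
    """
    report = SelectionReport()
    for group in GROUPS:
        for cat in CATEGORIES:
            n = int(((records["group"] == group) & (records["category"] == cat)).sum()) if len(records) else 0
            report.counts[SelectionReport.key(group, cat)] = n
    report.total_genes = len(records)
    report.total_loci = int(records["n_loci"].sum()) if len(records) else 0
    return report


def _order_records(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        return records
    records = records.copy()
    records["_g"] = records["group"].map({g: i for i, g in enumerate(GROUPS)})
    records["_c"] = records["category"].map({c: i for i, c in enumerate(CATEGORIES)})
    records["_d"] = -records["delta"].abs()
    records = records.sort_values(["_g", "_c", "_d", "gene_symbol"]).drop(
        columns=["_g", "_c", "_d"]
    )
    return records.reset_index(drop=True)


def _per_patient_tables(
    genes: pd.DataFrame,
    betas: BetaMatrix,
    expr: ExpressionMatrix,
    design: SampleDesign,
    group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient beta difference (reported locus) and signed FC (probe)."""
    patients = design.patients(group)
    linear = expr.linear
    d_rows, f_rows = {}, {}
    for gene, row in genes.iterrows():
        d, f = [], []
        for p in patients:
            t = design.sample_of(p, "tumor")
            n = design.sample_of(p, "normal")
            d.append(betas.beta.loc[row["meth_probe_id"], t] - betas.beta.loc[row["meth_probe_id"], n])
            f.append(ex.signed_fold_change(linear.loc[row["expr_probe_id"], t], linear.loc[row["expr_probe_id"], n]))
        d_rows[gene] = d
        f_rows[gene] = f
    return (
        pd.DataFrame.from_dict(d_rows, orient="index", columns=patients),
        pd.DataFrame.from_dict(f_rows, orient="index", columns=patients),
    )


def integrate_profiles(
    betas: BetaMatrix,
    meth_annotation: pd.DataFrame,
    expr: ExpressionMatrix,
    design: SampleDesign,
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    welch: bool = False,
) -> tuple[pd.DataFrame, SelectionReport, dict[str, IntegrationLog]]:
    """Run the per-group integration and emit ordered gene records.

    Each disease group (cancer, pre-cancer) is analyzed independently —
    tumor vs normal columns of that group — and the records concatenated.
    Returns (records, report, per-group logs); ``records`` columns:
    gene_symbol, group, category, loci, n_loci, delta, signed_fc, log2_fc.
    """
    all_records = []
    logs: dict[str, IntegrationLog] = {}
    for group in GROUPS:
        if not design.samples(group=group):
            continue
        m_calls = me.methylation_calls(
            betas, design, meth_annotation, group, threshold=thresholds.delta_threshold
        )
        x_calls = ex.expression_calls(
            expr, design, group, fc_threshold=thresholds.fc_threshold, welch=welch
        )
        try:
            pairs, log = map_loci_to_genes(m_calls, x_calls)
        except InputError:
            # no shared gene symbols at all (e.g. a pure-background simulation):
            # nothing to integrate for this group
            logs[group] = IntegrationLog(
                loci_without_expression=len(m_calls),
                probes_without_methylation=len(x_calls),
            )
            continue
        selected = select_negative_pairs(pairs)
        log.pairs_negative = len(selected)
        if selected.empty:
            logs[group] = log
            continue

        # one row per gene: all qualifying loci, the max-|delta| locus reported
        gene_rows = {}
        for gene, sub in selected.groupby("gene_symbol"):
            loci = sorted(set(sub["locus_id"]))
            best = sub.loc[sub["delta"].abs().idxmax()]
            gene_rows[gene] = {
                "gene_symbol": gene,
                "group": group,
                "category": best["category"],
                "loci": ";".join(loci),
                "n_loci": len(loci),
                "delta": float(best["delta"]),
                "signed_fc": float(best["signed_fc"]),
                "log2_fc": float(best["log2_fc"]),
                "meth_probe_id": best["meth_probe_id"],
                "expr_probe_id": best["expr_probe_id"],
            }
        genes = pd.DataFrame.from_dict(gene_rows, orient="index")
        log.genes_after_pairing = len(genes)

        ppd, ppf = _per_patient_tables(genes, betas, expr, design, group)
        kept, removed = consistency_filter(
            ppd,
            ppf,
            genes["category"],
            patient_delta_min=thresholds.patient_delta_min,
            patient_fc_min=thresholds.patient_fc_min,
        )
        log.genes_removed_consistency = removed
        logs[group] = log
        all_records.append(genes.loc[kept].drop(columns=["meth_probe_id", "expr_probe_id"]))

    records = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame(
            columns=[
                "gene_symbol",
                "group",
                "category",
                "loci",
                "n_loci",
                "delta",
                "signed_fc",
                "log2_fc",
            ]
        )
    )
    records = _order_records(records)
    _assert_category_invariants(records, thresholds)
    return records, build_selection_report(records), logs


def _assert_category_invariants(records: pd.DataFrame, thr: IntegrationThresholds) -> None:
    """Every output record must satisfy its category's sign contract."""
    for _, r in records.iterrows():
        if r["category"] == DOWN_BY_HYPER:
            ok = r["delta"] >= thr.delta_threshold and r["signed_fc"] <= -thr.fc_threshold
        else:
            ok = r["delta"] <= -thr.delta_threshold and r["signed_fc"] >= thr.fc_threshold
        if not ok:
            raise AssertionError(
                f"record {r['gene_symbol']} violates {r['category']} sign invariant"
            )
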