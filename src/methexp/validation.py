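"""Validation-arm analytics: qPCR relative quantification, in-silico
bisulfite conversion, and methylation-specific PCR (MSP) primer matching.

The wet-lab experiment these mirror: HeLa cells treated with increasing
doses of the demethylating agent 5-aza-2'-deoxycytidine (decitabine; 0, 5,
10, 20 uM), after which target-gene expression is quantified by the
2^-ddCt method and promoter methylation probed by MSP on
bisulfite-converted DNA with methylation- and unmethylation-specific
primer pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .containers import InputError
from .resources import load_msp_primers

DECITABINE_DOSES_UM = (0.0, 5.0, 10.0, 20.0)


def relative_expression_ddct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_baseline: float,
    ct_ref_baseline: float,
) -> float:
    """Fold expression by the 2^-ddCt method.

    ddCt = (Ct_target,cond - Ct_ref,cond) - (Ct_target,base - Ct_ref,base);
    invariant under adding any constant to all four Ct values.
    """
    for ct in (ct_target_cond, ct_ref_cond, ct_target_baseline, ct_ref_baseline):
        if not math.isfinite(ct):
            raise InputError("Ct values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_baseline - ct_ref_baseline)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class PrimerPair:
    """An MSP primer pair specific for methylated or unmethylated template."""

    gene: str
    specificity: str  # "methylated" | "unmethylated"
    sense: str
    antisense: str
    expected_product_bp: int

    def __post_init__(self) -> None:
        for seq in (self.sense, self.antisense):
            if not seq or set(seq) - set("ACGT"):
                raise InputError(f"primer must be non-empty uppercase ACGT: {seq!r}")
        if self.specificity not in ("methylated", "unmethylated"):
            raise InputError(f"unknown specificity {self.specificity!r}")


def packaged_primer_pairs() -> list[PrimerPair]:
    """The packaged MSP primer pairs for the three validated genes."""
    return [
        PrimerPair(
            gene=r.gene,
            specificity=r.specificity,
            sense=r.sense,
            antisense=r.antisense,
            expected_product_bp=int(r.product_bp),
        )
        for r in load_msp_primers().itertuples(index=False)
    ]


def bisulfite_convert(sequence: str, methylated_cpg_positions: frozenset[int] | set[int] = frozenset()) -> str:
    """Bisulfite conversion of a top strand: C -> T except protected 5mC.

    ``methylated_cpg_positions`` are 0-based indices of methylated CpG
    cytosines, which the chemistry does not touch.  Positions must point at
    a C in CpG context.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise InputError("sequence must be ACGT only")
    for pos in methylated_cpg_positions:
        if not (0 <= pos < len(seq)) or seq[pos] != "C" or pos + 1 >= len(seq) or seq[pos + 1] != "G":
            raise InputError(f"position {pos} is not a CpG-context cytosine")
    out = []
    for i, base in enumerate(seq):
        if base == "C" and i not in methylated_cpg_positions:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass
class MspMatch:
    """All amplicons a primer pair supports on one converted template."""

    gene: str
    specificity: str
    products: list[tuple[int, int, int]]  # (sense_start, antisense_end, size_bp)
    ambiguous: bool

    @property
    def matched(self) -> bool:
        return bool(self.products)

    @property
    def product_size(self) -> int | None:
        return self.products[0][2] if self.products else None


def _find_all(template: str, pattern: str) -> list[int]:
    hits, start = [], template.find(pattern)
    while start != -1:
        hits.append(start)
        start = template.find(pattern, start + 1)
    return hits


def msp_match(primer_pair: PrimerPair, converted_template: str) -> MspMatch:
    """Exact-match both primers on a bisulfite-converted top strand.

    The sense primer is searched as-is, the antisense primer as its reverse
    complement.  The product size is counted inclusively from the first base
    of the sense site to the last base of the antisense site.  Multiple
    possible amplicons are all reported and flagged ambiguous.
    """
    template = converted_template.upper()
    anti_rc = reverse_complement(primer_pair.antisense)
    sense_hits = _find_all(template, primer_pair.sense)
    anti_hits = _find_all(template, anti_rc)
    products = []
    for s in sense_hits:
        for a in anti_hits:
            end = a + len(anti_rc) - 1
            if a >= s + len(primer_pair.sense) or (s == a and len(anti_rc) == len(primer_pair.sense)):
                products.append((s, end, end - s + 1))
    # a primer pair equal to the whole template amplifies the template itself
    if not products and primer_pair.sense == template and anti_rc == template:
        products.append((0, len(template) - 1, len(template)))
    products.sort()
    return MspMatch(
        gene=primer_pair.gene,
        specificity=primer_pair.specificity,
        products=products,
        ambiguous=len(products) > 1,
    )


def embed_primer_pair(
    primer_pair: PrimerPair,
    product_bp: int | None = None,
    flank: int = 30,
    seed: int = 0,
) -> str:
    """Synthetic converted-alphabet template with one amplicon planted.

    The sense primer and the reverse complement of the antisense primer are
    placed so the inclusive sense-start to antisense-end span equals
    ``product_bp`` (default: the pair's expected product size).  Filler is
    random over A/T/G — the alphabet of a fully converted non-CpG strand —
    and the construction is rejected and reseeded if a spurious primer site
    appears.
    """
    size = product_bp if product_bp is not None else primer_pair.expected_product_bp
    anti_rc = reverse_complement(primer_pair.antisense)
    gap = size - len(primer_pair.sense) - len(anti_rc)
    if gap < 0:
        raise InputError(f"product of {size} bp cannot hold both primer footprints")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ATG"))
    for _ in range(100):
        middle = "".join(rng.choice(bases, size=gap))
        left = "".join(rng.choice(bases, size=flank))
        right = "".join(rng.choice(bases, size=flank))
        template = left + primer_pair.sense + middle + anti_rc + right
        result = msp_match(primer_pair, template)
        if result.products == [(flank, flank + size - 1, size)]:
            return template
    raise InputError("could not build an unambiguous template")


def dose_response_summary(
    relative_expressions: dict[float, float], tolerance: float = 0.0
) -> dict:
    """Monotonicity verdict over the decitabine dose series.

    ``relative_expressions`` maps dose -> fold vs the 0-dose baseline
    (baseline itself must be present).  The verdict is non-decreasing fold
    across increasing doses, allowing each step to dip by at most
    ``tolerance`` (a fraction of the previous fold).  Missing doses from the
    canonical series make the verdict partial.
    """
    if 0.0 not in relative_expressions:
        raise InputError("baseline dose 0 missing from dose series")
    doses = sorted(relative_expressions)
    folds = [relative_expressions[d] for d in doses]
    monotone = all(
        later >= earlier * (1.0 - tolerance) for earlier, later in zip(folds, folds[1:])
    )
    missing = [d for d in DECITABINE_DOSES_UM if d not in relative_expressions]
    return {
        "doses": doses,
        "folds": folds,
        "monotone_increasing": bool(monotone),
        "partial": bool(missing),
        "missing_doses": missing,
        "tolerance": tolerance,
    }


def ct_table_fold_changes(
    ct_table: pd.DataFrame,
    reference_gene: str,
    baseline_condition: float | str = 0.0,
) -> pd.DataFrame:
    """Per-gene, per-condition 2^-ddCt folds from a long-format Ct table.

    ``ct_table`` columns: gene, condition, replicate, ct.  Replicate Ct
    values are averaged per (gene, condition); the named housekeeping
    ``reference_gene`` anchors each condition and ``baseline_condition``
    anchors the series.
    """
    required = {"gene", "condition", "ct"}
    if required - set(ct_table.columns):
        raise InputError(f"Ct table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise InputError("Ct values must be positive")
    mean_ct = ct_table.groupby(["gene", "condition"])["ct"].mean()
    genes = [g for g in ct_table["gene"].unique() if g != reference_gene]
    conditions = sorted(ct_table["condition"].unique())
    if reference_gene not in set(ct_table["gene"]):
        raise InputError(f"reference gene {reference_gene!r} absent from Ct table")
    rows = []
    for gene in genes:
        for cond in conditions:
            try:
                fold = relative_expression_ddct(
                    mean_ct[(gene, cond)],
                    mean_ct[(reference_gene, cond)],
                    mean_ct[(gene, baseline_condition)],
                    mean_ct[(reference_gene, baseline_condition)],
                )
            except KeyError as err:
                raise InputError(f"missing Ct for {gene}/{cond}: {err}") from err
            rows.append({"gene": gene, "condition": cond, "fold": fold})
    return pd.DataFrame(rows)
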