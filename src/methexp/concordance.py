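"""Database-concordance tallies for the candidate-gene table.

Two external resources annotate the packaged 19-gene table: CCDB (a curated
cervical-cancer gene database; a gene absent from it is "novel") and GENT
(a cross-tissue expression compendium; a gene is direction-concordant when
GENT's tumor-vs-normal direction matches the sign of the fold change found
here).  Both are consumed as packaged static columns — the live web
resources are version-unstable and out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import InputError
from .resources import load_integrated_genes

CCDB_STATUSES = ("down", "up", "absent")
GENT_DIRECTIONS = ("down", "down_highly", "up", "up_highly", "not_changed", "absent")

_GENT_DOWN = {"down", "down_highly"}
_GENT_UP = {"up", "up_highly"}


def _check(rows: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "fold_change", "ccdb", "gent"}
    if required - set(rows.columns):
        raise InputError(f"annotation table needs columns {sorted(required)}")
    if rows["gene"].duplicated().any():
        raise InputError("duplicate gene rows in annotation table")
    bad = set(rows["ccdb"]) - set(CCDB_STATUSES) | set(rows["gent"]) - set(GENT_DIRECTIONS)
    if bad:
        raise InputError(f"unknown annotation labels: {sorted(bad)}")
    return rows


def tally_novel(rows: pd.DataFrame) -> int:
    """Number of genes absent from CCDB (i.e. novel for cervical cancer)."""
    if rows.empty:
        return 0
    return int((_check(rows)["ccdb"] == "absent").sum())


def gene_concordant(fold_change_sign: str, gent_direction: str) -> bool:
    """True when the GENT direction matches this study's fold-change sign.

    "not_changed" and "absent" never concord; qualifier levels (plain vs
    "highly") are ignored by the tally.
    """
    if fold_change_sign == "down":
        return gent_direction in _GENT_DOWN
    if fold_change_sign == "up":
        return gent_direction in _GENT_UP
    raise InputError(f"fold_change_sign must be up/down, got {fold_change_sign!r}")


def tally_gent_concordance(rows: pd.DataFrame) -> int:
    """Number of genes whose GENT direction agrees with the observed sign."""
    if rows.empty:
        return 0
    rows = _check(rows)
    signs = rows["fold_change"].apply(lambda f: "down" if f < 0 else "up")
    return int(
        sum(gene_concordant(s, g) for s, g in zip(signs, rows["gent"]))
    )


def concordance_report(rows: pd.DataFrame | None = None) -> dict:
    """Full JSON-able concordance report (defaults to the packaged table)."""
    if rows is None:
        rows = load_integrated_genes()
    if rows.empty:
        return {"total": 0, "novel_ccdb": 0, "gent_concordant": 0, "per_gene": []}
    rows = _check(rows)
    signs = rows["fold_change"].apply(lambda f: "down" if f < 0 else "up")
    per_gene = [
        {
            "gene": r.gene,
            "fold_change_sign": s,
            "ccdb": r.ccdb,
            "gent": r.gent,
            "novel": r.ccdb == "absent",
            "gent_concordant": gene_concordant(s, r.gent),
        }
        for r, s in zip(rows.itertuples(index=False), signs)
    ]
    return {
        "total": len(rows),
        "novel_ccdb": tally_novel(rows),
        "gent_concordant": tally_gent_concordance(rows),
        "per_gene": per_gene,
    }


def write_concordance_report(path: str | Path, rows: pd.DataFrame | None = None) -> dict:
    report = concordance_report(rows)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
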