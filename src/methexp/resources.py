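"""Loaders for the packaged reference tables.

Three static tables ship with the package:

* ``integrated_genes.tsv`` — the 19 candidate genes with their group-mean
  methylation difference (delta), signed expression fold change, and the
  cervical-cancer database (CCDB) / cross-tissue expression database (GENT)
  annotations used by the concordance report.
* ``msp_primers.tsv`` — methylation- and unmethylation-specific PCR primer
  pairs with expected product sizes for the three validated genes.
* ``functional_clusters.tsv`` — static gene-ontology annotation clusters of
  the 19 genes (reference only; never recomputed here).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "methexp.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_integrated_genes() -> pd.DataFrame:
    """The packaged 19-gene candidate table (one row per gene)."""
    df = _read("integrated_genes.tsv")
    df["delta"] = df["delta"].astype(float)
    df["fold_change"] = df["fold_change"].astype(float)
    return df


def load_msp_primers() -> pd.DataFrame:
    """Packaged MSP primer pairs (gene, specificity, sense, antisense, product_bp)."""
    return _read("msp_primers.tsv")


def load_functional_clusters() -> pd.DataFrame:
    """Static functional-annotation clustering of the 19 genes."""
    return _read("functional_clusters.tsv")
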