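"""In-memory containers for the paired tumor/normal array study design.

The study layout is four patients — two invasive cervical-cancer cases and
two pre-invasive (CIN III / CIS) cases — each contributing a normal and a
tumor biopsy, so every matrix in the pipeline is probes x 8 samples.
Containers are thin dataclasses around :class:`pandas.DataFrame` so that all
downstream arithmetic stays in pandas/numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("cancer", "pre-cancer")
TISSUES = ("normal", "tumor")

#: categories of an integrated candidate gene
DOWN_BY_HYPER = "down_by_hyper"
UP_BY_HYPO = "up_by_hypo"
CATEGORIES = (DOWN_BY_HYPER, UP_BY_HYPO)


class InputError(ValueError):
    """Raised when an input matrix or parameter violates a contract."""


@dataclass
class SampleDesign:
    """Maps array columns to (patient, disease group, tissue).

    ``table`` columns: ``sample_id``, ``patient``, ``group`` (one of
    :data:`GROUPS`), ``tissue`` (one of :data:`TISSUES`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "patient", "group", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"design table missing columns: {sorted(missing)}")
        bad_group = set(self.table["group"]) - set(GROUPS)
        bad_tissue = set(self.table["tissue"]) - set(TISSUES)
        if bad_group or bad_tissue:
            raise InputError(
                f"unknown group/tissue labels: {sorted(bad_group | bad_tissue)}"
            )

    @classmethod
    def paired(cls, n_cancer: int = 2, n_precancer: int = 2) -> "SampleDesign":
        """Build the paired design: each patient has one normal, one tumor array."""
        rows = []
        for group, prefix, n in (("cancer", "CX", n_cancer), ("pre-cancer", "PC", n_precancer)):
            for i in range(1, n + 1):
                patient = f"{prefix}{i}"
                for tissue, suffix in (("normal", "N"), ("tumor", "T")):
                    rows.append(
                        {
                            "sample_id": f"{patient}_{suffix}",
                            "patient": patient,
                            "group": group,
                            "tissue": tissue,
                        }
                    )
        return cls(pd.DataFrame(rows))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, group: str | None = None, tissue: str | None = None) -> list[str]:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return list(t["sample_id"])

    def patients(self, group: str | None = None) -> list[str]:
        t = self.table if group is None else self.table[self.table["group"] == group]
        return list(dict.fromkeys(t["patient"]))

    def sample_of(self, patient: str, tissue: str) -> str:
        t = self.table
        hit = t[(t["patient"] == patient) & (t["tissue"] == tissue)]
        if len(hit) != 1:
            raise InputError(f"no unique sample for patient={patient}, tissue={tissue}")
        return hit["sample_id"].iloc[0]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MethylationArraySet:
    """Two-channel methylation array data for one sample set.

    ``meth``/``unmeth`` are probes x samples fluorescence intensities,
    ``negative_controls`` is controls x samples background intensities, and
    ``annotation`` maps each probe to a gene symbol and CpG locus id
    (index: probe_id; columns: gene_symbol, locus_id).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    negative_controls: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise InputError("meth and unmeth matrices must share probes and samples")
        if not self.negative_controls.columns.equals(self.meth.columns):
            raise InputError("negative controls must cover the same samples")
        for name, m in (("meth", self.meth), ("unmeth", self.unmeth)):
            if (m.values < 0).any():
                raise InputError(f"negative raw intensities in {name} channel")
        missing = self.meth.index.difference(self.annotation.index)
        if len(missing):
            raise InputError(f"{len(missing)} probes lack annotation")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.meth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with detection p companions.

    ``beta`` values lie in [0, 1]: the fraction of methylated signal after
    background subtraction. ``zero_denominator`` flags probes/samples where
    both channels fell below background (beta reported as 0).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    zero_denominator: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        b = self.beta.values
        if ((b < 0) | (b > 1)).any():
            raise InputError("beta values outside [0, 1]")
        p = self.detection_p.values
        if ((p < 0) | (p > 1)).any():
            raise InputError("detection p outside [0, 1]")


@dataclass
class ExpressionMatrix:
    """Single-channel expression signals with processing-state tracking.

    ``state`` follows raw -> log2 -> normalized; fold changes are always
    computed from linear-scale values (2**x once log-transformed).
    ``annotation`` maps probe_id -> gene_symbol.
    """

    signal: pd.DataFrame
    detection_p: pd.DataFrame
    annotation: pd.DataFrame
    state: str = "raw"

    _STATES = ("raw", "log2", "normalized")

    def __post_init__(self) -> None:
        if self.state not in self._STATES:
            raise InputError(f"unknown state {self.state!r}")
        if self.state != "raw" and not np.isfinite(self.signal.values).all():
            raise InputError("non-finite values in log-scale expression matrix")

    def advance_state(self, new_state: str) -> None:
        order = self._STATES
        if order.index(new_state) != order.index(self.state) + 1:
            raise InputError(f"illegal state transition {self.state} -> {new_state}")
        self.state = new_state

    @property
    def linear(self) -> pd.DataFrame:
        """Signals on the linear scale regardless of current state."""
        if self.state == "raw":
            return self.signal
        return 2.0 ** self.signal


@dataclass
class SelectionReport:
    """Counts of selected genes per (disease group x regulation category)."""

    counts: dict[str, int] = field(default_factory=dict)
    total_genes: int = 0
    total_loci: int = 0

    @staticmethod
    def key(group: str, category: str) -> str:
        return f"{group}:{category}"

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total_genes": self.total_genes,
            "total_loci": self.total_loci,
        }
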