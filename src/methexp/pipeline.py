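"""End-to-end pipeline: simulate -> methylation -> expression -> integrate ->
cluster -> validate -> report, driven by a single serializable config.

Every stage is a pure function of (inputs, config); intermediates are
written as TSVs with a JSON sidecar schema that carries the config hash, so
a rerun with the same config is byte-identical and any stage can be re-run
in isolation from saved intermediates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, concordance, validation
from .containers import (
    BetaMatrix,
    ExpressionMatrix,
    InputError,
    MethylationArraySet,
    SampleDesign,
    SelectionReport,
)
from .expression import process_expression_matrix
from .integration import IntegrationThresholds, integrate_profiles
from .methylation import betas_from_arrayset, process_beta_matrix
from .resources import load_integrated_genes
from .simulate import SimulationParams, fixture_from_table1, generate_expression_set, generate_methylation_set

FLOAT_FORMAT = "%.10g"


class ConfigError(InputError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, source selection and determinism settings for a run.

    ``source`` is "table1_fixture" (plant the packaged 19-gene table plus
    ``decoys`` sub-threshold genes) or "simulate" (free simulation from
    ``simulation`` parameters).
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    source: str = "table1_fixture"
    decoys: int = 1000
    alpha: float = 0.05
    min_fraction: float = 0.5
    delta_threshold: float = 0.2
    fc_threshold: float = 2.0
    patient_delta_min: float = 0.1
    patient_fc_min: float = 1.5
    noise_sd_beta: float = 0.0
    background_sd: float = 0.0
    welch: bool = False
    stages: tuple[str, ...] = (
        "simulate",
        "methylation",
        "expression",
        "integrate",
        "cluster",
        "validate",
        "report",
    )
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "alpha",
            "min_fraction",
            "delta_threshold",
            "fc_threshold",
            "patient_delta_min",
            "patient_fc_min",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.source not in ("table1_fixture", "simulate"):
            raise ConfigError(f"unknown source {self.source!r}")
        if self.decoys < 0:
            raise ConfigError("decoys must be >= 0")

    def thresholds(self) -> IntegrationThresholds:
        return IntegrationThresholds(
            delta_threshold=self.delta_threshold,
            fc_threshold=self.fc_threshold,
            patient_delta_min=self.patient_delta_min,
            patient_fc_min=self.patient_fc_min,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        try:
            return cls(**d)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        """Hash of the analysis settings (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index_label: str | None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label,
              index=index_label is not None)
    schema = {
        "config_hash": cfg_hash,
        "columns": [index_label, *df.columns] if index_label else list(df.columns),
        "rows": len(df),
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=1, sort_keys=True) + "\n"
    )


def _write_json(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    report: SelectionReport
    records: pd.DataFrame
    concordance: dict
    validation: dict
    out_dir: Path
    files: list[str]


def _simulate(config: PipelineConfig) -> tuple[MethylationArraySet, ExpressionMatrix, SampleDesign]:
    if config.source == "table1_fixture":
        return fixture_from_table1(
            decoys=config.decoys,
            seed=config.seed,
            noise_sd_beta=config.noise_sd_beta,
            background_sd=config.background_sd,
        )
    params = SimulationParams(seed=config.seed, **config.simulation)
    meth = generate_methylation_set(params)
    expr = generate_expression_set(params)
    return meth, expr, params.design()


def _validation_demo(config: PipelineConfig) -> dict:
    """Deterministic validation-arm demo on the packaged primers.

    Builds a synthetic Ct table with a planted dose-dependent re-expression
    of the three validated genes, summarizes 2^-ddCt dose response, and
    checks MSP primer specificity/product size on synthetic converted
    templates.
    """
    rng = np.random.default_rng(config.seed + 7)
    genes = ("CAMK2N1", "ALDH1A3", "PPP1R3C")
    doses = validation.DECITABINE_DOSES_UM
    planted_folds = {0.0: 1.0, 5.0: 1.8, 10.0: 3.2, 20.0: 5.5}
    rows = []
    gene_base = {gene: 26.0 + 2.0 * rng.random() for gene in genes}
    for dose in doses:
        for rep in (1, 2, 3):
            rows.append({"gene": "REF", "condition": dose, "replicate": rep, "ct": 18.0})
        for gene in genes:
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "gene": gene,
                        "condition": dose,
                        "replicate": rep,
                        "ct": gene_base[gene] - np.log2(planted_folds[dose]),
                    }
                )
    ct_table = pd.DataFrame(rows)
    folds = validation.ct_table_fold_changes(ct_table, reference_gene="REF")
    out: dict = {"dose_response": {}, "msp": {}}
    for gene in genes:
        sub = folds[folds["gene"] == gene]
        series = dict(zip(sub["condition"], sub["fold"]))
        out["dose_response"][gene] = validation.dose_response_summary(series)
    for pair in validation.packaged_primer_pairs():
        if pair.specificity != "methylated":
            continue
        template = validation.embed_primer_pair(pair, seed=config.seed + 11)
        hit = validation.msp_match(pair, template)
        unmeth = next(
            p
            for p in validation.packaged_primer_pairs()
            if p.gene == pair.gene and p.specificity == "unmethylated"
        )
        cross = validation.msp_match(unmeth, template)
        out["msp"][pair.gene] = {
            "expected_product_bp": pair.expected_product_bp,
            "observed_product_bp": hit.product_size,
            "unmethylated_pair_matches": cross.matched,
        }
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all enabled stages in order and write artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    files: list[str] = []

    def record(path: Path) -> Path:
        files.append(path.name)
        return path

    stage = "simulate"
    try:
        meth_set, expr_raw, design = _simulate(config)
        design.to_tsv(record(out / "design.tsv"))
        _write_tsv(meth_set.annotation, out / "meth_annotation.tsv", h, "probe_id")
        record(out / "meth_annotation.tsv")

        stage = "methylation"
        betas_raw = betas_from_arrayset(meth_set)
        betas, meth_log = process_beta_matrix(
            betas_raw, alpha=config.alpha, min_fraction=config.min_fraction
        )
        _write_tsv(betas.beta, record(out / "beta_normalized.tsv"), h, "probe_id")

        stage = "expression"
        expr, expr_log = process_expression_matrix(
            expr_raw, alpha=config.alpha, min_fraction=config.min_fraction
        )
        _write_tsv(expr.signal, record(out / "expression_normalized_log2.tsv"), h, "probe_id")

        stage = "integrate"
        records, report, logs = integrate_profiles(
            betas,
            meth_set.annotation,
            expr,
            design,
            thresholds=config.thresholds(),
            welch=config.welch,
        )
        table = _attach_reference_annotations(records)
        _write_tsv(table, record(out / "integrated_genes.tsv"), h, None)
        _write_json(
            {
                "selection": report.as_dict(),
                "filter_logs": {
                    "methylation": vars(meth_log),
                    "expression": vars(expr_log),
                },
                "integration_logs": {g: vars(l) for g, l in logs.items()},
            },
            record(out / "selection_report.json"),
            h,
        )

        stage = "cluster"
        if "cluster" in config.stages:
            files.extend(_cluster_stage(records, betas, expr, design, out, h))

        stage = "validate"
        val = _validation_demo(config) if "validate" in config.stages else {}
        if val:
            _write_json(val, record(out / "validation_report.json"), h)

        stage = "report"
        conc = concordance.concordance_report()
        _write_json(conc, record(out / "concordance_report.json"), h)

        _write_json(
            {"config": config.to_dict(), "files": sorted(files)},
            out / "manifest.json",
            h,
        )
    except (InputError, KeyError, ValueError) as err:
        raise StageError(stage, err) from err
    return PipelineResult(
        report=report,
        records=records,
        concordance=conc,
        validation=val,
        out_dir=out,
        files=sorted(files),
    )


def _attach_reference_annotations(records: pd.DataFrame) -> pd.DataFrame:
    """Add accession/CCDB/GENT columns from the packaged table where known."""
    ref = load_integrated_genes().set_index("gene")
    table = records.copy()
    for col, default in (("accession", "-"), ("ccdb", "absent"), ("gent", "absent")):
        table[col] = [
            ref[col].get(g, default) if col in ref.columns else default
            for g in table["gene_symbol"]
        ]
    return table


def _cluster_stage(
    records: pd.DataFrame,
    betas: BetaMatrix,
    expr: ExpressionMatrix,
    design: SampleDesign,
    out: Path,
    cfg_hash: str,
) -> list[str]:
    """Cluster per-patient delta and log2-FC profiles of the selected genes.

    The clustered input mirrors the red/green per-patient heatmap: one
    column per patient, one row per selected gene, methylation and
    expression matrices side by side.
    """
    if len(records) < 2:
        return []
    patients = design.patients()
    meth_rows, expr_rows = {}, {}
    for _, r in records.iterrows():
        locus = r["loci"].split(";")[0]
        gene = r["gene_symbol"]
        d_vals, f_vals = [], []
        for p in patients:
            t, n = design.sample_of(p, "tumor"), design.sample_of(p, "normal")
            d_vals.append(float(betas.beta.loc[locus, t] - betas.beta.loc[locus, n]))
        meth_rows[gene] = d_vals
        expr_probe = expr.annotation.index[expr.annotation["gene_symbol"] == gene]
        lin = expr.linear.loc[expr_probe[0]]
        for p in patients:
            t, n = design.sample_of(p, "tumor"), design.sample_of(p, "normal")
            f_vals.append(float(np.log2(lin[t] / lin[n])))
        expr_rows[gene] = f_vals
    written: list[str] = []
    for name, rows in (("methylation", meth_rows), ("expression", expr_rows)):
        mat = pd.DataFrame.from_dict(rows, orient="index", columns=patients)
        if (mat.std(axis=1) == 0).any() or (mat.std(axis=0) == 0).any():
            # degenerate profiles cannot be clustered with correlation distance
            continue
        ordered, row_tree, col_tree = clustering.cluster_matrix(mat)
        paths = clustering.write_treeview_files(
            ordered, out / f"cluster_{name}", row_tree=row_tree, col_tree=col_tree
        )
        if row_tree is not None:
            (out / f"cluster_{name}_dendrogram.json").write_text(row_tree.to_json() + "\n")
            written.append(f"cluster_{name}_dendrogram.json")
        written.extend(p.name for p in paths.values())
    return written
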