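"""Synthetic two-channel methylation and expression array generator.

Emulates the study design: two cervical-cancer patients and two
pre-invasive-cancer patients, each with a paired normal/tumor array (8
columns).  Effects are planted per gene: a methylation difference
``delta_beta`` (tumor minus normal group-mean beta) and a signed expression
``log2_fc``, applied identically in both patients of the gene's disease
group so the per-patient consistency filter passes by construction.

Intensities relate to beta through ``M = scale * beta + background`` and
``U = scale * (1 - beta) + background``; negative-control probes draw from
the same background distribution, which is what the beta computation
subtracts back out.

The deterministic fixture (:func:`fixture_from_table1`) plants the packaged
19-gene table exactly.  So that the printed delta and fold-change values
survive quantile normalization bit-for-bit, every effect probe is paired
with a mirror probe carrying the same two values with tumor/normal swapped:
all array columns are then permutations of one another and quantile
normalization is an exact fixed point.  Mirror probes belong to synthetic
"complement" genes whose other data type is flat, so the negative-correlation
step discards them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    GROUPS,
    ExpressionMatrix,
    InputError,
    MethylationArraySet,
    SampleDesign,
)
from .resources import load_integrated_genes


@dataclass(frozen=True)
class PlantedGene:
    """One gene with planted methylation and expression effects.

    ``delta_beta`` is the tumor-minus-normal group-mean beta difference in
    [-1, 1]; ``log2_fc`` the log2 tumor/normal expression ratio.  The
    control (normal) beta defaults to 0.5 - delta_beta/2 so tumor and normal
    betas sit symmetrically inside [0, 1].
    """

    gene_symbol: str
    group: str
    delta_beta: float
    log2_fc: float
    n_cpg_loci: int = 1
    baseline_beta: float | None = None
    baseline_log2_expr: float = 8.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InputError(f"unknown group {self.group!r}")
        if not -1.0 <= self.delta_beta <= 1.0:
            raise InputError("delta_beta outside [-1, 1]")
        if self.n_cpg_loci < 1:
            raise InputError("n_cpg_loci must be >= 1")
        b = self.beta_normal
        for v in (b, b + self.delta_beta):
            if not 0.0 <= v <= 1.0:
                raise InputError(
                    f"{self.gene_symbol}: baseline {b:.3f} + delta {self.delta_beta:.3f} "
                    "pushes beta outside [0, 1]"
                )

    @property
    def beta_normal(self) -> float:
        if self.baseline_beta is not None:
            return self.baseline_beta
        return 0.5 - self.delta_beta / 2.0


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings.

    Counts default to the platforms emulated (~485k CpG probes, ~47k
    expression probes); tests and the fixture use far smaller matrices.
    ``noise_sd_beta`` is the SD of truncated-Gaussian noise added to beta
    per probe/sample; expression noise is Gaussian on the log2 scale.
    """

    planted_genes: tuple[PlantedGene, ...] = ()
    n_patients_cancer: int = 2
    n_patients_precancer: int = 2
    n_cpg_probes: int = 10_000
    n_expr_probes: int = 47_000
    n_negative_controls: int = 100
    noise_sd_beta: float = 0.02
    noise_sd_log2_expr: float = 0.1
    intensity_scale: float = 5_000.0
    background_mean: float = 200.0
    background_sd: float = 20.0
    detection_p_expressed: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_patients_cancer",
            "n_patients_precancer",
            "n_cpg_probes",
            "n_expr_probes",
            "n_negative_controls",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.noise_sd_beta < 0 or self.noise_sd_log2_expr < 0:
            raise InputError("noise SDs must be >= 0")
        symbols = [g.gene_symbol for g in self.planted_genes]
        if len(symbols) != len(set(symbols)):
            raise InputError("planted gene symbols must be unique")
        n_loci = sum(g.n_cpg_loci for g in self.planted_genes)
        if n_loci > self.n_cpg_probes:
            raise InputError("n_cpg_probes smaller than planted loci")
        if len(self.planted_genes) > self.n_expr_probes:
            raise InputError("n_expr_probes smaller than planted genes")

    def design(self) -> SampleDesign:
        return SampleDesign.paired(self.n_patients_cancer, self.n_patients_precancer)


def _tumor_mask(design: SampleDesign, group: str) -> np.ndarray:
    t = design.table
    return ((t["group"] == group) & (t["tissue"] == "tumor")).to_numpy()


def _beta_row(gene: PlantedGene, design: SampleDesign) -> np.ndarray:
    """Noise-free beta profile of one locus across all columns."""
    row = np.full(len(design.table), gene.beta_normal)
    row[_tumor_mask(design, gene.group)] += gene.delta_beta
    return row


def _log2_expr_row(gene: PlantedGene, design: SampleDesign) -> np.ndarray:
    row = np.full(len(design.table), gene.baseline_log2_expr)
    row[_tumor_mask(design, gene.group)] += gene.log2_fc
    return row


def generate_methylation_set(params: SimulationParams) -> MethylationArraySet:
    """Generate a two-channel methylation array set with planted effects.

    Planted loci carry their gene's ``delta_beta`` in the tumor columns of
    the gene's group; the remaining probes are decoys with a constant
    baseline (expected delta 0) plus noise.
    """
    rng = np.random.default_rng(params.seed)
    design = params.design()
    n_samples = len(design.table)

    rows, probe_ids, gene_symbols, locus_ids = [], [], [], []
    locus_counter = 0
    for gene in params.planted_genes:
        for _ in range(gene.n_cpg_loci):
            locus_counter += 1
            rows.append(_beta_row(gene, design))
            probe_ids.append(f"cg{locus_counter:08d}")
            gene_symbols.append(gene.gene_symbol)
            locus_ids.append(f"cg{locus_counter:08d}")
    n_decoys = params.n_cpg_probes - locus_counter
    if n_decoys:
        baselines = rng.uniform(0.1, 0.9, size=n_decoys)
        for k in range(n_decoys):
            locus_counter += 1
            rows.append(np.full(n_samples, baselines[k]))
            probe_ids.append(f"cg{locus_counter:08d}")
            gene_symbols.append(f"BG{locus_counter:06d}")
            locus_ids.append(f"cg{locus_counter:08d}")

    beta = np.vstack(rows)
    if params.noise_sd_beta > 0:
        beta = beta + rng.normal(0.0, params.noise_sd_beta, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)

    scale, mu, sd = params.intensity_scale, params.background_mean, params.background_sd

    def bg(shape):
        if sd == 0:
            return np.full(shape, mu)
        return np.clip(rng.normal(mu, sd, size=shape), 0.0, None)

    meth = scale * beta + bg(beta.shape)
    unmeth = scale * (1.0 - beta) + bg(beta.shape)
    controls = bg((params.n_negative_controls, n_samples))

    cols = design.sample_ids
    annotation = pd.DataFrame(
        {"gene_symbol": gene_symbols, "locus_id": locus_ids}, index=pd.Index(probe_ids)
    )
    return MethylationArraySet(
        meth=pd.DataFrame(meth, index=probe_ids, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=probe_ids, columns=cols),
        negative_controls=pd.DataFrame(
            controls, index=[f"neg{i:04d}" for i in range(params.n_negative_controls)], columns=cols
        ),
        annotation=annotation,
    )


def generate_expression_set(params: SimulationParams) -> ExpressionMatrix:
    """Generate a single-channel expression matrix with planted fold changes.

    Planted genes get one probe each whose tumor/normal linear ratio is
    2**log2_fc in expectation; decoy probes are centered on ratio 1.  Noise
    is Gaussian on the log2 scale (log-normal on the linear scale).
    """
    rng = np.random.default_rng(params.seed + 1)
    design = params.design()
    n_samples = len(design.table)

    rows, probe_ids, gene_symbols = [], [], []
    for i, gene in enumerate(params.planted_genes, start=1):
        rows.append(_log2_expr_row(gene, design))
        probe_ids.append(f"ILMN_{i:07d}")
        gene_symbols.append(gene.gene_symbol)
    n_decoys = params.n_expr_probes - len(params.planted_genes)
    if n_decoys:
        baselines = rng.uniform(6.0, 12.0, size=n_decoys)
        for k in range(n_decoys):
            i = len(params.planted_genes) + k + 1
            rows.append(np.full(n_samples, baselines[k]))
            probe_ids.append(f"ILMN_{i:07d}")
            gene_symbols.append(f"BGX{i:06d}")

    log2sig = np.vstack(rows)
    if params.noise_sd_log2_expr > 0:
        log2sig = log2sig + rng.normal(0.0, params.noise_sd_log2_expr, size=log2sig.shape)

    cols = design.sample_ids
    signal = pd.DataFrame(2.0 ** log2sig, index=probe_ids, columns=cols)
    detp = pd.DataFrame(
        np.full(log2sig.shape, params.detection_p_expressed), index=probe_ids, columns=cols
    )
    annotation = pd.DataFrame({"gene_symbol": gene_symbols}, index=pd.Index(probe_ids))
    return ExpressionMatrix(signal=signal, detection_p=detp, annotation=annotation, state="raw")


def _signed_fc_to_log2(fc: float) -> float:
    """Signed fold change (|FC| >= 1) to signed log2 ratio."""
    if abs(fc) < 1:
        raise InputError("signed fold change must have magnitude >= 1")
    return math.log2(fc) if fc > 0 else -math.log2(-fc)


def table1_planted_genes() -> list[PlantedGene]:
    """The packaged 19-gene table as planted effects.

    The first nine genes (table order) carry two CpG loci, the rest one —
    28 loci across 19 genes.
    """
    table = load_integrated_genes()
    planted = []
    for i, row in enumerate(table.itertuples(index=False)):
        planted.append(
            PlantedGene(
                gene_symbol=row.gene,
                group=row.group,
                delta_beta=float(row.delta),
                log2_fc=_signed_fc_to_log2(float(row.fold_change)),
                n_cpg_loci=2 if i < 9 else 1,
            )
        )
    return planted


def _complements(gene: PlantedGene) -> list[PlantedGene]:
    """Mirror genes that keep every array column a permutation of the others.

    ``CMETH_<g>`` mirrors the methylation effect (flat expression) and
    ``CEXPR_<g>`` mirrors the expression effect (flat methylation).  Both are
    discarded by the negative-correlation step because their other data type
    shows no change.
    """
    out = []
    if gene.delta_beta != 0:
        out.append(
            PlantedGene(
                gene_symbol=f"CMETH_{gene.gene_symbol}",
                group=gene.group,
                delta_beta=-gene.delta_beta,
                log2_fc=0.0,
                n_cpg_loci=gene.n_cpg_loci,
                baseline_beta=gene.beta_normal + gene.delta_beta,
                baseline_log2_expr=gene.baseline_log2_expr,
            )
        )
    if gene.log2_fc != 0:
        out.append(
            PlantedGene(
                gene_symbol=f"CEXPR_{gene.gene_symbol}",
                group=gene.group,
                delta_beta=0.0,
                log2_fc=-gene.log2_fc,
                n_cpg_loci=1,
                baseline_beta=0.5,
                baseline_log2_expr=gene.baseline_log2_expr + gene.log2_fc,
            )
        )
    return out


def decoy_genes(n: int, seed: int) -> list[PlantedGene]:
    """Sub-threshold decoy genes in mirror pairs.

    Effects stay clear of the selection thresholds (|delta| < 0.15,
    |FC| < 1.7); consecutive decoys mirror each other so the column-
    permutation property of the fixture is preserved.  An odd trailing decoy
    is flat.
    """
    rng = np.random.default_rng(seed)
    out: list[PlantedGene] = []
    for i in range(0, n - 1, 2):
        delta = float(rng.uniform(0.02, 0.14)) * (1 if rng.random() < 0.5 else -1)
        fc_mag = float(rng.uniform(1.05, 1.65))
        log2_fc = math.log2(fc_mag) * (1 if rng.random() < 0.5 else -1)
        group = GROUPS[(i // 2) % 2]
        base_expr = float(rng.uniform(6.0, 12.0))
        a = PlantedGene(
            gene_symbol=f"DEC{i + 1:05d}",
            group=group,
            delta_beta=delta,
            log2_fc=log2_fc,
            baseline_log2_expr=base_expr,
        )
        b = PlantedGene(
            gene_symbol=f"DEC{i + 2:05d}",
            group=group,
            delta_beta=-delta,
            log2_fc=-log2_fc,
            baseline_beta=a.beta_normal + delta,
            baseline_log2_expr=base_expr + log2_fc,
        )
        out.extend([a, b])
    if len(out) < n:
        out.append(
            PlantedGene(
                gene_symbol=f"DEC{n:05d}", group="cancer", delta_beta=0.0, log2_fc=0.0
            )
        )
    return out


def fixture_from_table1(
    decoys: int = 0,
    seed: int = 0,
    noise_sd_beta: float = 0.0,
    background_sd: float = 0.0,
) -> tuple[MethylationArraySet, ExpressionMatrix, SampleDesign]:
    """Deterministic fixture planting the packaged 19-gene table exactly.

    With the default zero noise the pipeline recovers every printed delta
    and fold change to machine precision, so genes sitting exactly on the
    inclusive thresholds are selected deterministically.  ``decoys``
    sub-threshold genes (|delta| < 0.15, |FC| < 1.7) are added on top.
    """
    table_genes = table1_planted_genes()
    complements: list[PlantedGene] = []
    for gene in table_genes:
        complements += _complements(gene)
    # decoys arrive in mirror pairs already, so only table genes need complements
    planted = table_genes + decoy_genes(decoys, seed=seed + 101) + complements
    n_loci = sum(g.n_cpg_loci for g in planted)
    params = SimulationParams(
        planted_genes=tuple(planted),
        n_cpg_probes=n_loci,
        n_expr_probes=len(planted),
        noise_sd_beta=noise_sd_beta,
        noise_sd_log2_expr=0.0,
        background_sd=background_sd,
        seed=seed,
    )
    meth = generate_methylation_set(params)
    expr = generate_expression_set(params)
    return meth, expr, params.design()
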