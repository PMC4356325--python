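"""Synthetic-data generator: planted-effect recovery, determinism, fixture."""

import numpy as np
import pandas as pd
import pytest

from methexp.containers import InputError
from methexp.expression import process_expression_matrix, signed_fold_change
from methexp.methylation import betas_from_arrayset
from methexp.simulate import (
    PlantedGene,
    SimulationParams,
    fixture_from_table1,
    generate_expression_set,
    generate_methylation_set,
    table1_planted_genes,
)


def small_params(**kw):
    defaults = dict(
        n_cpg_probes=50,
        n_expr_probes=60,
        n_negative_controls=50,
        noise_sd_beta=0.0,
        noise_sd_log2_expr=0.0,
        background_sd=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


def empirical_delta(meth_set, design, gene, group):
    betas = betas_from_arrayset(meth_set)
    probes = meth_set.annotation.index[meth_set.annotation["gene_symbol"] == gene]
    tumor = design.samples(group=group, tissue="tumor")
    normal = design.samples(group=group, tissue="normal")
    b = betas.beta.loc[probes]
    return float((b[tumor].mean(axis=1) - b[normal].mean(axis=1)).mean())


class TestMethylationGenerator:
    def test_noise_free_delta_recovered_exactly(self):
        gene = PlantedGene("PPP1R3C", "cancer", delta_beta=0.22, log2_fc=-2.0)
        params = small_params(planted_genes=(gene,))
        meth = generate_methylation_set(params)
        delta = empirical_delta(meth, params.design(), "PPP1R3C", "cancer")
        assert delta == pytest.approx(0.22, abs=1e-12)

    def test_no_planted_genes_gives_null_deltas(self):
        params = small_params()
        meth = generate_methylation_set(params)
        design = params.design()
        betas = betas_from_arrayset(meth)
        tumor = design.samples(tissue="tumor")
        normal = design.samples(tissue="normal")
        deltas = betas.beta[tumor].mean(axis=1) - betas.beta[normal].mean(axis=1)
        np.testing.assert_allclose(deltas, 0.0, atol=1e-12)

    def test_same_seed_reproduces_bytes(self):
        params = small_params(noise_sd_beta=0.05, background_sd=10.0)
        a = generate_methylation_set(params)
        b = generate_methylation_set(params)
        assert a.meth.equals(b.meth) and a.unmeth.equals(b.unmeth)
        assert a.negative_controls.equals(b.negative_controls)

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(InputError, match="outside"):
            PlantedGene("X", "cancer", delta_beta=0.8, log2_fc=0.0, baseline_beta=0.5)

    def test_noise_recovery_improves_as_noise_shrinks(self):
        gene = PlantedGene("G1", "cancer", delta_beta=0.3, log2_fc=1.0)
        errors = []
        for sd in (0.2, 0.02):
            reps = []
            for seed in range(8):
                params = small_params(planted_genes=(gene,), noise_sd_beta=sd, seed=seed)
                meth = generate_methylation_set(params)
                reps.append(
                    abs(empirical_delta(meth, params.design(), "G1", "cancer") - 0.3)
                )
            errors.append(np.mean(reps))
        assert errors[1] < errors[0]


class TestExpressionGenerator:
    def test_noise_free_signed_fc_recovered(self):
        gene = PlantedGene("PPP1R3C", "cancer", delta_beta=0.22, log2_fc=-np.log2(6.18))
        params = small_params(planted_genes=(gene,))
        expr = generate_expression_set(params)
        design = params.design()
        probe = expr.annotation.index[expr.annotation["gene_symbol"] == "PPP1R3C"][0]
        t = expr.signal.loc[probe, design.samples(group="cancer", tissue="tumor")].mean()
        n = expr.signal.loc[probe, design.samples(group="cancer", tissue="normal")].mean()
        assert signed_fold_change(t, n) == pytest.approx(-6.18, rel=1e-12)

    def test_null_effect_gives_unit_fold_change(self):
        gene = PlantedGene("FLAT", "cancer", delta_beta=0.0, log2_fc=0.0)
        params = small_params(planted_genes=(gene,))
        expr = generate_expression_set(params)
        design = params.design()
        t = expr.signal.iloc[0][design.samples(group="cancer", tissue="tumor")].mean()
        n = expr.signal.iloc[0][design.samples(group="cancer", tissue="normal")].mean()
        assert signed_fold_change(t, n) == pytest.approx(1.0)

    def test_same_seed_reproduces_bytes(self):
        params = small_params(noise_sd_log2_expr=0.2)
        a = generate_expression_set(params)
        b = generate_expression_set(params)
        assert a.signal.equals(b.signal)


class TestTable1Fixture:
    def test_planted_genes_match_packaged_table(self):
        genes = {g.gene_symbol: g for g in table1_planted_genes()}
        assert len(genes) == 19
        plod2 = genes["PLOD2"]
        assert plod2.delta_beta == pytest.approx(-0.25)
        assert 2.0 ** plod2.log2_fc == pytest.approx(2.66)
        assert genes["PPP1R3C"].delta_beta == pytest.approx(0.22)
        assert sum(g.n_cpg_loci for g in genes.values()) == 28

    def test_fixture_columns_are_permutations(self):
        """The mirror construction makes quantile normalization an exact no-op."""
        meth, expr, design = fixture_from_table1(decoys=10, seed=0)
        betas = betas_from_arrayset(meth)
        sorted_beta = np.sort(betas.beta.values, axis=0)
        for j in range(1, sorted_beta.shape[1]):
            np.testing.assert_allclose(sorted_beta[:, j], sorted_beta[:, 0], atol=1e-12)
        sorted_expr = np.sort(np.log2(expr.signal.values), axis=0)
        for j in range(1, sorted_expr.shape[1]):
            np.testing.assert_allclose(sorted_expr[:, j], sorted_expr[:, 0], atol=1e-12)

    def test_decoys_below_thresholds(self):
        meth, expr, design = fixture_from_table1(decoys=30, seed=2)
        betas = betas_from_arrayset(meth)
        expr_n, _ = process_expression_matrix(expr)
        for group in ("cancer", "pre-cancer"):
            tumor = design.samples(group=group, tissue="tumor")
            normal = design.samples(group=group, tissue="normal")
            decoy_probes = meth.annotation.index[
                meth.annotation["gene_symbol"].str.startswith("DEC")
            ]
            deltas = (
                betas.beta.loc[decoy_probes, tumor].mean(axis=1)
                - betas.beta.loc[decoy_probes, normal].mean(axis=1)
            )
            assert (deltas.abs() < 0.15).all()
            lin = expr_n.linear
            decoy_expr = expr_n.annotation.index[
                expr_n.annotation["gene_symbol"].str.startswith("DEC")
            ]
            for probe in decoy_expr:
                fc = signed_fold_change(
                    lin.loc[probe, tumor].mean(), lin.loc[probe, normal].mean()
                )
                assert abs(fc) < 1.7

    def test_fixture_determinism(self):
        a = fixture_from_table1(decoys=6, seed=9)
        b = fixture_from_table1(decoys=6, seed=9)
        assert a[0].meth.equals(b[0].meth)
        assert a[1].signal.equals(b[1].signal)
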