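"""Gene-level integration: pairing, negative-correlation selection,
per-patient consistency filtering and the selection report."""

import numpy as np
import pandas as pd
import pytest

from methexp.containers import InputError
from methexp.expression import process_expression_matrix
from methexp.integration import (
    IntegrationThresholds,
    build_selection_report,
    consistency_filter,
    integrate_profiles,
    map_loci_to_genes,
    select_negative_pairs,
)
from methexp.methylation import betas_from_arrayset, process_beta_matrix
from methexp.simulate import fixture_from_table1


def meth_calls(rows):
    return pd.DataFrame(
        rows, columns=["locus_id", "gene_symbol", "delta", "status"]
    ).set_index(pd.Index([f"cg{i}" for i in range(len(rows))]))


def expr_calls(rows):
    return pd.DataFrame(
        rows, columns=["gene_symbol", "signed_fc", "log2_fc", "t_p", "bh_q", "status"]
    ).set_index(pd.Index([f"ILMN_{i}" for i in range(len(rows))]))


class TestMapLociToGenes:
    def test_direct_join(self):
        pairs, log = map_loci_to_genes(
            meth_calls([["L1", "geneA", 0.3, "hyper"]]),
            expr_calls([["geneA", -3.0, -1.58, 0.1, 0.1, "down"]]),
        )
        assert len(pairs) == 1 and log.pairs_total == 1

    def test_unmatched_locus_dropped_and_logged(self):
        pairs, log = map_loci_to_genes(
            meth_calls([["L1", "geneA", 0.3, "hyper"], ["L2", "geneB", 0.3, "hyper"]]),
            expr_calls([["geneA", -3.0, -1.58, 0.1, 0.1, "down"]]),
        )
        assert len(pairs) == 1
        assert log.loci_without_expression == 1

    def test_join_cardinality_two_loci_one_probe(self):
        pairs, _ = map_loci_to_genes(
            meth_calls(
                [["L1", "geneA", 0.3, "hyper"], ["L2", "geneA", 0.25, "hyper"]]
            ),
            expr_calls([["geneA", -3.0, -1.58, 0.1, 0.1, "down"]]),
        )
        assert len(pairs) == 2
        assert set(pairs["gene_symbol"]) == {"geneA"}

    def test_empty_overlap_raises_diagnostic(self):
        with pytest.raises(InputError, match="no gene symbols shared"):
            map_loci_to_genes(
                meth_calls([["L1", "geneA", 0.3, "hyper"]]),
                expr_calls([["geneB", -3.0, -1.58, 0.1, 0.1, "down"]]),
            )


class TestSelectNegativePairs:
    def build_pairs(self, combos):
        rows = []
        for i, (ms, xs) in enumerate(combos):
            rows.append(
                {
                    "meth_probe_id": f"cg{i}",
                    "locus_id": f"L{i}",
                    "gene_symbol": f"g{i}",
                    "delta": 0.22 if ms == "hyper" else -0.25,
                    "status_meth": ms,
                    "expr_probe_id": f"P{i}",
                    "signed_fc": -6.18 if xs == "down" else 2.66,
                    "log2_fc": -2.6 if xs == "down" else 1.4,
                    "status_expr": xs,
                }
            )
        return pd.DataFrame(rows)

    def test_sign_opposed_combinations_kept(self):
        pairs = self.build_pairs([("hyper", "down"), ("hypo", "up")])
        out = select_negative_pairs(pairs)
        assert list(out["category"]) == ["down_by_hyper", "up_by_hypo"]

    def test_concordant_and_null_combinations_discarded(self):
        pairs = self.build_pairs(
            [("hyper", "up"), ("hypo", "down"), ("none", "down"), ("hyper", "none")]
        )
        assert select_negative_pairs(pairs).empty


class TestConsistencyFilter:
    def frame(self, values, patients=("P1", "P2")):
        return pd.DataFrame(values, columns=patients)

    def test_concordant_patients_kept(self):
        deltas = self.frame([[0.25, 0.20]], ["P1", "P2"]).set_index(pd.Index(["g"]))
        fcs = self.frame([[-3.0, -2.5]], ["P1", "P2"]).set_index(pd.Index(["g"]))
        cats = pd.Series({"g": "down_by_hyper"})
        kept, removed = consistency_filter(deltas, fcs, cats)
        assert kept == ["g"] and removed == []

    def test_one_unmethylated_patient_removes_gene(self):
        deltas = self.frame([[0.40, 0.01]]).set_index(pd.Index(["g"]))
        fcs = self.frame([[-3.0, -2.5]]).set_index(pd.Index(["g"]))
        kept, removed = consistency_filter(
            deltas, fcs, pd.Series({"g": "down_by_hyper"})
        )
        assert kept == [] and removed == ["g"]

    def test_discordant_fc_signs_remove_gene(self):
        deltas = self.frame([[0.25, 0.25]]).set_index(pd.Index(["g"]))
        fcs = self.frame([[-3.0, 2.5]]).set_index(pd.Index(["g"]))
        kept, removed = consistency_filter(
            deltas, fcs, pd.Series({"g": "down_by_hyper"})
        )
        assert removed == ["g"]

    def test_missing_patient_data_removes_gene(self):
        deltas = self.frame([[0.25, np.nan]]).set_index(pd.Index(["g"]))
        fcs = self.frame([[-3.0, -2.5]]).set_index(pd.Index(["g"]))
        kept, removed = consistency_filter(
            deltas, fcs, pd.Series({"g": "down_by_hyper"})
        )
        assert removed == ["g"]


class TestSelectionOnFixture:
    def test_table1_counts_and_membership(self, table1_selection, table1_fixture):
        records, report, _ = table1_selection
        assert report.total_genes == 19
        assert report.counts == {
            "cancer:down_by_hyper": 9,
            "cancer:up_by_hypo": 4,
            "pre-cancer:down_by_hyper": 5,
            "pre-cancer:up_by_hypo": 1,
        }
        meth, _, _ = table1_fixture
        planted = {
            g
            for g in meth.annotation["gene_symbol"]
            if not g.startswith(("DEC", "CMETH_", "CEXPR_"))
        }
        assert set(records["gene_symbol"]) == planted

    def test_category_sign_invariants_hold(self, table1_selection):
        records, _, _ = table1_selection
        hyper = records[records["category"] == "down_by_hyper"]
        hypo = records[records["category"] == "up_by_hypo"]
        assert (hyper["delta"] >= 0.2).all() and (hyper["signed_fc"] <= -2).all()
        assert (hypo["delta"] <= -0.2).all() and (hypo["signed_fc"] >= 2).all()

    def test_selection_monotone_in_thresholds(self, table1_fixture):
        meth, expr, design = table1_fixture
        betas, _ = process_beta_matrix(betas_from_arrayset(meth))
        normalized, _ = process_expression_matrix(expr)
        base, _, _ = integrate_profiles(betas, meth.annotation, normalized, design)
        stricter, _, _ = integrate_profiles(
            betas,
            meth.annotation,
            normalized,
            design,
            thresholds=IntegrationThresholds(delta_threshold=0.22, fc_threshold=2.5),
        )
        assert set(stricter["gene_symbol"]) <= set(base["gene_symbol"])
        assert len(stricter) < len(base)

    def test_empty_records_report(self):
        report = build_selection_report(pd.DataFrame())
        assert report.total_genes == 0 and report.total_loci == 0
        assert all(v == 0 for v in report.counts.values())
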