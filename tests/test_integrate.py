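"""Integration cascade: ranking, filters, anti-correlation, robust selection."""

import numpy as np
import pandas as pd
import pytest

from mirnet.containers import (
    DETable,
    ExpressionMatrix,
    FamilyRegistry,
    MirnetError,
    SampleDesign,
    TargetPredictionTable,
    TransformState,
)
from mirnet.integrate import (
    MiRFamilyRecord,
    NetworkEdge,
    anti_correlated_targets,
    build_family_records,
    conservation_filter,
    expression_share,
    export_network,
    filter_targets,
    select_robust_families,
    select_top_expressed,
)

STAGES = ["1D", "1W", "8W"]


def _expr(means: dict[str, float]) -> ExpressionMatrix:
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "condition": ["sham", "MI"],
                "stage": ["1D", "1D"],
                "replicate": [1, 1],
            }
        )
    )
    df = pd.DataFrame({"a": means, "b": means})
    return ExpressionMatrix(df, design, "miRNA", TransformState.LINEAR)


class TestExpressionShare:
    def test_k1(self):
        assert expression_share(_expr({"x": 90.0, "y": 9.0, "z": 1.0}), 1) == pytest.approx(0.9)

    def test_k_equals_n(self):
        assert expression_share(_expr({"x": 90.0, "y": 9.0, "z": 1.0}), 3) == pytest.approx(1.0)

    def test_k_nonpositive_rejected(self):
        with pytest.raises(MirnetError, match="positive"):
            expression_share(_expr({"x": 1.0}), 0)

    def test_requires_linear_state(self):
        expr = _expr({"x": 1.0, "y": 2.0})
        expr.transform_state = TransformState.LOG2P1
        with pytest.raises(MirnetError, match="transform state"):
            expression_share(expr, 1)


class TestFilterTargets:
    def _table(self, rows):
        return TargetPredictionTable(
            pd.DataFrame(
                rows,
                columns=[
                    "family_id",
                    "gene_id",
                    "wcsp",
                    "seed_sites",
                    "conserved_mouse",
                    "conserved_rat",
                    "conserved_human",
                    "conserved_site",
                ],
            )
        )

    def test_wcsp_boundary_strict(self):
        t = self._table(
            [
                ("f", "g1", 50.0, 1, True, True, True, True),
                ("f", "g2", 50.1, 1, True, True, True, True),
            ]
        )
        kept = filter_targets(t).table
        assert list(kept["gene_id"]) == ["g2"]

    def test_seed_site_requirement(self):
        t = self._table(
            [
                ("f", "g1", 80.0, 0, True, True, True, True),
                ("f", "g2", 80.0, 1, True, True, True, True),
            ]
        )
        assert list(filter_targets(t).table["gene_id"]) == ["g2"]

    def test_constructed_counts(self):
        rows = []
        # 4 rows pass (wcsp>50 and seeds>=1); 6 fail on one criterion
        for i, (wcsp, seeds) in enumerate(
            [(60, 1), (75, 2), (51, 1), (99, 3), (50, 1), (10, 1), (45, 2), (70, 0), (30, 0), (50, 0)]
        ):
            rows.append(("f", f"g{i}", float(wcsp), seeds, True, True, True, True))
        assert len(filter_targets(self._table(rows)).table) == 4


class TestConservationFilter:
    def _records(self, conserved):
        return {
            "f": MiRFamilyRecord("f", ["m"], set(conserved), {s: "up" for s in STAGES})
        }

    def test_all_three_retained(self):
        assert conservation_filter({"f"}, self._records({"mouse", "rat", "human"})) == {"f"}

    def test_two_species_excluded(self):
        assert conservation_filter({"f"}, self._records({"mouse", "rat"})) == set()

    def test_empty_input(self):
        assert conservation_filter(set(), {}) == set()


def _de_table(records: list[tuple[str, str, str, float]], alpha=0.05) -> DETable:
    rows = []
    for feature, stage, direction, log2fc in records:
        rows.append(
            {
                "feature_id": feature,
                "stage": stage,
                "mean_sham": 1.0,
                "mean_mi": 2.0**log2fc,
                "log2fc": log2fc,
                "fold_change": 2.0**log2fc if log2fc >= 0 else -(2.0 ** (-log2fc)),
                "p_raw": 0.001 if direction != "ns" else 0.9,
                "p_adj": 0.002 if direction != "ns" else 0.95,
                "direction": direction,
            }
        )
    return DETable(pd.DataFrame(rows), alpha=alpha)


def _predictions(rows) -> TargetPredictionTable:
    return TargetPredictionTable(
        pd.DataFrame(
            rows,
            columns=[
                "family_id",
                "gene_id",
                "wcsp",
                "seed_sites",
                "conserved_mouse",
                "conserved_rat",
                "conserved_human",
                "conserved_site",
            ],
        )
    )


class TestAntiCorrelatedTargets:
    def setup_method(self):
        self.family = MiRFamilyRecord(
            "fam", ["m1"], {"mouse", "rat", "human"}, {"1D": "up", "1W": "ns"}
        )
        self.degs = _de_table(
            [("gA", "1D", "down", -2.0), ("gB", "1D", "up", 2.0), ("gC", "1D", "down", -1.5)]
        )
        self.pred = _predictions(
            [
                ("fam", "gA", 80.0, 1, True, True, True, True),
                ("fam", "gB", 80.0, 1, True, True, True, True),
            ]
        )

    def test_opposite_direction_emits_edge(self):
        edges = anti_correlated_targets(self.family, self.degs, self.pred, "1D")
        assert [(e.gene_id, e.gene_direction) for e in edges] == [("gA", "down")]

    def test_same_direction_no_edge(self):
        edges = anti_correlated_targets(self.family, self.degs, self.pred, "1D")
        assert "gB" not in {e.gene_id for e in edges}

    def test_unpredicted_gene_no_edge(self):
        edges = anti_correlated_targets(self.family, self.degs, self.pred, "1D")
        assert "gC" not in {e.gene_id for e in edges}  # down-DEG but not predicted

    def test_ns_family_empty(self):
        assert anti_correlated_targets(self.family, self.degs, self.pred, "1W") == []

    def test_edge_invariant_enforced(self):
        with pytest.raises(MirnetError, match="anti-correlated"):
            NetworkEdge("f", "g", "1D", "up", "up", True)
        with pytest.raises(MirnetError, match="non-ns"):
            NetworkEdge("f", "g", "1D", "ns", "down", True)


def _synthetic_selection_inputs(conserved_counts: dict[str, list[int]]):
    """Build a one-family-per-entry scenario with given per-stage conserved
    target counts; every family is DE down at all stages and top-ranked."""
    mirnas = [f"m_{fam}" for fam in conserved_counts]
    demir_rows = [
        (m, s, "down", -2.0) for m in mirnas for s in STAGES
    ]
    demirs = _de_table(demir_rows)
    gene_idx = 0
    pred_rows, deg_rows = [], []
    for fam, counts in conserved_counts.items():
        for stage, n in zip(STAGES, counts):
            for _ in range(n):
                g = f"g{gene_idx}"
                gene_idx += 1
                pred_rows.append((fam, g, 90.0, 1, True, True, True, True))
                deg_rows.append((g, stage, "up", 2.0))
    # fill other stages as ns for listed genes
    listed = {r[0] for r in deg_rows}
    for g in listed:
        for s in STAGES:
            if not any(r[0] == g and r[1] == s for r in deg_rows):
                deg_rows.append((g, s, "ns", 0.0))
    degs = _de_table(deg_rows)
    predictions = _predictions(pred_rows)
    registry = FamilyRegistry(
        pd.DataFrame(
            {
                "mirna_id": mirnas,
                "family_id": list(conserved_counts),
                "conserved_mouse": True,
                "conserved_rat": True,
                "conserved_human": True,
            }
        )
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "condition": ["sham", "MI"] * 3,
                "stage": [s for s in STAGES for _ in range(2)],
                "replicate": [1, 1, 1, 1, 1, 1],
            }
        )
    )
    expr = ExpressionMatrix(
        pd.DataFrame(
            {f"s{i}": [1000.0 - 10 * j for j in range(len(mirnas))] for i in range(6)},
            index=mirnas,
        ),
        design,
        "miRNA",
        TransformState.LINEAR,
    )
    return demirs, degs, expr, predictions, registry


class TestSelectRobustFamilies:
    def test_min_target_rule(self):
        demirs, degs, expr, pred, reg = _synthetic_selection_inputs(
            {"ok": [12, 15, 11], "short": [12, 9, 11]}
        )
        result = select_robust_families(demirs, degs, expr, pred, reg, k=50, min_targets=10)
        assert result.selected_families == ["ok"]
        assert result.eliminated["short"] == "min_conserved_targets"

    def test_cascade_counts_non_increasing(self):
        demirs, degs, expr, pred, reg = _synthetic_selection_inputs(
            {"a": [12, 12, 12], "b": [1, 1, 1]}
        )
        result = select_robust_families(demirs, degs, expr, pred, reg)
        counts = [n for _, n in result.cascade]
        assert counts == sorted(counts, reverse=True)

    def test_prediction_row_order_invariance(self, bundle, pipeline_result):
        from mirnet import io
        from mirnet.normalize import filter_all_zero, rpm

        design = io.read_design(bundle.design)
        pred = io.read_predictions(bundle.targets)
        shuffled = TargetPredictionTable(
            pred.table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        mirna_counts = io.read_counts(bundle.mirna_counts, design, "miRNA")
        expr = filter_all_zero(rpm(mirna_counts))
        reg = io.read_families(bundle.families)
        base = pipeline_result.integration
        again = select_robust_families(
            pipeline_result.demir_table, pipeline_result.deg_table, expr, shuffled, reg
        )
        assert again.selected_families == base.selected_families
        assert again.cascade == base.cascade

    def test_full_recovery_and_decoy_attribution(self, bundle, pipeline_result):
        truth = bundle.truth
        result = pipeline_result.integration
        assert result.selected_families == sorted(truth.planted_families)
        for fam, expected_filter in truth.decoy_families.items():
            assert result.eliminated[fam] == expected_filter, fam

    def test_every_edge_anti_correlated(self, pipeline_result):
        for edges in pipeline_result.integration.edges_by_stage.values():
            for e in edges:
                assert e.mirna_direction != e.gene_direction
                assert "ns" not in (e.mirna_direction, e.gene_direction)


class TestSelectTopExpressed:
    def test_k_larger_than_demir_count_keeps_all(self):
        demirs, degs, expr, pred, reg = _synthetic_selection_inputs({"a": [1, 1, 1]})
        fams = select_top_expressed(demirs, expr, reg, k=999)
        assert fams == {"a"}

    def test_low_abundance_decoy_outside_top_k(self, bundle, pipeline_result):
        truth = bundle.truth
        fam = next(f for f, m in truth.decoy_families.items() if m == "top_k")
        assert pipeline_result.integration.eliminated[fam] == "top_k"


class TestExportNetwork:
    def test_empty_result_header_only(self, tmp_path):
        from mirnet.integrate import IntegrationResult

        empty = IntegrationResult(
            selected_families=[],
            edges_by_stage={},
            cascade=[(s, 0) for s in ("f1", "f2")],
            eliminated={},
            top_share=0.0,
        )
        paths = export_network(empty, tmp_path)
        edges = pd.read_csv(paths["edges"], sep="\t")
        assert len(edges) == 0 and "family_id" in edges.columns

    def test_edge_list_round_trip(self, pipeline_result, tmp_path):
        result = pipeline_result.integration
        paths = export_network(result, tmp_path)
        loaded = pd.read_csv(paths["edges"], sep="\t")
        assert len(loaded) == sum(len(v) for v in result.edges_by_stage.values())
        rebuilt = {
            (r.stage, r.family_id, r.gene_id, r.mirna_direction, r.gene_direction)
            for r in loaded.itertuples()
        }
        original = {
            (e.stage, e.family_id, e.gene_id, e.mirna_direction, e.gene_direction)
            for es in result.edges_by_stage.values()
            for e in es
        }
        assert rebuilt == original

    def test_selected_networks_as_graph(self, pipeline_result):
        g = pipeline_result.integration.to_networkx()
        fams = {n for n, d in g.nodes(data=True) if d["kind"] == "family"}
        assert fams == set(pipeline_result.integration.selected_families)
        assert all(g.degree(f) >= 10 for f in fams)
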