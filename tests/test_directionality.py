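"""Directed edge tables and cortical/subcortical summaries."""

import numpy as np
import pandas as pd
import pytest

from restcause import (
    AggregateScores,
    CausalSelection,
    aggregate_matrices,
    build_edge_table,
    dominant_source_truth,
    fit_all_subjects,
    generate_var_timeseries,
    select_targets,
    select_top,
    summarize_by_class,
)
from restcause.directionality import RegionLabelMap
from restcause.fixtures import (
    affected_edge_table,
    causal_scores,
    load_causal_components,
    load_region_labels,
)


def scores_from_matrix(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[0]
    return AggregateScores(
        agg_matrix=matrix,
        scores=(matrix - np.diag(np.diag(matrix))).sum(axis=1),
        component_ids=ids or list(range(1, k + 1)),
        approach="absolute",
    )


class TestSelectTargets:
    def test_hand_checkable_threshold(self):
        # source row [., 10, 8.5, 7, 1]: cutoff 8 keeps the first two targets
        m = np.zeros((5, 5))
        m[0, 1:] = [10, 8.5, 7, 1]
        out = select_targets(scores_from_matrix(m), source=1, fraction=0.2)
        assert out == [(2, 10.0), (3, 8.5)]

    def test_single_nonzero_entry_selects_exactly_it(self):
        m = np.zeros((4, 4))
        m[2, 0] = 3.5
        out = select_targets(scores_from_matrix(m), source=3)
        assert out == [(1, 3.5)]

    def test_all_zero_row_warns_and_returns_empty(self):
        m = np.zeros((3, 3))
        m[1, 0] = 1.0
        with pytest.warns(UserWarning, match="all-zero"):
            assert select_targets(scores_from_matrix(m), source=3) == []

    def test_driven_targets_are_recovered(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = dominant_source_truth(6, coupling=0.0, seed=2000 + seed)
            a = truth.true_matrix
            a[0, 1] = a[0, 2] = 0.45  # source 1 drives targets 2 and 3 only
            ts, _ = generate_var_timeseries(20, 1000, 6, truth)
            agg = aggregate_matrices(fit_all_subjects(ts))
            chosen = {t for t, _ in select_targets(agg, source=1, fraction=0.2)}
            hits += int({2, 3} <= chosen)
        assert hits >= 9


class TestBuildEdgeTable:
    def test_full_fraction_lists_every_other_component(self, rng):
        m = np.abs(rng.normal(size=(4, 4))) + 0.1
        agg = scores_from_matrix(m)
        sel = CausalSelection(cutoff=0.0, selected=[2], fraction=1.0, rule="value_threshold")
        table = build_edge_table(sel, agg, fraction=1.0)
        assert sorted(t for _, t, _ in table.edges) == [1, 3, 4]
        for _, t, w in table.edges:
            assert table.per_target_sum[t] == pytest.approx(w)

    def test_per_target_sums_are_self_consistent(self, rng):
        m = np.abs(rng.normal(size=(8, 8)))
        agg = scores_from_matrix(m)
        sel = select_top(agg, fraction=0.5)
        table = build_edge_table(sel, agg, fraction=0.4)
        recomputed: dict[int, float] = {}
        for _, target, w in table.edges:
            recomputed[target] = recomputed.get(target, 0.0) + w
        for t, total in table.per_target_sum.items():
            assert total == pytest.approx(recomputed[t], abs=1e-8)
        assert table.affected == sorted(
            table.per_target_sum, key=lambda t: (-table.per_target_sum[t], t)
        )

    def test_edge_weights_come_straight_from_the_aggregate(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        agg = scores_from_matrix(m)
        sel = select_top(agg, fraction=0.6)
        table = build_edge_table(sel, agg, fraction=0.5)
        ids = agg.component_ids
        for s, t, w in table.edges:
            assert w == agg.agg_matrix[ids.index(s), ids.index(t)]

    def test_empty_selection_rejected(self, rng):
        agg = scores_from_matrix(np.ones((3, 3)))
        sel = CausalSelection(cutoff=0, selected=[], fraction=0.2, rule="value_threshold")
        with pytest.raises(ValueError, match="empty"):
            build_edge_table(sel, agg)


class TestWorkedExampleGrid:
    def test_twenty_eight_affected_networks(self):
        table = affected_edge_table()
        assert len(table.affected) == 28

    def test_middle_temporal_receives_the_most_influence(self):
        table = affected_edge_table()
        assert table.affected[0] == 80

    def test_sources_may_reappear_as_targets(self):
        # the precuneus source (36) influences a distinct precuneus target (112)
        table = affected_edge_table()
        assert (36, 112, 53.09) in table.edges

    def test_wide_layout_round_trips_the_sums(self):
        table = affected_edge_table()
        wide = table.to_wide()
        assert list(wide.index) == table.affected
        assert wide["Sum"].iloc[0] == pytest.approx(table.per_target_sum[80])


class TestSummarizeByClass:
    def test_causal_class_totals_match_known_sums(self):
        frame = load_causal_components()
        labels = load_region_labels()
        summary = summarize_by_class(
            frame["component_id"], labels, scores=causal_scores()
        )
        assert summary.loc["subcortical", "count"] == 6
        assert summary.loc["cortical", "count"] == 6
        assert summary.loc["subcortical", "total_rounded"] == 24903
        assert summary.loc["cortical", "total_rounded"] == 23071

    def test_class_totals_partition_the_grand_total(self):
        summary = summarize_by_class(
            load_causal_components()["component_id"],
            load_region_labels(),
            scores=causal_scores(),
        )
        assert summary["total"].sum() == pytest.approx(causal_scores().sum(), abs=1e-8)

    def test_affected_split_is_24_cortical_4_subcortical(self):
        table = affected_edge_table()
        summary = summarize_by_class(table.affected, load_region_labels())
        assert summary.loc["cortical", "count"] == 24
        assert summary.loc["subcortical", "count"] == 4

    def test_single_class_holds_everything(self):
        labels = RegionLabelMap(
            table=pd.DataFrame(
                {"component_id": [1, 2], "region": ["a", "b"], "class": ["cortical"] * 2}
            )
        )
        summary = summarize_by_class([1, 2], labels, scores={1: 2.0, 2: 3.0})
        assert list(summary.index) == ["cortical"]
        assert summary.loc["cortical", "total"] == 5.0

    def test_missing_labels_are_reported(self):
        labels = load_region_labels()
        with pytest.raises(ValueError, match=r"\[999\]"):
            summarize_by_class([111, 999], labels)
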