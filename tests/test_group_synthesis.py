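"""Group aggregation, hierarchical synthesis and the end-to-end study run."""

import math

import numpy as np
import pytest

from ahpgroup import synthetic_data
from ahpgroup.errors import DesignError
from ahpgroup.judgments import PairwiseMatrix
from ahpgroup.group_synthesis import (
    aggregate_judgments,
    round_half_up,
    run_study,
    synthesize,
)
from ahpgroup.priority_engine import PriorityVector, consistency, principal_eigenvector

from conftest import scenario


def matrix2(a12):
    return PairwiseMatrix(items=("a", "b"), values=np.array([[1.0, a12], [1.0 / a12, 1.0]]))


class TestAggregateJudgments:
    def test_geometric_mean_of_reciprocal_opinions_is_indifference(self):
        agg = aggregate_judgments([matrix2(9.0), matrix2(1 / 9)], method="geometric")
        assert agg.values[0, 1] == pytest.approx(1.0)

    def test_single_respondent_identity(self):
        m = matrix2(3.0)
        for method in ("geometric", "arithmetic"):
            assert np.allclose(aggregate_judgments([m], method).values, m.values)

    def test_arithmetic_mean_repairs_reciprocity(self):
        agg = aggregate_judgments([matrix2(9.0), matrix2(1 / 9)], method="arithmetic")
        up = (9 + 1 / 9) / 2
        assert agg.values[0, 1] == pytest.approx(up)
        assert agg.values[1, 0] == pytest.approx(1 / up)

    def test_geometric_aggregate_of_consistent_stars_stays_consistent(self):
        rng = np.random.default_rng(8)
        mats = []
        items = tuple(f"x{i}" for i in range(5))
        for _ in range(6):
            col = np.concatenate(([1.0], np.exp(rng.normal(0, 0.5, size=4))))
            a = np.outer(col, 1.0 / col)
            np.fill_diagonal(a, 1.0)
            mats.append(PairwiseMatrix(items=items, values=a))
        agg = aggregate_judgments(mats, "geometric")
        rep = consistency(principal_eigenvector(agg))
        assert rep.cr == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_item_sets_rejected(self):
        other = PairwiseMatrix(items=("a", "c"), values=np.array([[1.0, 2.0], [0.5, 1.0]]))
        with pytest.raises(DesignError, match="mismatch"):
            aggregate_judgments([matrix2(2.0), other])


class TestSynthesize:
    @staticmethod
    def pv(weights, items=("x", "y")):
        return PriorityVector(items=items, weights=np.asarray(weights, float),
                              lambda_max=math.nan)

    def test_hand_example(self):
        overall = synthesize(
            {"l1": 0.5, "l2": 0.5},
            {"l1": self.pv([0.2, 0.8]), "l2": self.pv([0.6, 0.4])},
        )
        assert overall.weights == pytest.approx([0.4, 0.6])

    def test_identical_leaf_priorities_are_a_fixed_point(self):
        p = self.pv([0.3, 0.25, 0.45], items=("x", "y", "z"))
        overall = synthesize({"a": 0.7, "b": 0.2, "c": 0.1}, {k: p for k in "abc"})
        assert overall.weights == pytest.approx(p.weights)

    def test_matches_brute_force_double_loop(self, small_study, hierarchy):
        res = run_study(small_study.respondents, small_study.judgments, hierarchy)
        for g, gr in res.groups.items():
            items = gr.overall.items
            for k, item in enumerate(items):
                brute = sum(
                    gr.global_weights[leaf] * gr.leaf_priorities[leaf].weights[j]
                    for leaf in gr.global_weights
                    for j in range(len(items))
                    if gr.leaf_priorities[leaf].items[j] == item
                )
                assert gr.overall.weights[k] == pytest.approx(brute, abs=1e-12)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(DesignError, match="sum"):
            synthesize({"l1": 0.6, "l2": 0.6},
                       {"l1": self.pv([0.5, 0.5]), "l2": self.pv([0.5, 0.5])})

    def test_item_mismatch_rejected(self):
        with pytest.raises(DesignError, match="mismatch"):
            synthesize({"l1": 0.5, "l2": 0.5},
                       {"l1": self.pv([0.5, 0.5]),
                        "l2": self.pv([0.5, 0.5], items=("x", "zzz"))})


class TestRunStudy:
    def test_zero_noise_recovers_truth(self, noise_free_study, hierarchy):
        res = run_study(noise_free_study.respondents, noise_free_study.judgments, hierarchy)
        for g, truth in noise_free_study.truth.items():
            gr = res.groups[g]
            assert gr.overall.weights == pytest.approx(truth.overall.weights, abs=1e-6)
            for node, w in truth.local_weights.items():
                assert gr.local_weights[node] == pytest.approx(w, abs=1e-6)

    def test_single_respondent_group_equals_individual(self, hierarchy):
        cfg = scenario([("physicians", 1)], seed=9, sigma=0.3, discretize=True)
        study = synthetic_data.simulate_study(cfg)
        res = run_study(study.respondents, study.judgments, hierarchy)
        assert res.groups["physicians"].n_respondents == 1
        # aggregation of one respondent is the identity: rerunning with the
        # same single respondent duplicated changes nothing
        doubled_resp = list(study.respondents) * 2
        doubled_resp = [
            type(r)(id=f"{r.id}_{i}", group=r.group)
            for i, r in enumerate(doubled_resp)
        ]
        doubled_judg = [
            type(j)(respondent_id=f"{study.respondents[0].id}_{i}", context=j.context,
                    left=j.left, right=j.right, favored=j.favored, score=j.score)
            for i in range(2)
            for j in study.judgments
        ]
        res2 = run_study(doubled_resp, doubled_judg, hierarchy)
        assert res2.groups["physicians"].overall.weights == pytest.approx(
            res.groups["physicians"].overall.weights, abs=1e-12
        )

    def test_every_block_normalized(self, small_study, hierarchy):
        res = run_study(small_study.respondents, small_study.judgments, hierarchy)
        for gr in res.groups.values():
            assert math.fsum(gr.global_weights.values()) == pytest.approx(1.0, abs=1e-9)
            assert gr.overall.weights.sum() == pytest.approx(1.0, abs=1e-9)
            for pv in gr.leaf_priorities.values():
                assert pv.weights.sum() == pytest.approx(1.0, abs=1e-9)
            for parent, children in hierarchy.sibling_sets().items():
                assert math.fsum(gr.local_weights[c] for c in children) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_duplicating_every_respondent_changes_nothing(self, small_study, hierarchy):
        res = run_study(small_study.respondents, small_study.judgments, hierarchy)
        respondents = list(small_study.respondents) + [
            type(r)(id=f"{r.id}_copy", group=r.group) for r in small_study.respondents
        ]
        judgments = list(small_study.judgments) + [
            type(j)(respondent_id=f"{j.respondent_id}_copy", context=j.context,
                    left=j.left, right=j.right, favored=j.favored, score=j.score)
            for j in small_study.judgments
        ]
        res2 = run_study(respondents, judgments, hierarchy)
        for g in res.groups:
            assert res2.groups[g].overall.weights == pytest.approx(
                res.groups[g].overall.weights, abs=1e-12
            )

    def test_incomplete_respondent_excluded_with_reason(self, small_study, hierarchy):
        drop_rid = small_study.respondents[0].id
        judgments = [
            j for j in small_study.judgments
            if not (j.respondent_id == drop_rid and j.context == "criteria:goal")
        ]
        res = run_study(small_study.respondents, judgments, hierarchy)
        assert [rid for rid, _ in res.excluded] == [drop_rid]
        assert res.groups["patients"].n_respondents == 7
        with pytest.raises(DesignError, match=drop_rid):
            run_study(small_study.respondents, judgments, hierarchy, on_incomplete="error")

    def test_report_is_deterministic(self, small_study, hierarchy):
        a = run_study(small_study.respondents, small_study.judgments, hierarchy).to_json()
        b = run_study(small_study.respondents, small_study.judgments, hierarchy).to_json()
        assert a == b

    def test_tables_shape_and_rounding(self, small_study, hierarchy):
        res = run_study(small_study.respondents, small_study.judgments, hierarchy)
        crit = res.criteria_table(rounded=True)
        assert list(crit.index) == [n.id for n in hierarchy]
        prio = res.priority_table(rounded=True)
        assert prio.shape == (10, 2)
        assert prio.index[0] == "current_care"
        no_base = res.priority_table(drop_baseline=True)
        assert no_base.shape == (9, 2)
        assert no_base.sum(axis=0).values == pytest.approx([1.0, 1.0])


def test_round_half_up_matches_table_convention():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(0.115) == 0.12
    assert round_half_up(0.1049) == 0.10
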