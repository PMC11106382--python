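"""Causal flow, covariate-adjusted group tests, BH-FDR, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcdec.granger_dec import ECMatrix
from fcdec.io_config import CohortManifest
from fcdec.group_stats import (
    abnormal_node_report,
    adjusted_group_test,
    causal_flow,
    fdr_bh,
    spearman_assoc,
)
from fcdec.state_clustering import StateModel

from .oracles import bf_fdr_bh


def _manifest(groups, ages=None, sexes=None):
    n = len(groups)
    return CohortManifest(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": groups,
                "age": ages if ages is not None else [20.0] * n,
                "sex": sexes if sexes is not None else ["M"] * n,
            }
        )
    )


def _state_model(assignments, point_ids, k):
    return StateModel(
        k=k, centroids=np.zeros((k, 2)), assignments=np.asarray(assignments),
        point_ids=point_ids, objective=0.0, objective_trace=np.zeros(1),
    )


class TestCausalFlow:
    def test_single_window_row_and_column_sums(self):
        ec = {"a": [ECMatrix(np.array([[0.0, 2.0], [1.0, 0.0]]), 0, "a")]}
        model = _state_model([1], [("a", 0)], k=1)
        flow = causal_flow(ec, model)
        np.testing.assert_allclose(flow.out_weighted["a"][1], [2.0, 1.0])
        np.testing.assert_allclose(flow.in_weighted["a"][1], [1.0, 2.0])

    def test_zero_matrix_zero_flow(self):
        ec = {"a": [ECMatrix(np.zeros((3, 3)), 0, "a")]}
        flow = causal_flow(ec, _state_model([1], [("a", 0)], k=1))
        np.testing.assert_array_equal(flow.in_weighted["a"][1], 0.0)

    def test_transpose_swaps_in_and_out(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((4, 4))
        np.fill_diagonal(m, 0.0)
        f1 = causal_flow({"a": [ECMatrix(m, 0, "a")]}, _state_model([1], [("a", 0)], 1))
        f2 = causal_flow({"a": [ECMatrix(m.T, 0, "a")]}, _state_model([1], [("a", 0)], 1))
        np.testing.assert_allclose(f1.in_weighted["a"][1], f2.out_weighted["a"][1])

    def test_flow_conservation_total_in_equals_total_out(self):
        rng = np.random.default_rng(1)
        ec = {}
        ids = []
        for s, sid in enumerate(["a", "b"]):
            mats = []
            for w in range(6):
                m = rng.standard_normal((5, 5))
                np.fill_diagonal(m, 0.0)
                mats.append(ECMatrix(m, w, sid))
                ids.append((sid, w))
            ec[sid] = mats
        model = _state_model(rng.integers(1, 3, size=12), ids, k=2)
        flow = causal_flow(ec, model)
        for sid in ec:
            for s in flow.in_weighted[sid]:
                assert flow.in_weighted[sid][s].sum() == pytest.approx(
                    flow.out_weighted[sid][s].sum(), abs=1e-9
                )

    def test_subject_absent_from_state_is_missing(self):
        ec = {"a": [ECMatrix(np.zeros((2, 2)), 0, "a")],
              "b": [ECMatrix(np.zeros((2, 2)), 0, "b")]}
        model = _state_model([1, 2], [("a", 0), ("b", 0)], k=2)
        flow = causal_flow(ec, model)
        assert 2 not in flow.in_weighted["a"] and 1 not in flow.in_weighted["b"]


class TestAdjustedGroupTest:
    def test_identical_groups_give_t_zero_p_one(self):
        man = _manifest(["patient"] * 3 + ["control"] * 3,
                        sexes=["M", "F", "M", "M", "F", "M"])  # ages equal -> dropped
        values = {f"s{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])}
        res = adjusted_group_test(values, man)
        assert res.t == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_constant_covariates_reduce_to_pooled_t(self):
        rng = np.random.default_rng(2)
        man = _manifest(["patient"] * 8 + ["control"] * 8)
        vals = np.r_[rng.normal(1.0, 1.0, 8), rng.normal(0.0, 1.0, 8)]
        res = adjusted_group_test({f"s{i}": v for i, v in enumerate(vals)}, man)
        t_ref, p_ref = stats.ttest_ind(vals[:8], vals[8:], equal_var=True)
        assert res.t == pytest.approx(t_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_power_on_planted_shift(self):
        rng = np.random.default_rng(3)
        hits = 0
        man = _manifest(["patient"] * 20 + ["control"] * 20,
                        ages=list(rng.uniform(15, 30, 40)),
                        sexes=list(rng.choice(["M", "F"], 40)))
        for rep in range(100):
            vals = np.r_[rng.normal(1.0, 0.1, 20), rng.normal(0.0, 0.1, 20)]
            res = adjusted_group_test({f"s{i}": v for i, v in enumerate(vals)}, man)
            hits += res.p < 0.001
        assert hits >= 95

    def test_group_with_too_few_subjects_rejected(self):
        man = _manifest(["patient"] * 2 + ["control"] * 4)
        with pytest.raises(ValueError, match="fewer than 3"):
            adjusted_group_test({f"s{i}": 1.0 * i for i in range(6)}, man)

    def test_collinear_covariate_named(self):
        man = _manifest(["patient"] * 4 + ["control"] * 4,
                        ages=[30, 30, 30, 30, 20, 20, 20, 20])  # age == group indicator
        vals = {f"s{i}": float(i) for i in range(8)}
        with pytest.raises(ValueError, match="age"):
            adjusted_group_test(vals, man)


class TestFdrBH:
    def test_stepup_worked_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.3])[0] == 0.3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_bh(p), bf_fdr_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 25)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert spearman_assoc([1, 2, 3, 4], [4, 3, 2, 1])[0] == -1.0

    def test_rank_difference_formula_example(self):
        rho, _ = spearman_assoc([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)  # 1 - 6*4/(5*24)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_assoc([1, 2, np.nan], [1, 2, 3])


class TestAbnormalNodeReport:
    def _tests_frame(self, p_fdr_by_node):
        rows = []
        for (node, metric), p in p_fdr_by_node.items():
            rows.append({"metric": metric, "node": node, "t": 2.0, "p": p / 2, "p_fdr": p,
                         "mean_patient": 1.0, "mean_control": 0.5, "direction": "increased"})
        return pd.DataFrame(rows)

    def test_no_significant_tests_empty_report(self):
        report = abnormal_node_report(self._tests_frame({(1, "degree"): 0.9, (2, "degree"): 0.5}))
        assert report.empty

    def test_significant_nodes_listed_with_direction(self):
        report = abnormal_node_report(
            self._tests_frame({(1, "degree"): 0.01, (2, "degree"): 0.8, (1, "efficiency"): 0.02})
        )
        assert sorted(report["node"].unique()) == [1]
        assert set(report["direction"]) == {"increased"}

    def test_direction_is_sign_of_mean_difference(self):
        from fcdec.group_stats import TestResult

        up = TestResult("u", 2.0, 0.01, 0.02, mean_patient=2.0, mean_control=1.0)
        down = TestResult("u", -2.0, 0.01, 0.02, mean_patient=1.0, mean_control=2.0)
        assert up.direction == "increased" and down.direction == "decreased"
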