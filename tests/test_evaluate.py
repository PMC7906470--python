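import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_curve

from clusterbn.bn import Dag, cpdag
from clusterbn.evaluate import (Scenario, auc_metrics, crossvalidate,
                                match_groups, partition_metric,
                                run_simulation_study, shd, shd_normalized)
from clusterbn.model import LearnSettings
from clusterbn.simulate import make_split_advantage_data

FAST = LearnSettings(n_bootstrap=10, restarts=1)


def _random_partition(rng, items, max_groups=4):
    labels = rng.integers(0, max_groups, size=len(items))
    out = {}
    for it, lb in zip(items, labels):
        out.setdefault(f"g{lb}", []).append(it)
    return out


class TestPartitionMetric:
    def test_identical_partitions_are_zero(self):
        g = {"A": ["x", "y"], "B": ["z"]}
        assert partition_metric(g, {"Q": ["x", "y"], "R": ["z"]}) == 0.0

    def test_crossed_pairs_value(self):
        got = partition_metric({"A": ["a", "b"], "B": ["c", "d"]},
                               {"A": ["a", "c"], "B": ["b", "d"]})
        assert got == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_lump_vs_singletons_value(self):
        got = partition_metric({"A": list("abcd")},
                               {c: [c] for c in "abcd"})
        assert got == pytest.approx(np.log(4), abs=1e-12)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            partition_metric({"A": ["x"]}, {"A": ["y"]})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_axioms_on_random_partition_triples(self, seed):
        """Identity of indiscernibles, symmetry and triangle inequality."""
        rng = np.random.default_rng(seed)
        items = [f"v{i}" for i in range(8)]
        g1, g2, g3 = (_random_partition(rng, items) for _ in range(3))
        d12 = partition_metric(g1, g2)
        assert partition_metric(g1, g1) == 0.0
        assert d12 == pytest.approx(partition_metric(g2, g1), abs=1e-12)
        assert d12 >= 0
        assert d12 <= partition_metric(g1, g3) + partition_metric(g3, g2) + 1e-9


class TestShd:
    def test_identical_cpdags_zero(self):
        c = cpdag(Dag(list("ABC"), [("A", "B"), ("A", "C")]))
        assert shd(c, c) == 0

    def test_missing_single_arc_is_one(self):
        truth = cpdag(Dag(list("AB"), [("A", "B")]))
        empty = cpdag(Dag(list("AB")))
        assert shd_normalized(empty, truth) == pytest.approx(1.0)

    def test_half_of_undirected_path_missing(self):
        truth = cpdag(Dag(list("ABC"), [("A", "B"), ("B", "C")]))  # A-B-C
        part = cpdag(Dag(list("ABC"), [("A", "B")]))               # A-B
        assert shd_normalized(part, truth) == pytest.approx(0.5)

    def test_orientation_change_counts_one(self):
        coll = cpdag(Dag(list("ABC"), [("A", "C"), ("B", "C")]))
        chain = cpdag(Dag(list("ABC"), [("A", "C"), ("C", "B")]))
        assert shd(coll, chain) == 2  # both arcs change kind

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            shd_normalized(cpdag(Dag(["A"])), cpdag(Dag(["A"])))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetric_edit_count_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list("ABCDE")

        def rand_dag():
            arcs = [(nodes[i], nodes[j]) for i in range(5)
                    for j in range(i + 1, 5) if rng.random() < 0.4]
            return cpdag(Dag(nodes, arcs))

        c1, c2 = rand_dag(), rand_dag()
        assert shd(c1, c2) == shd(c2, c1)
        assert shd(c1, c1) == 0


class TestAucMetrics:
    def test_perfect_separation(self):
        auroc, auprc = auc_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auroc == 1.0 and auprc == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        auroc, _ = auc_metrics([0, 1, 0, 1], [0.5] * 4)
        assert auroc == pytest.approx(0.5)

    def test_rank_formula_hand_case(self):
        auroc, _ = auc_metrics([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        assert auroc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_metrics([1, 1], [0.2, 0.4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rank_formula_equals_trapezoidal_integration(self, seed):
        """The rank statistic and the trapezoid under the ROC curve are
        the same number (1e-10)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        auroc, _ = auc_metrics(y, s)
        fpr, tpr, _ = roc_curve(y, s)
        assert auroc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)


class TestCrossvalidate:
    @pytest.fixture(scope="class")
    @staticmethod
    def cv_data():
        return make_split_advantage_data(250, seed=3)

    def test_each_row_tested_once(self, cv_data):
        tab = crossvalidate(cv_data, "target", settings=FAST, folds=5,
                            seed=0, n_groups=3, n_particles=200, runs=2)
        assert tab["n_test"].sum() == cv_data.n_obs
        assert len(tab) == 5

    def test_informative_target_beats_permuted_control(self, cv_data):
        """Mean AUROC of the real model exceeds chance by more than three
        standard deviations of a permuted-label control on the same folds."""
        tab = crossvalidate(cv_data, "target", settings=FAST, folds=5,
                            seed=7, n_groups=3, n_particles=300, runs=2)
        real = tab.attrs["auroc_mean"]

        perms = []
        for p_seed in range(4):
            rng = np.random.default_rng(1000 + p_seed)
            df = cv_data.df.copy()
            df["target"] = rng.permutation(df["target"].to_numpy())
            from clusterbn.data import MixedDataset
            Dp = MixedDataset(df, dict(cv_data.var_kinds),
                              {k: list(v) for k, v in cv_data.levels.items()})
            t = crossvalidate(Dp, "target", settings=FAST, folds=5,
                              seed=7, n_groups=3, n_particles=300, runs=2)
            perms.append(t.attrs["auroc_mean"])
        sd = max(np.std(perms, ddof=1), 0.01)
        assert real > 0.5 + 3 * sd


class TestSimulationStudy:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_study():
        return run_simulation_study(
            [Scenario(n_groups=3, group_size=2, noise=0.1, n=200)],
            reps=2, seed=5, settings=FAST)

    def test_record_count(self, tiny_study):
        assert len(tiny_study) == 2 * 4  # reps x arms

    def test_ground_truth_arm_partition_is_zero(self, tiny_study):
        gt = tiny_study[tiny_study["method"] == "ground_truth_grouping"]
        assert (gt["partition_distance"] == 0).all()

    def test_records_carry_scenario_metadata(self, tiny_study):
        assert set(["n_groups", "group_size", "noise", "n", "replicate",
                    "method", "partition_distance", "normalized_shd",
                    "prediction_error"]) <= set(tiny_study.columns)


class TestMatchGroups:
    def test_relabels_by_overlap(self):
        learned = {"L1": ["a", "b"], "L2": ["c", "d"]}
        truth = {"T1": ["c", "d"], "T2": ["a", "b"]}
        m = match_groups(learned, truth)
        assert m == {"L1": "T2", "L2": "T1"}
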