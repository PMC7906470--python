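import itertools

import numpy as np
import pandas as pd
import pytest

from clusterbn import bn
from clusterbn.bn import (ArcStrengths, Cpdag, Dag, adaptive_threshold,
                          bic_local, bic_score, bootstrap_average, cpdag,
                          fit_parameters, hill_climb, markov_blanket,
                          moralize)

from _oracles import all_dags, bic_local_bruteforce, cpdag_by_enumeration


class TestDag:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Dag(["a", "b"], [("a", "b"), ("b", "a")])

    def test_self_loop_rejected(self):
        g = Dag(["a", "b"])
        with pytest.raises(ValueError):
            g.add_arc("a", "a")

    def test_parents_children(self):
        g = Dag(list("abc"), [("a", "c"), ("b", "c")])
        assert g.parents("c") == ["a", "b"]
        assert g.children("a") == ["c"]


class TestBicLocal:
    def test_hand_computed_counts_3_1(self):
        """Counts (1 zero, 3 ones), no parents, N=4."""
        df = pd.DataFrame({"x": ["1", "1", "1", "0"]})
        expect = 3 * np.log(3 / 4) + 1 * np.log(1 / 4) - 0.5 * np.log(4)
        assert bic_local("x", [], df) == pytest.approx(expect, abs=1e-10)
        assert bic_local("x", [], df) == pytest.approx(-2.9424, abs=1e-4)

    def test_hand_computed_counts_2_2(self):
        df = pd.DataFrame({"x": ["0", "0", "1", "1"]})
        assert bic_local("x", [], df) == pytest.approx(-3.4657, abs=5e-5)

    def test_parent_gain_vs_penalty(self):
        """A deterministic parent is worth its penalty at N=100."""
        x = np.repeat(["0", "1"], 50)
        df = pd.DataFrame({"p": x, "x": x})
        gain = bic_local("x", ["p"], df) - bic_local("x", [], df)
        # likelihood gain N log 2, extra penalty (q-1)(r-1)/2 log N
        assert gain == pytest.approx(100 * np.log(2) - 0.5 * np.log(100),
                                     abs=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_counting_oracle(self, seed):
        """50 random small datasets against an independent loop-based
        contingency implementation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        cards = rng.integers(2, 4, size=3)
        df = pd.DataFrame({
            f"v{i}": rng.integers(0, cards[i], size=n).astype(str)
            for i in range(3)})
        n_par = int(rng.integers(0, 3))
        parents = [f"v{i + 1}" for i in range(n_par)]
        mine = bic_local("v0", parents, df)
        oracle = bic_local_bruteforce(
            df["v0"].tolist(), [df[p].tolist() for p in parents])
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            bic_local("x", [], pd.DataFrame({"x": []}))

    def test_score_decomposability(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({c: rng.integers(0, 2, 100).astype(str)
                           for c in "abc"})
        g = Dag(list("abc"), [("a", "b"), ("b", "c")])
        total = bic_score(g, df)
        parts = sum(bic_local(v, g.parents(v), df) for v in g.nodes)
        assert total == pytest.approx(parts, abs=1e-9)


class TestHillClimb:
    def test_independent_variables_give_empty_graph(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.integers(0, 2, 1000).astype(str),
                           "b": rng.integers(0, 2, 1000).astype(str)})
        assert hill_climb(df, restarts=2, seed=0).arcs == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_deterministic_copy_recovered(self, seed):
        """x2 = x1 exactly: the pair must be linked, x3 stay isolated."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 200)
        df = pd.DataFrame({"x1": x.astype(str), "x2": x.astype(str),
                           "x3": rng.integers(0, 2, 200).astype(str)})
        got = cpdag(hill_climb(df, restarts=2, seed=seed))
        assert got.edge_type("x1", "x2") != "none"
        assert got.edge_type("x1", "x3") == "none"
        assert got.edge_type("x2", "x3") == "none"

    def test_score_never_below_init(self, random_binary_bn):
        M = random_binary_bn(3, n=5)
        df = M.sample(300, np.random.default_rng(5))
        learned = hill_climb(df, init=M.dag, restarts=1, seed=0)
        assert bic_score(learned, df) >= bic_score(M.dag, df) - 1e-9
        assert learned.is_acyclic()


class TestBootstrapAverage:
    def test_adaptive_threshold_hand_case(self):
        """Strengths (1, 1, 0.02): t=0.02 minimizes the L1 distance and
        keeps exactly the two unit-strength arcs."""
        assert adaptive_threshold([1.0, 1.0, 0.02]) == pytest.approx(0.02)

    def test_adaptive_threshold_degenerate(self):
        assert adaptive_threshold([]) == 0.0
        assert adaptive_threshold([1.0, 1.0]) == 0.0  # keep all at t=0

    def test_strength_invariants_and_averaged_dag(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 300)
        df = pd.DataFrame({"a": x.astype(str),
                           "b": np.where(rng.random(300) < 0.95, x,
                                         1 - x).astype(str),
                           "c": rng.integers(0, 2, 300).astype(str)})
        st, thr, avg = bootstrap_average(df, B=30, restarts=1, seed=0)
        for (u, v), s in st.strength.items():
            assert 0.0 <= s <= 1.0
            assert st.strength[(v, u)] == pytest.approx(s)
            assert st.direction[(u, v)] + st.direction[(v, u)] == pytest.approx(1.0)
        assert avg.is_acyclic()
        assert frozenset(("a", "b")) in {frozenset(a) for a in avg.arcs}

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({c: rng.integers(0, 2, 100).astype(str)
                           for c in "abc"})
        r1 = bootstrap_average(df, B=10, restarts=1, seed=42)
        r2 = bootstrap_average(df, B=10, restarts=1, seed=42)
        assert r1[2].arcs == r2[2].arcs and r1[0].strength == r2[0].strength


class TestFitParameters:
    def test_uniform_prior_hand_cases(self):
        g = Dag(["x"])
        bn1 = fit_parameters(g, pd.DataFrame({"x": ["0", "0", "1", "1"]}))
        np.testing.assert_allclose(bn1.cpts["x"], [[0.5, 0.5]])
        bn2 = fit_parameters(g, pd.DataFrame({"x": ["1"] * 4}),
                             states={"x": ["0", "1"]})
        np.testing.assert_allclose(bn2.cpts["x"], [[0.1, 0.9]])

    def test_unseen_parent_configuration_gets_prior(self):
        g = Dag(["p", "x"], [("p", "x")])
        df = pd.DataFrame({"p": ["0", "0"], "x": ["0", "1"]})
        fitted = fit_parameters(g, df, states={"p": ["0", "1"],
                                               "x": ["0", "1"]})
        np.testing.assert_allclose(fitted.cpts["x"][1], [0.5, 0.5])

    def test_rows_normalized(self, random_binary_bn):
        M = random_binary_bn(7)
        df = M.sample(50, np.random.default_rng(0))
        fitted = fit_parameters(M.dag, df, states=M.states)
        for v in fitted.nodes:
            np.testing.assert_allclose(fitted.cpts[v].sum(axis=1), 1.0,
                                       atol=1e-12)


class TestCpdag:
    def test_chain_is_fully_undirected(self):
        got = cpdag(Dag(list("ABC"), [("A", "B"), ("B", "C")]))
        assert got.directed == set()
        assert got.undirected == {frozenset("AB"), frozenset("BC")}

    def test_collider_stays_directed(self):
        got = cpdag(Dag(list("ABC"), [("A", "C"), ("B", "C")]))
        assert got.directed == {("A", "C"), ("B", "C")}
        assert got.undirected == set()

    def test_empty_graph(self):
        got = cpdag(Dag(list("AB")))
        assert got.n_edges == 0

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exhaustive_equivalence_enumeration(self, n):
        """Every DAG on <= 4 nodes against the brute-force equivalence-
        class oracle (compelled = same orientation across the class)."""
        names = [str(i) for i in range(n)]
        for arcs in all_dags(n):
            named = [(names[u], names[v]) for u, v in arcs]
            got = cpdag(Dag(names, named))
            odir, oundir = cpdag_by_enumeration(arcs, n)
            odir = {(names[u], names[v]) for u, v in odir}
            oundir = {frozenset((names[u], names[v])) for u, v in
                      (tuple(e) for e in oundir)}
            assert got.directed == odir, f"arcs={named}"
            assert got.undirected == oundir, f"arcs={named}"


class TestGraphOps:
    def test_markov_blanket_examples(self):
        chain = Dag(list("ABC"), [("A", "B"), ("B", "C")])
        assert markov_blanket(chain, "B") == {"A", "C"}
        coll = Dag(list("ABC"), [("A", "C"), ("B", "C")])
        assert markov_blanket(coll, "A") == {"B", "C"}
        iso = Dag(list("AB"))
        assert markov_blanket(iso, "A") == set()
        with pytest.raises(KeyError):
            markov_blanket(chain, "Z")

    def test_moralize_examples(self):
        coll = Dag(list("ABC"), [("A", "C"), ("B", "C")])
        assert set(map(frozenset, moralize(coll).edges)) == {
            frozenset("AC"), frozenset("BC"), frozenset("AB")}
        chain = Dag(list("ABC"), [("A", "B"), ("B", "C")])
        assert set(map(frozenset, moralize(chain).edges)) == {
            frozenset("AB"), frozenset("BC")}

    @pytest.mark.parametrize("seed", range(20))
    def test_moral_adjacency_equals_markov_blanket(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(6)]
        arcs = [(nodes[i], nodes[j]) for i in range(6) for j in range(i + 1, 6)
                if rng.random() < 0.35]
        g = Dag(nodes, arcs)
        moral = moralize(g)
        for v in nodes:
            assert set(moral.neighbors(v)) == markov_blanket(g, v)
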