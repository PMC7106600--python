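import numpy as np
import pandas as pd
import pytest

from pvqnet.bayesnet import (DAG, ArcConstraints, ConstraintError, ScoreSpec,
                             UnsupportedAlgorithmError, check_acyclic, cpdag,
                             get_algorithm, hill_climb, score_network, shd,
                             tabu_search)
from conftest import all_dags_3, dfs_has_cycle, skeleton_vstructs


class TestAcyclicity:
    def test_chain_is_acyclic(self):
        dag = DAG({"A": (0, 1), "B": (0, 1), "C": (0, 1)}, {("A", "B"), ("B", "C")})
        assert check_acyclic(dag)

    def test_two_cycle_rejected_by_checker(self):
        g = DAG.__new__(DAG)
        g.nodes = {"A": (0, 1), "B": (0, 1)}
        g.arcs = {("A", "B"), ("B", "A")}
        assert not check_acyclic(g)

    def test_matches_dfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        names = [f"n{i}" for i in range(50)]
        for _ in range(1000):
            arcs = set()
            for _ in range(rng.integers(0, 80)):
                u, v = rng.choice(50, size=2, replace=False)
                arcs.add((names[u], names[v]))
            g = DAG.__new__(DAG)
            g.nodes = {n: (0, 1) for n in names}
            g.arcs = arcs
            assert check_acyclic(g) == (not dfs_has_cycle(names, arcs))


class TestConstraints:
    def test_overlapping_lists_rejected(self):
        c = ArcConstraints(whitelist={("A", "B")}, blacklist={("A", "B")})
        with pytest.raises(ConstraintError):
            c.validate(["A", "B"])

    def test_cyclic_whitelist_rejected(self):
        c = ArcConstraints(whitelist={("A", "B"), ("B", "A")})
        with pytest.raises(ConstraintError):
            c.validate(["A", "B"])

    def test_json_round_trip(self, tmp_path):
        c = ArcConstraints(whitelist={("A", "B")}, blacklist={("B", "C")})
        p = tmp_path / "arcs.json"
        c.to_json(p)
        back = ArcConstraints.from_json(p)
        assert back.whitelist == c.whitelist and back.blacklist == c.blacklist


def _two_node_data(n=5000, dependent=True, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.choice(["x", "y"], size=n)
    if dependent:
        b = np.where(rng.random(n) < 0.9, a, np.where(a == "x", "y", "x"))
    else:
        b = rng.choice(["x", "y"], size=n)
    return pd.DataFrame({"A": a, "B": b}), {"A": ("x", "y"), "B": ("x", "y")}


class TestHillClimb:
    def test_strong_dependence_recovered_up_to_equivalence(self):
        data, states = _two_node_data(dependent=True)
        dag = hill_climb(data, states=states)
        truth = DAG(states, {("A", "B")})
        assert shd(cpdag(dag), cpdag(truth)) == 0

    def test_independence_gives_empty_graph(self):
        data, states = _two_node_data(dependent=False)
        dag = hill_climb(data, states=states)
        assert dag.arcs == set()

    def test_whitelist_arc_survives_independence(self):
        data, states = _two_node_data(dependent=False)
        dag = hill_climb(data, ArcConstraints(whitelist={("A", "B")}), states=states)
        assert ("A", "B") in dag.arcs

    def test_blacklist_respected(self):
        data, states = _two_node_data(dependent=True)
        dag = hill_climb(
            data, ArcConstraints(blacklist={("A", "B"), ("B", "A")}), states=states)
        assert dag.arcs == set()

    def test_output_satisfies_constraints_and_acyclicity(self, truth_network):
        from pvqnet import synthetic_data as sd
        data = sd.sample_network(truth_network, 2000, 9)
        constraints = ArcConstraints(whitelist={("oq_level", "sb_group")},
                                     blacklist={("sb_group", "age_band")})
        dag = hill_climb(data, constraints, states=truth_network.dag.nodes)
        assert check_acyclic(dag)
        assert ("oq_level", "sb_group") in dag.arcs
        assert ("sb_group", "age_band") not in dag.arcs
        # search never ends below its whitelist start
        start = DAG(dict(truth_network.dag.nodes), set(constraints.whitelist))
        assert score_network(dag, data, states=dag.nodes) >= score_network(
            start, data, states=start.nodes)


def _collider_data(n=5000, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.choice(["x", "y"], size=n)
    b = rng.choice(["x", "y"], size=n)
    noise = rng.random(n) < 0.85
    c = np.where(noise, np.where(a == b, "x", "y"), np.where(a == b, "y", "x"))
    return (pd.DataFrame({"A": a, "B": b, "C": c}),
            {"A": ("x", "y"), "B": ("x", "y"), "C": ("x", "y")})


def _exhaustive_best_cpdag(data, states, spec=ScoreSpec()):
    best, best_s = None, -np.inf
    for arcs in all_dags_3(tuple(sorted(states))):
        dag = DAG(states, set(arcs))
        s = score_network(dag, data, spec, states=states)
        if s > best_s + 1e-12:
            best, best_s = dag, s
    return cpdag(best), best_s


class TestTabu:
    def test_collider_recovered_against_exhaustive_oracle(self):
        data, states = _collider_data()
        dag = tabu_search(data, states=states)
        best_c, best_s = _exhaustive_best_cpdag(data, states)
        assert shd(cpdag(dag), best_c) == 0
        assert score_network(dag, data, states=states) == pytest.approx(best_s, abs=1e-6)

    def test_never_below_hill_climb(self):
        rng = np.random.default_rng(1)
        states = {f"n{i}": ("x", "y") for i in range(4)}
        for trial in range(50):
            n = 300
            cols = {}
            base = rng.choice(["x", "y"], size=n)
            for i, name in enumerate(states):
                flip = rng.random(n) < rng.uniform(0.1, 0.5)
                cols[name] = np.where(flip, np.where(base == "x", "y", "x"), base)
            data = pd.DataFrame(cols)
            s_hc = score_network(hill_climb(data, states=states), data, states=states)
            s_tabu = score_network(tabu_search(data, states=states), data, states=states)
            assert s_tabu >= s_hc - 1e-9

    def test_zero_iterations_returns_whitelist_graph(self):
        data, states = _two_node_data(dependent=True)
        constraints = ArcConstraints(whitelist={("B", "A")})
        dag = tabu_search(data, constraints, tabu_length=1, max_iter=0, states=states)
        assert dag.arcs == {("B", "A")}

    def test_deterministic(self):
        data, states = _collider_data(seed=5)
        d1 = tabu_search(data, states=states)
        d2 = tabu_search(data, states=states)
        assert d1.arcs == d2.arcs


class TestAlgorithmRegistry:
    def test_supported_names(self):
        assert get_algorithm("tabu") is tabu_search
        assert get_algorithm("hill_climbing") is hill_climb

    @pytest.mark.parametrize("name", ["grow_shrink", "iamb", "fast_iamb",
                                      "inter_iamb", "mmpc"])
    def test_constraint_based_names_raise_unsupported(self, name):
        with pytest.raises(UnsupportedAlgorithmError):
            get_algorithm(name)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            get_algorithm("simulated_annealing")


class TestCPDAG:
    def test_matches_equivalence_class_oracle_on_all_3_node_dags(self):
        names = ("A", "B", "C")
        states = {n: ("x", "y") for n in names}
        dags = all_dags_3(names)
        # oracle: group by (skeleton, v-structures); an edge is compelled iff
        # it has the same orientation in every member of its class
        classes = {}
        for arcs in dags:
            classes.setdefault(skeleton_vstructs(names, arcs), []).append(arcs)
        for key, members in classes.items():
            for arcs in members:
                directed, undirected = cpdag(DAG(states, set(arcs)))
                for u, v in arcs:
                    same = all((u, v) in m for m in members)
                    if same:
                        assert (u, v) in directed
                    else:
                        assert frozenset((u, v)) in undirected

    def test_shd_counts_every_kind_of_difference(self):
        states = {n: ("x", "y") for n in "ABC"}
        chain = cpdag(DAG(states, {("A", "B"), ("B", "C")}))
        collider = cpdag(DAG(states, {("A", "B"), ("C", "B")}))
        empty = cpdag(DAG(states, set()))
        assert shd(chain, chain) == 0
        assert shd(chain, empty) == 2
        assert shd(chain, collider) == 2   # both edges change type
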