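import itertools

import numpy as np
import pandas as pd
import pytest

from causaltransport.graph import (CausalGraph, CycleError, GraphError,
                                   GraphParseError, ImpliedIndependence,
                                   UndefinedCorrelationError, parse_graph,
                                   partial_correlation)
from causaltransport.graph import test_independencies as run_ci_tests

from conftest import dsep_path_oracle, make_graph, upper_triangular_dags


class TestParsing:
    def test_bare_edge_list_declares_nodes_implicitly(self):
        g = parse_graph("a -> b\nb -> c")
        assert g.node_names == ["a", "b", "c"]
        assert g.edges == (("a", "b"), ("b", "c"))
        assert g.exogenous == ["a"]

    def test_two_cycle_rejected(self):
        with pytest.raises(CycleError, match="not acyclic"):
            parse_graph("a -> b\nb -> a")

    def test_longer_cycle_named_in_error(self):
        with pytest.raises(CycleError, match="not acyclic"):
            parse_graph("a -> b\nb -> c\nc -> a")

    def test_undeclared_node_in_edge_is_error_when_declarations_present(self):
        with pytest.raises(GraphParseError, match="line 3"):
            parse_graph("a : continuous\nb : continuous\na -> z")

    def test_unknown_outcome_rejected(self):
        with pytest.raises(GraphParseError, match="outcome"):
            parse_graph("a -> b\noutcome: zzz")

    def test_garbage_line_reports_line_number(self):
        with pytest.raises(GraphParseError, match="line 2"):
            parse_graph("a -> b\na --> b")

    def test_roundtrip_identity(self, fig1_graph):
        assert parse_graph(fig1_graph.to_text()) == fig1_graph

    def test_comments_and_kinds(self):
        g = parse_graph("# header\nx : binary\ny : continuous\nx -> y  # e\n")
        assert g.kind("x") == "binary"
        assert g.role("x") == "exogenous"
        assert g.role("y") == "endogenous"

    def test_topological_order_consistent(self, fig1_graph):
        order = fig1_graph.topological_order()
        pos = {v: i for i, v in enumerate(order)}
        assert all(pos[a] < pos[b] for a, b in fig1_graph.edges)


class TestPredictorSets:
    def test_fig1_partitions_match_published_lists(self, fig1_graph):
        assert fig1_graph.predictor_set("parents") == [
            "age", "apoe4", "sex", "educ", "bmi", "cardio", "tau", "abeta"]
        assert fig1_graph.predictor_set("children") == [
            "hippo", "ventr", "icv", "fdg", "mmse"]
        assert fig1_graph.predictor_set("exogenous") == ["age", "apoe4", "sex"]
        assert fig1_graph.predictor_set("all") == [
            "age", "apoe4", "sex", "educ", "bmi", "hypert", "alc", "smok",
            "cardio", "tau", "abeta", "hippo", "ventr", "icv", "fdg", "mmse"]

    def test_chain_outcome_exogenous_scheme(self, chain_graph):
        assert chain_graph.predictor_set("exogenous") == ["a"]
        assert chain_graph.predictor_set("parents") == ["a"]
        assert chain_graph.predictor_set("children") == ["c"]

    def test_outcome_required(self):
        g = parse_graph("a -> b")
        with pytest.raises(GraphError, match="outcome"):
            g.predictor_set("all")


class TestDSeparation:
    def test_blocked_chain(self):
        g = make_graph(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assert g.d_separated("a", "c", {"b"})
        assert not g.d_separated("a", "c", set())

    def test_collider_opens_when_conditioned(self):
        g = make_graph(["a", "b", "c"], [("a", "b"), ("c", "b")])
        assert g.d_separated("a", "c", set())
        assert not g.d_separated("a", "c", {"b"})

    def test_descendant_of_collider_opens_path(self):
        g = make_graph(["a", "b", "c", "d"],
                       [("a", "b"), ("c", "b"), ("b", "d")])
        assert not g.d_separated("a", "c", {"d"})

    def test_unknown_node_raises(self, chain_graph):
        with pytest.raises(GraphError, match="unknown"):
            chain_graph.d_separated("a", "zz", set())

    def test_matches_path_oracle_on_all_four_node_dags(self):
        for nodes, edges in upper_triangular_dags(4):
            g = make_graph(nodes, edges)
            for x, y in itertools.combinations(nodes, 2):
                rest = [v for v in nodes if v not in (x, y)]
                for r in range(len(rest) + 1):
                    for given in itertools.combinations(rest, r):
                        assert g.d_separated(x, y, set(given)) == \
                            dsep_path_oracle(edges, nodes, x, y, given), \
                            (edges, x, y, given)

    def test_matches_networkx_on_fig1(self, fig1_graph):
        import networkx as nx
        dg = nx.DiGraph(list(fig1_graph.edges))
        dg.add_nodes_from(fig1_graph.node_names)
        rng = np.random.default_rng(5)
        names = fig1_graph.node_names
        for _ in range(200):
            x, y = rng.choice(names, size=2, replace=False)
            rest = [v for v in names if v not in (x, y)]
            given = set(rng.choice(rest, size=rng.integers(0, 4), replace=False))
            assert fig1_graph.d_separated(x, y, given) == \
                nx.is_d_separator(dg, {x}, {y}, given)


class TestImpliedIndependencies:
    def test_complete_graph_has_none(self):
        g = make_graph(["a", "b", "c"],
                       [("a", "b"), ("a", "c"), ("b", "c")])
        assert g.implied_independencies() == []

    def test_chain_basis(self):
        g = make_graph(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assert g.implied_independencies() == [
            ImpliedIndependence("a", "c", frozenset({"b"}))]

    def test_every_statement_is_d_separated(self, fig1_graph):
        implied = fig1_graph.implied_independencies()
        assert len(implied) > 0
        for ind in implied:
            assert fig1_graph.d_separated(ind.x, ind.y, ind.given), str(ind)

    def test_basis_d_separated_on_random_small_dags(self):
        rng = np.random.default_rng(11)
        nodes = [f"v{i}" for i in range(6)]
        pairs = [(nodes[i], nodes[j]) for i in range(6) for j in range(i + 1, 6)]
        for _ in range(100):
            edges = [e for e in pairs if rng.random() < 0.4]
            g = make_graph(nodes, edges)
            for ind in g.implied_independencies():
                assert g.d_separated(ind.x, ind.y, ind.given), (edges, str(ind))


class TestCITesting:
    def test_partial_correlation_vanishes_in_chain_data(self):
        rng = np.random.default_rng(0)
        n = 5000
        a = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * rng.standard_normal(n)
        c = 0.8 * b + 0.6 * rng.standard_normal(n)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        res = run_ci_tests(
            df, [ImpliedIndependence("a", "c", frozenset({"b"}))])
        assert abs(res[0].estimate) < 0.05
        assert res[0].n == n

    def test_identical_columns_give_unit_correlation(self):
        x = np.arange(50, dtype=float)
        df = pd.DataFrame({"x": x, "y": x.copy()})
        res = run_ci_tests(df, [ImpliedIndependence("x", "y", frozenset())])
        assert res[0].estimate == pytest.approx(1.0)
        assert res[0].p_value == 0.0

    def test_collider_conditioning_induces_bias(self):
        # a -> b <- c with unit effects: conditioning on b makes a and c
        # negatively dependent; the magnitude follows from the coefficients:
        # partial corr = -beta_a*beta_c / sqrt((beta_a^2+s2)(beta_c^2+s2))
        rng = np.random.default_rng(1)
        n = 20_000
        a = rng.standard_normal(n)
        c = rng.standard_normal(n)
        b = a + c + 0.5 * rng.standard_normal(n)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        res = run_ci_tests(
            df, [ImpliedIndependence("a", "c", frozenset({"b"}))])
        expected = -1.0 / (1.0 + 0.25)
        assert res[0].estimate == pytest.approx(expected, abs=0.03)
        assert res[0].p_value < 1e-10

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                           "y": [1.0] * 6})
        with pytest.raises(UndefinedCorrelationError, match="'y'"):
            run_ci_tests(df, [ImpliedIndependence("x", "y", frozenset())])

    def test_type_i_error_calibrated_under_true_model(self):
        # data generated from the chain itself: the implied CI holds, so the
        # Fisher-z test should reject at ~alpha
        rng = np.random.default_rng(7)
        n, reps, alpha = 400, 500, 0.05
        rejections = 0
        ind = ImpliedIndependence("a", "c", frozenset({"b"}))
        for _ in range(reps):
            a = rng.standard_normal(n)
            b = 0.7 * a + rng.standard_normal(n) * 0.71
            c = 0.7 * b + rng.standard_normal(n) * 0.71
            df = pd.DataFrame({"a": a, "b": b, "c": c})
            if run_ci_tests(df, [ind])[0].p_value < alpha:
                rejections += 1
        rate = rejections / reps
        # 3 MC sds of 0.05 at 500 replications is ~0.03
        assert abs(rate - alpha) < 0.03
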