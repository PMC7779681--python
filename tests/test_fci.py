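"""FCI: CI tests, skeleton search, orientation rules, PAG recovery."""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from koaprog.fci import (
    ARROW,
    CIRCLE,
    TAIL,
    DSeparationOracle,
    FCIModel,
    PAG,
    apply_orientation_rules,
    ci_test,
    learn_skeleton,
    orient_v_structures,
    run_fci,
)
from koaprog.synthetic import default_causal_spec, default_transition_matrix, simulate_cohort

SYMPTOMS = ("swelling", "grinding", "catching", "limited_flexion", "pain")


# -- independent brute-force reference over DAGs ----------------------------

def all_dags(nodes):
    """Every DAG over the given nodes (each node pair: no edge / -> / <-)."""
    pairs = list(combinations(nodes, 2))
    for choice in product((0, 1, 2), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                g.add_edge(a, b)
            elif c == 2:
                g.add_edge(b, a)
        if nx.is_directed_acyclic_graph(g):
            yield g


def true_skeleton(dag):
    return {frozenset(e) for e in dag.edges()}


def true_colliders(dag):
    """Unshielded colliders a -> b <- c of the DAG."""
    out = set()
    skel = true_skeleton(dag)
    for b in dag.nodes():
        for a, c in combinations(sorted(dag.predecessors(b)), 2):
            if frozenset((a, c)) not in skel:
                out.add((a, b, c))
    return out


def learned_colliders(pag: PAG):
    out = set()
    for b in pag.nodes:
        for a, c in combinations(sorted(pag.adjacent(b)), 2):
            if pag.has_edge(a, c):
                continue
            if pag.mark(a, b) == ARROW and pag.mark(c, b) == ARROW:
                out.add((a, b, c))
    return out


# -- CI tests ----------------------------------------------------------------

class TestFisherZ:
    def test_type_one_error_calibrated(self):
        rejections = 0
        reps = 500
        for s in range(reps):
            rng = np.random.default_rng(s)
            df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["x", "y"])
            res = ci_test(df, "x", "y", [], alpha=0.05)
            rejections += not res.independent
        assert 0.03 <= rejections / reps <= 0.07

    def test_perfect_copy_is_dependent(self):
        x = np.random.default_rng(0).normal(size=500)
        df = pd.DataFrame({"x": x, "y": x})
        res = ci_test(df, "x", "y", [])
        assert res.p_value < 1e-10 and not res.independent

    def test_chain_blocked_by_middle_node(self):
        hits = 0
        reps = 40
        for s in range(reps):
            rng = np.random.default_rng(100 + s)
            x = rng.normal(size=10_000)
            z = x + rng.normal(size=10_000)
            y = z + rng.normal(size=10_000)
            df = pd.DataFrame({"x": x, "y": y, "z": z})
            marginal = ci_test(df, "x", "y", [], alpha=0.01)
            given_z = ci_test(df, "x", "y", ["z"], alpha=0.01)
            hits += (not marginal.independent) and given_z.independent
        assert hits >= 0.95 * reps

    def test_oversized_conditioning_set_rejected(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 5)),
                          columns=list("abcde"))
        with pytest.raises(ValueError, match="conditioning"):
            ci_test(df, "a", "b", ["c", "d", "e"])


class TestGSquared:
    def test_independent_binary_pair(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.integers(0, 2, 5000), "y": rng.integers(0, 3, 5000)})
        res = ci_test(df, "x", "y", [], family="g_squared", alpha=0.01)
        assert res.independent

    def test_dependence_detected_and_blocked_by_stratification(self):
        rng = np.random.default_rng(3)
        z = rng.integers(0, 2, 8000)
        x = (z + (rng.random(8000) < 0.2)).clip(0, 1)
        y = (z + (rng.random(8000) < 0.2)).clip(0, 1)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        assert not ci_test(df, "x", "y", [], family="g_squared").independent
        assert ci_test(df, "x", "y", ["z"], family="g_squared").independent


# -- skeleton ----------------------------------------------------------------

class TestLearnSkeleton:
    def test_mutually_independent_variables_give_empty_skeleton(self):
        clean = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            df = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
            adj, _ = learn_skeleton(df, alpha=0.01, max_depth=2)
            n_edges = sum(len(v) for v in adj.values()) // 2
            clean += n_edges <= 1
        assert clean >= 9

    def test_collider_skeleton_and_empty_sepset(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10_000)
        c = rng.normal(size=10_000)
        b = a + c + 0.5 * rng.normal(size=10_000)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        adj, sepsets = learn_skeleton(df, alpha=0.01, max_depth=2)
        assert adj["a"] == {"b"} and adj["c"] == {"b"}
        assert sepsets[frozenset(("a", "c"))] == set()

    def test_dense_graph_keeps_all_edges(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        y = 0.8 * x + rng.normal(size=5000)
        z = 0.8 * x - 0.8 * y + rng.normal(size=5000)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        adj, sepsets = learn_skeleton(df, alpha=0.01, max_depth=2)
        assert all(len(v) == 2 for v in adj.values())
        assert sepsets == {}

    def test_every_removed_edge_has_consistent_sepset(self, spec, tm):
        cohort = simulate_cohort(spec, tm, 4000, 2, seed=9)
        model = FCIModel(cohort, spec.observed_nodes, alpha=0.01, max_depth=3)
        data = model._matrix()
        adj, sepsets = learn_skeleton(data, alpha=0.01, max_depth=3)
        nodes = sorted(adj)
        for x, y in combinations(nodes, 2):
            if y not in adj[x]:
                assert frozenset((x, y)) in sepsets
                s = sepsets[frozenset((x, y))]
                assert ci_test(data, x, y, sorted(s), alpha=0.01).independent
            else:
                assert frozenset((x, y)) not in sepsets


# -- orientation -------------------------------------------------------------

def _pag_edge(*edges):
    nodes = sorted({v for e in edges for v in e[:2]})
    pag = PAG(nodes)
    for a, b, ma, mb in edges:
        pag.add_edge(a, b, ma, mb)
    return pag


class TestOrientation:
    def test_v_structure_marks_arrows_at_collider(self):
        skel = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}}
        pag = orient_v_structures(skel, {frozenset(("a", "c")): set()})
        assert pag.mark("a", "b") == ARROW and pag.mark("c", "b") == ARROW
        assert pag.mark("b", "a") == CIRCLE and pag.mark("b", "c") == CIRCLE

    def test_non_collider_left_as_circles(self):
        skel = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}}
        pag = orient_v_structures(skel, {frozenset(("a", "c")): {"b"}})
        assert pag.mark("a", "b") == CIRCLE and pag.mark("c", "b") == CIRCLE

    def test_complete_graph_stays_circles(self):
        skel = {"a": {"b", "c"}, "b": {"a", "c"}, "c": {"a", "b"}}
        pag = orient_v_structures(skel, {})
        assert all(pag.mark(u, v) == CIRCLE for u, v in pag._marks)

    def test_rule1_orients_tail_arrow(self):
        pag = _pag_edge(("a", "b", CIRCLE, ARROW), ("b", "c", CIRCLE, CIRCLE))
        out = apply_orientation_rules(pag, {})
        assert out.mark(b="c", a="b") == ARROW
        assert out.mark("c", "b") == TAIL

    def test_all_circle_pag_is_fixed_point(self):
        pag = _pag_edge(("a", "b", CIRCLE, CIRCLE), ("b", "c", CIRCLE, CIRCLE))
        out = apply_orientation_rules(pag, {})
        assert out == pag

    def test_mark_monotonicity(self, spec, tm):
        cohort = simulate_cohort(spec, tm, 4000, 2, seed=10)
        model = FCIModel(cohort, spec.observed_nodes, alpha=0.01, max_depth=3)
        data = model._matrix()
        adj, sepsets = learn_skeleton(data, alpha=0.01, max_depth=3)
        before = orient_v_structures(adj, sepsets)
        after = apply_orientation_rules(before, sepsets)
        for key, mark in before._marks.items():
            if mark == ARROW:
                assert after._marks[key] == ARROW

    def test_y_structure_gets_directed_edge(self):
        # a -> b <- c plus b -> d, all linear-Gaussian
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(300 + s)
            a = rng.normal(size=10_000)
            c = rng.normal(size=10_000)
            b = a + c + 0.5 * rng.normal(size=10_000)
            d = b + 0.7 * rng.normal(size=10_000)
            df = pd.DataFrame({"a": a, "b": b, "c": c, "d": d})
            adj, sepsets = learn_skeleton(df, alpha=0.01, max_depth=3)
            pag = apply_orientation_rules(orient_v_structures(adj, sepsets), sepsets)
            if pag.has_edge("b", "d") and pag.is_directed("b", "d"):
                hits += 1
        assert hits >= 9


# -- oracle equivalence ------------------------------------------------------

class TestOracleEquivalence:
    def test_matches_bruteforce_on_all_four_node_dags(self):
        nodes = ["a", "b", "c", "d"]
        n_checked = 0
        for dag in all_dags(nodes):
            oracle = DSeparationOracle(dag)
            adj, sepsets = learn_skeleton(oracle, max_depth=3)
            got_skel = {frozenset((x, y)) for x in adj for y in adj[x]}
            assert got_skel == true_skeleton(dag), f"skeleton differs on {sorted(dag.edges())}"
            pag = orient_v_structures(adj, sepsets)
            assert learned_colliders(pag) == true_colliders(dag), (
                f"colliders differ on {sorted(dag.edges())}"
            )
            n_checked += 1
        assert n_checked == 543  # number of DAGs on 4 labelled nodes


# -- full FCI on the ground-truth cohort -------------------------------------

class TestRunFCI:
    @pytest.fixture(scope="class")
    def pag(self, spec, tm):
        cohort = simulate_cohort(spec, tm, 5000, 2, seed=2024)
        return run_fci(cohort, spec.observed_nodes, alpha=0.01, max_depth=3)

    def test_latent_confounded_alignments_bidirected(self, pag):
        assert pag.is_bidirected("left_alignment", "right_alignment")

    def test_alignment_to_jsn_adjacent_and_jsn_to_kl(self, pag):
        assert pag.has_edge("left_alignment", "jsn")
        assert pag.has_edge("right_alignment", "jsn")
        assert pag.has_edge("jsn", "kl")
        assert pag.mark("jsn", "kl") == ARROW

    def test_no_symptom_points_into_progression(self, pag):
        for s in SYMPTOMS:
            if pag.has_edge(s, "kl"):
                assert pag.mark(s, "kl") != ARROW

    def test_order_invariance_under_column_permutation(self, spec, tm):
        cohort = simulate_cohort(spec, tm, 2000, 2, seed=77)
        variables = spec.observed_nodes
        a = run_fci(cohort, variables, alpha=0.01, max_depth=2)
        shuffled = cohort.copy()
        perm = list(np.random.default_rng(1).permutation(shuffled.data.columns))
        shuffled.data = shuffled.data[perm]
        b = run_fci(shuffled, variables[::-1], alpha=0.01, max_depth=2)
        assert a == b

    def test_too_few_rows_rejected(self, spec, tm):
        cohort = simulate_cohort(spec, tm, 30, 2, seed=5)
        with pytest.raises(ValueError, match="complete rows"):
            run_fci(cohort, spec.observed_nodes)
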