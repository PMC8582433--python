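import itertools

import numpy as np
import pytest

from netdriver.network_prior import WeightedNetwork
from netdriver.pathfinding import Path, PathIndex
from netdriver.subnetwork_selection import (
    FormulaEvaluator,
    PathFormula,
    Subnetwork,
    build_formulas,
    jaccard,
    label_components,
    optimize_subnetwork,
    satisfaction_probability,
    scan_penalties,
    score_subnetwork,
)

from conftest import inclusion_exclusion_probability

E1, E2, E3 = ("A", "B"), ("B", "C"), ("B", "D")


def make_formula(source, clauses):
    clauses = tuple((frozenset(c), tw) for c, tw in clauses)
    return PathFormula(
        source=source,
        clauses=clauses,
        relevant_edges=frozenset().union(*(c for c, _ in clauses)),
    )


def _path(source, edges, score, tw=1.0):
    prod = score / tw
    return Path(source=source, target=edges[-1][1], edges=tuple(edges),
                edge_product=prod, terminal_weight=tw, score=score)


class TestBuildFormulas:
    def test_one_formula_per_source_with_paths(self):
        idx = PathIndex(paths_by_source={
            "A": [_path("A", [E1, E2], 0.5), _path("A", [E1, E3], 0.4)],
            "B": [],
        })
        formulas = build_formulas(idx)
        assert len(formulas) == 1
        (f,) = formulas
        assert f.source == "A"
        assert len(f.clauses) == 2
        assert f.relevant_edges == {E1, E2, E3}

    def test_duplicate_paths_keep_larger_terminal_weight(self):
        idx = PathIndex(paths_by_source={
            "A": [_path("A", [E1, E2], 0.4, tw=0.5),
                  _path("A", [E1, E2], 0.64, tw=0.8)],
        })
        (f,) = build_formulas(idx)
        assert len(f.clauses) == 1
        assert f.clauses[0][1] == pytest.approx(0.8)


class TestSatisfactionProbability:
    def test_two_overlapping_clauses(self):
        f = make_formula("A", [({E1, E2}, 1.0), ({E1, E3}, 1.0)])
        w = {E1: 0.5, E2: 0.5, E3: 0.5}
        p = satisfaction_probability(f, {E1, E2, E3}, w)
        assert p == pytest.approx(0.375, abs=1e-12)

    def test_single_clause_with_terminal_weight(self):
        f = make_formula("A", [({E1, E2}, 0.5)])
        w = {E1: 0.8, E2: 0.9}
        assert satisfaction_probability(f, {E1, E2}, w) == pytest.approx(0.36)

    def test_no_present_edges_gives_zero(self):
        f = make_formula("A", [({E1, E2}, 1.0)])
        w = {E1: 0.8, E2: 0.9}
        assert satisfaction_probability(f, set(), w) == 0.0
        assert satisfaction_probability(f, {E1}, w) == 0.0

    def test_missing_weight_is_error(self):
        f = make_formula("A", [({E1}, 1.0)])
        with pytest.raises(KeyError):
            satisfaction_probability(f, {E1}, {})

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_inclusion_exclusion_oracle(self, seed):
        """Exact model counting equals inclusion-exclusion on random
        formulas, including partially-present edge sets."""
        rng = np.random.default_rng(seed)
        edges = [("N%d" % i, "N%d" % (i + 1)) for i in range(12)]
        weights = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
        n_clauses = int(rng.integers(1, 9))
        clauses = []
        for _ in range(n_clauses):
            k = int(rng.integers(1, 5))
            cl = frozenset(
                edges[i] for i in rng.choice(len(edges), k, replace=False))
            clauses.append((cl, float(rng.uniform(0.1, 1.0))))
        f = make_formula("S", clauses)
        present = frozenset(
            e for e in edges if rng.random() < 0.75)
        live = [c for c in clauses if c[0] <= present]
        expected = inclusion_exclusion_probability(live, weights)
        got = satisfaction_probability(f, present, weights)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_edge_addition(self):
        rng = np.random.default_rng(3)
        edges = [("N%d" % i, "M%d" % i) for i in range(10)]
        weights = {e: float(rng.uniform(0.1, 1.0)) for e in edges}
        clauses = [
            (frozenset(edges[i] for i in rng.choice(10, 3, replace=False)),
             float(rng.uniform(0.2, 1.0)))
            for _ in range(6)
        ]
        f = make_formula("S", clauses)
        present: set = set()
        last = 0.0
        for e in edges:
            present.add(e)
            p = satisfaction_probability(f, present, weights)
            assert p >= last - 1e-15
            last = p

    def test_cache_transparency(self):
        """Cached and uncached evaluation agree bitwise across a random
        sequence of subnetworks."""
        rng = np.random.default_rng(17)
        edges = [("N%d" % i, "M%d" % i) for i in range(15)]
        weights = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
        clauses = [
            (frozenset(edges[i] for i in rng.choice(15, int(rng.integers(1, 5)),
                                                    replace=False)),
             float(rng.uniform(0.1, 1.0)))
            for _ in range(10)
        ]
        f = make_formula("S", clauses)
        cached = FormulaEvaluator(f, weights, use_cache=True)
        uncached = FormulaEvaluator(f, weights, use_cache=False)
        for _ in range(100):
            present = frozenset(e for e in edges if rng.random() < 0.5)
            assert cached.probability(present) == uncached.probability(present)


class TestScore:
    def test_sum_minus_penalty(self):
        f1 = make_formula("A", [({E1, E2}, 1.0)])   # 0.72 with 0.8*0.9
        f2 = make_formula("B", [({E3}, 0.5)])       # 0.5 with weight 1.0
        w = {E1: 0.8, E2: 0.9, E3: 1.0}
        s = score_subnetwork({E1, E2, E3}, [f1, f2], 0.1, w)
        assert s == pytest.approx(0.72 + 0.5 - 0.3)

    def test_empty_subnetwork_scores_zero(self):
        f = make_formula("A", [({E1}, 1.0)])
        assert score_subnetwork(set(), [f], 0.3, {E1: 0.9}) == 0.0

    def test_zero_penalty_monotone_in_edges(self):
        f = make_formula("A", [({E1, E2}, 0.9), ({E3}, 0.4)])
        w = {E1: 0.7, E2: 0.6, E3: 0.5}
        subsets = [set(), {E1}, {E1, E2}, {E1, E2, E3}]
        scores = [score_subnetwork(s, [f], 0.0, w) for s in subsets]
        assert scores == sorted(scores)


def _random_opt_instance(rng, n_edges=10, n_formulas=5):
    edges = [("U%d" % i, "V%d" % i) for i in range(n_edges)]
    net = WeightedNetwork(
        edges={e: float(rng.uniform(0.2, 1.0)) for e in edges})
    formulas = []
    for j in range(n_formulas):
        clauses = []
        for _ in range(int(rng.integers(1, 4))):
            k = int(rng.integers(1, 4))
            cl = frozenset(
                edges[i] for i in rng.choice(n_edges, k, replace=False))
            clauses.append((cl, float(rng.uniform(0.2, 1.0))))
        formulas.append(make_formula("S%d" % j, clauses))
    return net, formulas


def brute_force_best_score(formulas, net, penalty):
    candidates = sorted(frozenset().union(*(f.relevant_edges for f in formulas)))
    evs = [FormulaEvaluator(f, net.edges) for f in formulas]
    best = -np.inf
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            s = sum(ev.probability(frozenset(subset)) for ev in evs)
            s -= penalty * r
            if s > best:
                best = s
    return best


class TestOptimizer:
    def test_union_optimum_returned_unchanged(self):
        # penalty 0: the full union maximizes the (monotone) score
        net = WeightedNetwork(edges={E1: 0.8, E2: 0.9})
        f = make_formula("A", [({E1, E2}, 1.0)])
        sub = optimize_subnetwork([f], 0.0, net, seed=0)
        assert sub.edge_set == {E1, E2}
        assert sub.score == pytest.approx(0.72)

    def test_dominant_penalty_gives_empty_network(self):
        net = WeightedNetwork(edges={E1: 0.8, E2: 0.9})
        f = make_formula("A", [({E1, E2}, 1.0)])
        sub = optimize_subnetwork([f], penalty=1.0, net=net, seed=0)
        assert sub.edge_set == set()
        assert sub.score == 0.0

    def test_small_instance_hits_exhaustive_optimum(self):
        rng = np.random.default_rng(100)
        hits = 0
        for seed in range(10):
            net, formulas = _random_opt_instance(rng, n_edges=8, n_formulas=4)
            penalty = float(rng.uniform(0.01, 0.3))
            sub = optimize_subnetwork(formulas, penalty, net, seed=seed)
            best = brute_force_best_score(formulas, net, penalty)
            if sub.score == pytest.approx(best, abs=1e-9):
                hits += 1
        assert hits >= 9

    def test_connector_vs_mutated_labeling(self):
        net = WeightedNetwork(edges={E1: 0.9, E2: 0.9})
        f = make_formula("A", [({E1, E2}, 1.0)])
        sub = optimize_subnetwork([f], 0.0, net, seed=0,
                                  mutated_genes={"A", "C"})
        assert sub.mutated_nodes == {"A", "C"}
        assert sub.connector_nodes == {"B"}


class TestJaccard:
    def test_identical_and_disjoint(self):
        assert jaccard({E1, E2}, {E1, E2}) == 1.0
        assert jaccard({E1}, {E2}) == 0.0
        assert jaccard(set(), set()) == 1.0

    def test_partial_overlap(self):
        assert jaccard({E1, E2}, {E2, E3}) == pytest.approx(1 / 3)


class TestPenaltyScan:
    def _stable_instance(self):
        """Two formulas sharing a 2-edge core; all runs converge."""
        net = WeightedNetwork(edges={E1: 0.9, E2: 0.9, E3: 0.9})
        f1 = make_formula("A", [({E1, E2}, 1.0)])
        f2 = make_formula("X", [({E1, E3}, 1.0)])
        return net, [f1, f2]

    def test_stable_positive_penalty_accepted(self):
        net, formulas = self._stable_instance()
        res = scan_penalties(formulas, net, penalties=[0.05],
                             runs_per_penalty=3, seed=1)
        r = res.per_penalty[0.05]
        assert r.accepted and r.rejection_reason is None
        assert r.mean_jaccard == 1.0
        assert res.final_network.edge_set == {E1, E2, E3}

    def test_negative_score_rejected(self):
        net, formulas = self._stable_instance()
        res = scan_penalties(formulas, net, penalties=[5.0],
                             runs_per_penalty=2, seed=1)
        r = res.per_penalty[5.0]
        assert not r.accepted and r.rejection_reason == "score"
        assert res.final_network.edge_set == set()

    def test_oversized_subnetwork_rejected(self):
        rng = np.random.default_rng(2)
        edges = {("U%d" % i, "V%d" % i): 0.95 for i in range(90)}
        net = WeightedNetwork(edges=edges)
        formulas = [
            make_formula("S%d" % i, [({e}, 1.0)])
            for i, e in enumerate(edges)
        ]
        res = scan_penalties(formulas, net, penalties=[0.01],
                             runs_per_penalty=2, seed=0)
        r = res.per_penalty[0.01]
        assert len(r.best.edges) == 90
        assert not r.accepted and r.rejection_reason == "size"

    def test_gene_rank_is_highest_accepted_penalty(self):
        net, formulas = self._stable_instance()
        res = scan_penalties(formulas, net, penalties=[0.01, 0.05],
                             runs_per_penalty=2, seed=1)
        assert res.accepted_penalties == [0.01, 0.05]
        for gene in ("A", "B", "C"):
            assert res.gene_ranks[gene] == 0.05

    def test_order_invariance_of_penalty_list(self):
        net, formulas = self._stable_instance()
        a = scan_penalties(formulas, net, [0.01, 0.2, 0.05], 2, seed=3)
        b = scan_penalties(formulas, net, [0.05, 0.01, 0.2], 2, seed=3)
        assert {p: r.best.edge_set for p, r in a.per_penalty.items()} == \
               {p: r.best.edge_set for p, r in b.per_penalty.items()}

    def test_label_permutation_invariance(self):
        net, formulas = self._stable_instance()
        mapping = {"A": "P", "B": "Q", "C": "R", "D": "T", "X": "W"}

        def m_edge(e):
            return (mapping[e[0]], mapping[e[1]])

        net2 = WeightedNetwork(
            edges={m_edge(e): w for e, w in net.edges.items()})
        formulas2 = [
            PathFormula(
                source=mapping[f.source],
                clauses=tuple(
                    (frozenset(map(m_edge, c)), tw) for c, tw in f.clauses),
                relevant_edges=frozenset(map(m_edge, f.relevant_edges)),
            )
            for f in formulas
        ]
        a = scan_penalties(formulas, net, [0.05], 2, seed=5)
        b = scan_penalties(formulas2, net2, [0.05], 2, seed=5)
        assert {m_edge(e) for e in a.final_network.edge_set} == \
               b.final_network.edge_set


class TestComponents:
    def _final(self):
        edges = {
            ("A", "B"): 0.9, ("B", "C"): 0.9,   # triangle-ish component
            ("X", "Y"): 0.9,
        }
        return Subnetwork(edges=edges, score=0.0,
                          mutated_nodes={"A", "C", "X", "Y"},
                          connector_nodes={"B"})

    def test_components_split_and_rank_by_coverage(self):
        gene_samples = {
            "A": {"s1", "s2"}, "C": {"s3"},
            "X": {"s1"}, "Y": {"s1"},
        }
        comps = label_components(self._final(), gene_samples)
        assert len(comps) == 2
        assert comps[0].nodes == {"A", "B", "C"}   # 3 samples > 1 sample
        assert comps[0].score == 3.0
        assert comps[1].score == 1.0

    def test_tie_breaks_by_size_then_gene(self):
        edges = {("A", "B"): 0.9, ("C", "D"): 0.9, ("C", "E"): 0.9}
        final = Subnetwork(edges=edges, score=0.0,
                           mutated_nodes={"A", "B", "C", "D", "E"})
        gene_samples = {g: {"s1"} for g in "ABCDE"}
        comps = label_components(final, gene_samples)
        assert comps[0].nodes == {"C", "D", "E"}  # same coverage, larger
        # permutation invariance of the ordering
        comps2 = label_components(final, dict(reversed(gene_samples.items())))
        assert [c.nodes for c in comps2] == [c.nodes for c in comps]
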