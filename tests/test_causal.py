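import itertools

import numpy as np
import pytest

from pgcausal.causal import (
    CiSuffStat,
    Cpdag,
    apply_meek_rules,
    cpdag_to_dot,
    d_separation_oracle,
    dag_to_cpdag,
    fisher_z_test,
    orient_v_structures,
    partial_correlation,
    pc,
    pc_skeleton,
    read_cpdag_tsv,
    structural_hamming_distance,
    suff_stat_from_observations,
    summarize_cpdag,
    write_cpdag_tsv,
)
from pgcausal.synthetic import Dag, random_dag

CHAIN = Dag(("X", "Y", "Z"), frozenset({("X", "Y"), ("Y", "Z")}), {})
COLLIDER = Dag(("X", "Y", "Z"), frozenset({("X", "Y"), ("Z", "Y")}), {})


def all_labeled_dags(n):
    """Every labeled DAG on n nodes (pairwise none / forward / backward)."""
    nodes = tuple(f"M{i + 1}" for i in range(n))
    pairs = list(itertools.combinations(nodes, 2))
    for assignment in itertools.product([0, 1, 2], repeat=len(pairs)):
        edges = []
        for (a, b), s in zip(pairs, assignment):
            if s == 1:
                edges.append((a, b))
            elif s == 2:
                edges.append((b, a))
        try:
            yield Dag(nodes, frozenset(edges), {})
        except ValueError:
            continue


def brute_force_cpdag(dag):
    """Independent oracle: enumerate every acyclic orientation of the
    skeleton with the same v-structures; an edge is directed in the CPDAG
    iff all class members agree on its direction."""

    def v_structures(edges):
        eset = set(edges)
        adj = {frozenset(e) for e in edges}
        out = set()
        children = {}
        for (p, c) in edges:
            children.setdefault(c, []).append(p)
        for y, parents in children.items():
            for x, z in itertools.combinations(sorted(parents), 2):
                if frozenset((x, z)) not in adj:
                    out.add((x, y, z))
        return out

    skeleton = [tuple(sorted(e)) for e in sorted(dag.edges)]
    reference = v_structures(dag.edges)
    members = []
    for orient in itertools.product([0, 1], repeat=len(skeleton)):
        edges = [(a, b) if o == 0 else (b, a)
                 for (a, b), o in zip(skeleton, orient)]
        try:
            Dag(dag.nodes, frozenset(edges), {})
        except ValueError:
            continue
        if v_structures(edges) == reference:
            members.append(set(edges))
    directed = {e for e in members[0] if all(e in m for m in members)}
    undirected = {frozenset(e) for e in members[0] if e not in directed}
    return directed, undirected


class TestPartialCorrelation:
    def suff(self, corr, n=100):
        return CiSuffStat(np.array(corr), n)

    def test_empty_conditioning_returns_marginal(self):
        s = self.suff([[1.0, 0.3], [0.3, 1.0]])
        assert partial_correlation(s, 0, 1, []) == pytest.approx(0.3)

    def test_mediator_removes_induced_correlation(self):
        # cor(X,Z) = cor(X,Y) * cor(Y,Z) => partial given Y is exactly 0
        s = self.suff([
            [1.0, 0.8, 0.64],
            [0.8, 1.0, 0.8],
            [0.64, 0.8, 1.0],
        ])
        assert partial_correlation(s, 0, 2, [1]) == pytest.approx(0.0, abs=1e-10)

    def test_identity_matrix_gives_zero_for_any_conditioning(self):
        s = self.suff(np.eye(4))
        assert partial_correlation(s, 0, 3, [1, 2]) == pytest.approx(0.0)

    def test_singular_submatrix_reported(self):
        corr = np.array([
            [1.0, 1.0, 0.5],
            [1.0, 1.0, 0.5],
            [0.5, 0.5, 1.0],
        ])
        with pytest.raises(np.linalg.LinAlgError):
            partial_correlation(self.suff(corr), 0, 2, [1])

    def test_rejects_overlapping_arguments(self):
        s = self.suff(np.eye(3))
        with pytest.raises(ValueError):
            partial_correlation(s, 0, 0, [])
        with pytest.raises(ValueError):
            partial_correlation(s, 0, 1, [1])


class TestFisherZTest:
    def test_zero_correlation_is_independent_at_any_level(self):
        s = CiSuffStat(np.eye(3), 50)
        res = fisher_z_test(s, 0, 1, [], alpha=0.001)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.independent

    def test_moderate_correlation_small_sample_arithmetic(self):
        # rho=0.5, n=19, S empty: z = atanh(0.5) ~ 0.5493,
        # T = 4 * 0.5493 ~ 2.197, p ~ 0.028 => dependent at alpha 0.05
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = fisher_z_test(CiSuffStat(corr, 19), 0, 1, [], alpha=0.05)
        assert res.fisher_z == pytest.approx(0.5493, abs=1e-4)
        assert res.statistic == pytest.approx(2.1972, abs=1e-3)
        assert res.p_value == pytest.approx(0.028, abs=0.001)
        assert not res.independent

    def test_sample_size_precondition(self):
        s = CiSuffStat(np.eye(3), 4)
        with pytest.raises(ValueError, match="n - |S| - 3"):
            fisher_z_test(s, 0, 1, [2])


class TestSkeleton:
    def test_chain_skeleton_and_sepset(self):
        adj, sepsets = pc_skeleton(d_separation_oracle(CHAIN))
        assert adj == {"X": {"Y"}, "Y": {"X", "Z"}, "Z": {"Y"}}
        assert sepsets[frozenset(("X", "Z"))] == ("Y",)

    def test_mutually_independent_variables_give_empty_skeleton(self):
        dag = Dag(("A", "B", "C"), frozenset(), {})
        adj, sepsets = pc_skeleton(d_separation_oracle(dag))
        assert all(not neighbors for neighbors in adj.values())
        assert all(S == () for S in sepsets.values())

    def test_collider_sepset_is_empty(self):
        adj, sepsets = pc_skeleton(d_separation_oracle(COLLIDER))
        assert adj["X"] == {"Y"} and adj["Z"] == {"Y"}
        assert sepsets[frozenset(("X", "Z"))] == ()


class TestOrientation:
    def test_collider_oriented_when_mediator_outside_sepset(self):
        skeleton = {"X": {"Y"}, "Y": {"X", "Z"}, "Z": {"Y"}}
        directed, undirected = orient_v_structures(
            skeleton, {frozenset(("X", "Z")): ()})
        assert directed == {("X", "Y"), ("Z", "Y")}
        assert undirected == set()

    def test_no_orientation_when_mediator_in_sepset(self):
        skeleton = {"X": {"Y"}, "Y": {"X", "Z"}, "Z": {"Y"}}
        directed, undirected = orient_v_structures(
            skeleton, {frozenset(("X", "Z")): ("Y",)})
        assert directed == set()
        assert len(undirected) == 2

    def test_triangle_has_no_unshielded_triple(self):
        skeleton = {"X": {"Y", "Z"}, "Y": {"X", "Z"}, "Z": {"X", "Y"}}
        directed, undirected = orient_v_structures(skeleton, {})
        assert directed == set() and len(undirected) == 3


class TestMeekRules:
    def test_r1_propagates_away_from_collider(self):
        # A -> B, B - C, A and C non-adjacent => B -> C
        cpdag = apply_meek_rules(
            ("A", "B", "C"), {("A", "B")}, {frozenset(("B", "C"))})
        assert ("B", "C") in cpdag.directed_edges

    def test_r2_orients_shielding_edge_of_a_directed_path(self):
        # A -> B -> C with A - C => A -> C
        cpdag = apply_meek_rules(
            ("A", "B", "C"), {("A", "B"), ("B", "C")}, {frozenset(("A", "C"))})
        assert ("A", "C") in cpdag.directed_edges

    def test_undirected_triangle_is_a_fixpoint(self):
        und = {frozenset(p) for p in [("A", "B"), ("B", "C"), ("A", "C")]}
        cpdag = apply_meek_rules(("A", "B", "C"), set(), set(und))
        assert cpdag.directed_edges == frozenset()
        assert cpdag.undirected_edges == frozenset(und)


class TestPc:
    def test_chain_equivalence_class_is_fully_undirected(self):
        cpdag = pc(d_separation_oracle(CHAIN))
        assert cpdag.directed_edges == frozenset()
        assert cpdag.undirected_edges == {
            frozenset(("X", "Y")), frozenset(("Y", "Z"))}

    def test_collider_is_alone_in_its_class(self):
        cpdag = pc(d_separation_oracle(COLLIDER))
        assert cpdag.directed_edges == {("X", "Y"), ("Z", "Y")}
        assert cpdag.undirected_edges == frozenset()

    def test_independent_variables_give_empty_graph(self):
        dag = Dag(("A", "B", "C", "D"), frozenset(), {})
        cpdag = pc(d_separation_oracle(dag))
        assert cpdag.n_edges == 0

    def test_invariant_to_variable_relabeling_on_oracle_input(self):
        dag = random_dag(5, 0.5, seed=13)
        cpdag = pc(d_separation_oracle(dag))
        relabel = {n: f"W{i + 1}" for i, n in enumerate(reversed(dag.nodes))}
        permuted = Dag(
            tuple(relabel[n] for n in dag.nodes),
            frozenset((relabel[a], relabel[b]) for a, b in dag.edges),
            {},
        )
        cpdag_p = pc(d_separation_oracle(permuted))
        assert cpdag_p.directed_edges == {
            (relabel[a], relabel[b]) for a, b in cpdag.directed_edges}
        assert cpdag_p.undirected_edges == {
            frozenset(relabel[v] for v in p) for p in cpdag.undirected_edges}


class TestDSeparationOracle:
    def test_chain_blocked_by_mediator(self):
        oracle = d_separation_oracle(CHAIN)
        assert oracle.independent(0, 2, (1,))
        assert not oracle.independent(0, 2, ())

    def test_collider_opens_when_conditioned_on(self):
        oracle = d_separation_oracle(COLLIDER)
        assert oracle.independent(0, 2, ())
        assert not oracle.independent(0, 2, (1,))


class TestDagToCpdag:
    def test_single_edge_is_reversible(self):
        dag = Dag(("A", "B"), frozenset({("A", "B")}), {})
        cpdag = dag_to_cpdag(dag)
        assert cpdag.directed_edges == frozenset()
        assert cpdag.undirected_edges == {frozenset(("A", "B"))}

    def test_collider_directions_preserved(self):
        cpdag = dag_to_cpdag(COLLIDER)
        assert cpdag.directed_edges == {("X", "Y"), ("Z", "Y")}

    def test_complete_dag_is_fully_undirected(self):
        dag = Dag(
            ("A", "B", "C"),
            frozenset({("A", "B"), ("A", "C"), ("B", "C")}), {})
        cpdag = dag_to_cpdag(dag)
        assert cpdag.directed_edges == frozenset()
        assert len(cpdag.undirected_edges) == 3

    def test_matches_brute_force_class_enumeration_on_three_nodes(self):
        for dag in all_labeled_dags(3):
            cpdag = dag_to_cpdag(dag)
            directed, undirected = brute_force_cpdag(dag)
            assert set(cpdag.directed_edges) == directed
            assert set(cpdag.undirected_edges) == undirected

    def test_matches_brute_force_class_enumeration_on_four_nodes(self):
        for dag in all_labeled_dags(4):
            cpdag = dag_to_cpdag(dag)
            directed, undirected = brute_force_cpdag(dag)
            assert set(cpdag.directed_edges) == directed
            assert set(cpdag.undirected_edges) == undirected


class TestStructuralHammingDistance:
    def g(self, directed=(), undirected=(), nodes=("A", "B", "C")):
        return Cpdag(nodes, frozenset(directed),
                     frozenset(frozenset(p) for p in undirected))

    def test_identical_graphs_have_zero_distance(self):
        g = self.g(directed=[("A", "B")], undirected=[("B", "C")])
        assert structural_hamming_distance(g, g) == 0

    def test_extra_undirected_edge_counts_one(self):
        assert structural_hamming_distance(
            self.g(undirected=[("A", "B")]), self.g()) == 1

    def test_direction_mismatch_counts_one(self):
        assert structural_hamming_distance(
            self.g(directed=[("A", "B")]),
            self.g(undirected=[("A", "B")])) == 1
        assert structural_hamming_distance(
            self.g(directed=[("A", "B")]),
            self.g(directed=[("B", "A")])) == 1

    def test_requires_matching_node_sets(self):
        with pytest.raises(ValueError):
            structural_hamming_distance(
                self.g(), self.g(nodes=("A", "B", "D")))


class TestSummarize:
    def test_two_cause_collider_summary(self):
        g = Cpdag(("A", "B", "C", "D"),
                  frozenset({("A", "C"), ("B", "C")}), frozenset())
        s = summarize_cpdag(g)
        assert s.n_directed == 2
        assert s.n_undirected == 0
        assert s.n_connected_subgraphs == 1
        assert s.effect_only_nodes == ("C",)

    def test_empty_graph_summary(self):
        s = summarize_cpdag(Cpdag(("A", "B"), frozenset(), frozenset()))
        assert (s.n_directed, s.n_undirected, s.n_connected_subgraphs) == (0, 0, 0)
        assert s.effect_only_nodes == ()

    def test_undirected_pair_is_not_effect_only(self):
        g = Cpdag(("A", "B"), frozenset(), frozenset({frozenset(("A", "B"))}))
        s = summarize_cpdag(g)
        assert s.n_undirected == 1
        assert s.n_connected_subgraphs == 1
        assert s.effect_only_nodes == ()


class TestCpdagValidationAndIo:
    def test_pair_cannot_appear_in_both_edge_sets(self):
        with pytest.raises(ValueError):
            Cpdag(("A", "B"), frozenset({("A", "B")}),
                  frozenset({frozenset(("A", "B"))}))

    def test_tsv_round_trip(self, tmp_path):
        g = Cpdag(("A", "B", "C"), frozenset({("A", "B")}),
                  frozenset({frozenset(("B", "C"))}))
        path = tmp_path / "edges.tsv"
        write_cpdag_tsv(g, path)
        back = read_cpdag_tsv(path, g.nodes)
        assert back == g

    def test_dot_rendering_marks_undirected_edges(self):
        g = Cpdag(("A", "B", "C"), frozenset({("A", "B")}),
                  frozenset({frozenset(("B", "C"))}))
        dot = cpdag_to_dot(g)
        assert '"A" -> "B";' in dot
        assert "[dir=none]" in dot


class TestSampleBasedPc:
    def test_recovers_a_well_separated_collider_from_data(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = x + z + 0.5 * rng.normal(size=n)
        suff = suff_stat_from_observations(
            np.column_stack([x, y, z]), ["X", "Y", "Z"])
        cpdag = pc(suff, alpha=0.01)
        assert cpdag.directed_edges == {("X", "Y"), ("Z", "Y")}

    def test_max_cond_size_respects_small_samples(self):
        # n = 8 caps |S| at 3, keeping the Fisher-z preconditions valid
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 6))
        suff = suff_stat_from_observations(X)
        pc(suff, alpha=0.05)  # must not raise
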