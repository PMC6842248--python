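"""Spearman statistic, network construction, and the intersection screen."""

import itertools

import numpy as np
import pytest

from mycoscreen import synthetic
from mycoscreen.coexpression import (
    ExpressionMatrix,
    build_network,
    intersect_subnetworks,
    query_subnetwork,
    spearman_rho,
)


def classical_spearman(x, y):
    """Textbook 1 - 6*sum(d^2)/(n(n^2-1)) formula, tie-free vectors only."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = x.argsort().argsort() + 1
    ry = y.argsort().argsort() + 1
    d2 = ((rx - ry) ** 2).sum()
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([3, 1, 4, 1, 5], [3, 1, 4, 1, 5], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # sum d^2 = 2
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_matches_classical_formula_on_tie_free_vectors(self):
        rng = np.random.default_rng(42)
        for n in (5, 8, 20, 100):
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            assert spearman_rho(x, y) == pytest.approx(classical_spearman(x, y))

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho)
        assert spearman_rho(x, np.exp(y / 3)) == pytest.approx(rho)
        ranks = x.argsort().argsort().astype(float)
        assert spearman_rho(ranks, y) == pytest.approx(rho)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 12))
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x))

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]),  # constant
            ([1, 2, 3], [1, 2, 3, 4]),  # length mismatch
            ([1], [2]),  # too short
        ],
    )
    def test_rejects_degenerate_inputs(self, x, y):
        with pytest.raises(ValueError):
            spearman_rho(x, y)


def small_matrix(seed=0, n_genes=30, n_conditions=20):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        gene_ids=tuple(f"g{i}" for i in range(n_genes)),
        condition_ids=tuple(f"c{j}" for j in range(n_conditions)),
        values=rng.normal(size=(n_genes, n_conditions)),
    )


class TestExpressionMatrix:
    def test_rejects_missing_values(self):
        values = np.ones((3, 6))
        values[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(("a", "b", "c"), tuple("uvwxyz"), values)

    def test_rejects_too_few_conditions(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(("a",), ("c1", "c2"), np.ones((1, 2)))

    def test_tsv_round_trip(self, tmp_path):
        matrix = small_matrix(seed=5, n_genes=4, n_conditions=6)
        path = tmp_path / "expr.tsv"
        matrix.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        assert back.gene_ids == matrix.gene_ids
        assert back.condition_ids == matrix.condition_ids
        np.testing.assert_allclose(back.values, matrix.values)


class TestBuildNetwork:
    def test_noise_free_module_is_complete_subgraph(self):
        module = synthetic.ModuleSpec("m", tuple(f"m{i}" for i in range(10)), 0.9)
        matrix = synthetic.generate_expression_matrix(
            n_genes=30, n_conditions=20, modules=[module], noise_sd=0.0, seed=1
        )
        network = build_network(matrix, cutoff=0.5)
        members = set(module.member_genes)
        module_edges = [
            (a, b) for a, b in network.graph.edges if a in members and b in members
        ]
        assert len(module_edges) == 45  # C(10, 2)

    def test_cutoff_above_null_maximum_gives_empty_network(self):
        matrix = small_matrix(seed=2, n_genes=15, n_conditions=12)
        max_rho = max(
            spearman_rho(matrix.values[i], matrix.values[j])
            for i, j in itertools.combinations(range(matrix.n_genes), 2)
        )
        assert max_rho < 1
        network = build_network(matrix, cutoff=max_rho)
        assert network.n_edges == 0

    def test_edge_requires_strictly_greater_rho(self):
        # rank permutation with sum d^2 = 20 gives rho = 0 exactly (integer
        # rank dot product is 0), probing the boundary at cutoff 0
        values = np.array([[1.0, 2, 3, 4, 5], [2, 5, 3, 1, 4]], dtype=float)
        matrix = ExpressionMatrix(("a", "b"), tuple("vwxyz"), values)
        assert spearman_rho(values[0], values[1]) == 0.0
        network = build_network(matrix, cutoff=0.0)
        assert not network.graph.has_edge("a", "b")

    def test_invariant_under_condition_permutation(self):
        matrix = small_matrix(seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_conditions)
        permuted = ExpressionMatrix(
            matrix.gene_ids,
            tuple(matrix.condition_ids[p] for p in perm),
            matrix.values[:, perm],
        )
        edges = lambda net: {frozenset(e) for e in net.graph.edges}  # noqa: E731
        assert edges(build_network(matrix, 0.3)) == edges(build_network(permuted, 0.3))

    def test_raising_cutoff_never_adds_edges(self):
        matrix = small_matrix(seed=4)
        edge_sets = [
            {frozenset(e) for e in build_network(matrix, c).graph.edges}
            for c in (0.0, 0.3, 0.6, 0.9)
        ]
        for lower, higher in zip(edge_sets, edge_sets[1:]):
            assert higher <= lower

    def test_screen_mode_matches_full_network_on_query_rows(self):
        matrix = small_matrix(seed=6)
        full = build_network(matrix, 0.3)
        screen = build_network(matrix, 0.3, query_restriction=["g0", "g5"])
        for q in ("g0", "g5"):
            assert query_subnetwork(screen, q) == query_subnetwork(full, q)

    def test_rejects_bad_cutoff(self):
        matrix = small_matrix()
        for cutoff in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                build_network(matrix, cutoff)


class TestQueryAndIntersection:
    def test_isolated_node_has_empty_neighbourhood(self):
        matrix = small_matrix(seed=8)
        network = build_network(matrix, 0.99)
        assert query_subnetwork(network, "g0") == set()

    def test_module_member_sees_other_members(self):
        module = synthetic.ModuleSpec("m", tuple(f"m{i}" for i in range(10)), 0.9)
        matrix = synthetic.generate_expression_matrix(
            n_genes=12, n_conditions=20, modules=[module], noise_sd=0.0, seed=1
        )
        network = build_network(matrix, cutoff=0.5)
        assert query_subnetwork(network, "m0") >= set(module.member_genes) - {"m0"}

    def test_neighbourhood_symmetry(self):
        matrix = small_matrix(seed=9)
        network = build_network(matrix, 0.2)
        for a in matrix.gene_ids:
            for b in query_subnetwork(network, a):
                assert a in query_subnetwork(network, b)

    def test_unknown_gene_named_in_error(self):
        matrix = small_matrix()
        network = build_network(matrix, 0.5)
        with pytest.raises(KeyError, match="nope"):
            query_subnetwork(network, "nope")

    def test_six_queries_in_noise_free_module_recover_all_other_members(self):
        members = tuple(f"m{i}" for i in range(50))
        module = synthetic.ModuleSpec("m", members, 0.9)
        matrix = synthetic.generate_expression_matrix(
            n_genes=80, n_conditions=20, modules=[module], noise_sd=0.0, seed=2
        )
        network = build_network(matrix, cutoff=0.5)
        result = intersect_subnetworks(network, members[:6])
        assert result.intersection == frozenset(members[6:])
        assert result.intersection_size == 44

    def test_matches_brute_force_intersection_on_noisy_fixture(self):
        matrix = small_matrix(seed=10, n_genes=40, n_conditions=15)
        queries = ["g1", "g2", "g3"]
        network = build_network(matrix, 0.2)
        result = intersect_subnetworks(network, queries)
        # independent recomputation: per-pair spearman, then set intersection
        expected = None
        for q in queries:
            neigh = {
                g
                for g in matrix.gene_ids
                if g != q and spearman_rho(matrix.row(q), matrix.row(g)) > 0.2
            }
            expected = neigh if expected is None else expected & neigh
        expected -= set(queries)
        assert result.intersection == expected

    def test_adding_queries_never_grows_intersection(self):
        matrix = small_matrix(seed=12, n_genes=25, n_conditions=15)
        network = build_network(matrix, 0.1)
        queries = ["g0", "g1", "g2", "g3"]
        sizes = [
            intersect_subnetworks(network, queries[: k + 1]).intersection_size
            for k in range(len(queries))
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_disjoint_neighbourhoods_intersect_empty(self):
        modules = [
            synthetic.ModuleSpec("a", ("a1", "a2", "a3"), 0.9),
            synthetic.ModuleSpec("b", ("b1", "b2", "b3"), 0.9),
        ]
        matrix = synthetic.generate_expression_matrix(
            n_genes=6, n_conditions=30, modules=modules, noise_sd=0.0, seed=3
        )
        network = build_network(matrix, cutoff=0.95)
        result = intersect_subnetworks(network, ["a1", "b1"])
        assert result.intersection == frozenset()

    def test_empty_query_list_rejected(self):
        matrix = small_matrix()
        network = build_network(matrix, 0.5)
        with pytest.raises(ValueError):
            intersect_subnetworks(network, [])
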