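import networkx as nx
import numpy as np
import pytest
from sklearn.base import clone

from mvgbin.containers import GraphView, LabelState
from mvgbin.propagation import (
    BinRefiner,
    MultiViewLabelPropagation,
    build_laplacian,
    multi_view_propagate,
    normalized_laplacian,
    remove_ambiguous,
    remove_ambiguous_labels,
    run_pipeline,
    solve_harmonic,
    update_alpha,
)

from .conftest import make_catalog, random_graph, random_labels


# --------------------------------------------------------------------------
# independent dense oracles
# --------------------------------------------------------------------------

def dense_normalized_laplacian(W: np.ndarray) -> np.ndarray:
    d = W.sum(axis=1)
    inv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.diag((d > 0).astype(float)) - inv[:, None] * W * inv[None, :]
    return L


def dense_harmonic(Ws, alpha, y, s) -> np.ndarray:
    """Classical clamped harmonic propagation, dense, per component."""
    n = Ws[0].shape[0]
    L = sum(a * dense_normalized_laplacian(W) for a, W in zip(alpha, Ws))
    union = (sum(Ws) > 0).astype(int)
    g = nx.from_numpy_array(union)
    F = np.zeros((n, s))
    labeled = np.flatnonzero(y >= 0)
    F[labeled, y[labeled]] = 1.0
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        lab = [v for v in comp if y[v] >= 0]
        unl = [v for v in comp if y[v] < 0]
        if not lab or not unl:
            continue
        A = L[np.ix_(unl, unl)]
        B = L[np.ix_(unl, lab)]
        F[unl] = np.linalg.solve(A, -B @ F[lab])
    return F


def bfs_ambiguity_oracle(W: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-vertex BFS oracle: labels removed when the closest labeled
    vertices include a different label."""
    g = nx.from_numpy_array(W)
    y_new = y.copy()
    for v in np.flatnonzero(y >= 0):
        dist = nx.single_source_shortest_path_length(g, v)
        others = [(d, u) for u, d in dist.items() if u != v and y[u] >= 0]
        if not others:
            continue
        dmin = min(d for d, _ in others)
        closest_labels = {y[u] for d, u in others if d == dmin}
        if closest_labels - {y[v]}:
            y_new[v] = -1
    return y_new


# --------------------------------------------------------------------------
# Laplacian
# --------------------------------------------------------------------------

class TestNormalizedLaplacian:
    def test_single_edge_pair(self):
        g = GraphView(make_catalog(2), frozenset({(0, 1)}))
        L = normalized_laplacian(g.adjacency()).toarray()
        np.testing.assert_allclose(L, [[1, -1], [-1, 1]])

    def test_triangle(self):
        g = GraphView(make_catalog(3), frozenset({(0, 1), (1, 2), (0, 2)}))
        L = normalized_laplacian(g.adjacency()).toarray()
        np.testing.assert_allclose(np.diag(L), 1.0)
        np.testing.assert_allclose(L[0, 1], -0.5)

    def test_isolated_vertex_row_all_zero(self):
        g = GraphView(make_catalog(3), frozenset({(0, 1)}))
        L = normalized_laplacian(g.adjacency()).toarray()
        np.testing.assert_array_equal(L[2], 0.0)

    def test_matches_dense_oracle_and_blocks(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 40, 0.15)
        W = g.adjacency().toarray()
        labeled = np.array([3, 7, 21])
        lv = build_laplacian(g, labeled)
        Ld = dense_normalized_laplacian(W)
        np.testing.assert_allclose(lv.laplacian.toarray(), Ld, atol=1e-12)
        np.testing.assert_allclose(
            lv.L_ul.toarray(), lv.L_lu.toarray().T, atol=1e-15
        )
        unl = np.setdiff1d(np.arange(40), labeled)
        np.testing.assert_allclose(lv.L_uu.toarray(), Ld[np.ix_(unl, unl)])

    def test_eigenvalues_within_zero_two(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, 30, 0.2)
        vals = np.linalg.eigvalsh(normalized_laplacian(g.adjacency()).toarray())
        assert vals.min() > -1e-10 and vals.max() < 2 + 1e-10


# --------------------------------------------------------------------------
# harmonic solve + alpha
# --------------------------------------------------------------------------

class TestSolveHarmonic:
    def test_single_label_component_assigns_positive_mass(self):
        # path a(A) - x - b(A): x must get positive score for A
        g = GraphView(make_catalog(3), frozenset({(0, 1), (1, 2)}))
        labeled = np.array([0, 2])
        lv = build_laplacian(g, labeled)
        F_u = solve_harmonic([lv], [1.0], np.array([[1.0], [1.0]]))
        assert F_u.shape == (1, 1) and F_u[0, 0] > 0

    def test_two_label_path_hand_solution(self):
        # path a(A)-x-y-b(B); 2x2 system solved by hand:
        # L_uu = [[1,-1/2],[-1/2,1]], rhs = [[1/r2,0],[0,1/r2]]
        g = GraphView(make_catalog(4), frozenset({(0, 1), (1, 2), (2, 3)}))
        lv = build_laplacian(g, np.array([0, 3]))
        F_u = solve_harmonic([lv], [1.0], np.eye(2))
        r2 = np.sqrt(2.0)
        inv = np.array([[1, 0.5], [0.5, 1]]) / 0.75
        expected = inv @ np.array([[1 / r2, 0], [0, 1 / r2]])
        np.testing.assert_allclose(F_u, expected, atol=1e-10)
        assert F_u[0, 0] > F_u[0, 1] and F_u[1, 1] > F_u[1, 0]
        np.testing.assert_allclose(F_u[0, 0], F_u[1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        g1 = random_graph(rng, n, 0.1)
        g2 = random_graph(rng, n, 0.05, catalog=g1.catalog)
        y = random_labels(rng, g1.catalog, max(2, n // 8), 3).assignment
        labeled = np.flatnonzero(y >= 0)
        Y_l = np.zeros((labeled.size, 3))
        Y_l[np.arange(labeled.size), y[labeled]] = 1.0
        alpha = [0.7, 0.3]
        lvs = [build_laplacian(g1, labeled), build_laplacian(g2, labeled)]
        F_u = solve_harmonic(lvs, alpha, Y_l)
        F_dense = dense_harmonic(
            [g1.adjacency().toarray(), g2.adjacency().toarray()], alpha, y, 3
        )
        np.testing.assert_allclose(F_u, F_dense[lvs[0].unlabeled], atol=1e-6)


class TestUpdateAlpha:
    def test_unit_trace_gives_half(self):
        # single vertex with L=[[1]] and F=[[1]]: trace 1 -> alpha 1/2
        L = np.array([[1.0]])
        import scipy.sparse as sp

        assert update_alpha([sp.csr_matrix(L)], np.array([[1.0]]))[0] == 0.5

    def test_quarter_trace_gives_one(self):
        import scipy.sparse as sp

        L = np.array([[0.25]])
        assert update_alpha([sp.csr_matrix(L)], np.array([[1.0]]))[0] == 1.0

    def test_vanishing_trace_capped(self):
        import scipy.sparse as sp

        L = sp.csr_matrix((2, 2))
        assert update_alpha([L], np.ones((2, 1)), alpha_max=1e6)[0] == 1e6

    def test_matches_dense_arithmetic(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 25, 0.2)
        F = rng.random((25, 3))
        lv = build_laplacian(g, np.array([0, 1]))
        got = update_alpha([lv], F)[0]
        tr = float(np.trace(F.T @ dense_normalized_laplacian(g.adjacency().toarray()) @ F))
        np.testing.assert_allclose(got, 1.0 / (2.0 * np.sqrt(tr)), rtol=1e-10)


# --------------------------------------------------------------------------
# ambiguity removal
# --------------------------------------------------------------------------

class TestRemoveAmbiguous:
    def test_three_vertex_path_mutual_ambiguity(self):
        # path u(A) - v(A) - w(B): the middle vertex sees both labels at
        # distance 1 and is removed; w's closest labeled vertex is v with a
        # different label, so w goes too; u agrees with its closest labeled
        # vertex v (marks are computed against the input labeling) and stays.
        g = GraphView(make_catalog(3), frozenset({(0, 1), (1, 2)}))
        y = np.array([0, 0, 1])
        y_new, marked = remove_ambiguous_labels(g.adjacency(), y)
        assert set(marked) == {1, 2}
        np.testing.assert_array_equal(y_new, [0, -1, -1])

    def test_agreeing_neighbors_untouched(self):
        g = GraphView(make_catalog(2), frozenset({(0, 1)}))
        y_new, marked = remove_ambiguous_labels(g.adjacency(), np.array([1, 1]))
        assert marked.size == 0 and (y_new == [1, 1]).all()

    def test_isolated_labeled_vertex_kept(self):
        g = GraphView(make_catalog(3), frozenset({(0, 1)}))
        y_new, _ = remove_ambiguous_labels(g.adjacency(), np.array([-1, -1, 2]))
        assert y_new[2] == 2

    def test_removal_is_simultaneous_not_sequential(self):
        # star: center B, leaves A,A. Leaves see only B at distance 1 ->
        # ambiguous; center sees {A,A} -> ambiguous. All three go at once.
        g = GraphView(make_catalog(3), frozenset({(0, 1), (0, 2)}))
        y_new, marked = remove_ambiguous_labels(g.adjacency(), np.array([1, 0, 0]))
        assert set(marked) == {0, 1, 2}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        g = random_graph(rng, n, 0.08)
        y = random_labels(rng, g.catalog, max(2, n // 3), 4).assignment
        got, _ = remove_ambiguous_labels(g.adjacency(), y)
        expected = bfs_ambiguity_oracle(g.adjacency().toarray(), y)
        np.testing.assert_array_equal(got, expected)

    def test_state_wrapper(self):
        g = GraphView(make_catalog(3), frozenset({(0, 1), (1, 2)}))
        st = LabelState(g.catalog, np.array([0, 0, 1]), ("a", "b"))
        assert remove_ambiguous(g, st).n_labeled == 1


# --------------------------------------------------------------------------
# multi-view propagation
# --------------------------------------------------------------------------

class TestMultiViewPropagation:
    def test_identical_views_reduce_to_single_view(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, 50, 0.1)
        y = random_labels(rng, g.catalog, 8, 2).assignment
        est = MultiViewLabelPropagation().fit([g, g], y)
        F_dense = dense_harmonic([g.adjacency().toarray()] * 1, [1.0], y, 2)
        pred = np.where(F_dense.max(axis=1) > 1e-12, F_dense.argmax(axis=1), -1)
        pred[y >= 0] = y[y >= 0]
        np.testing.assert_array_equal(est.transduction_, pred)
        for a in est.alpha_trace_:
            np.testing.assert_allclose(a[0], a[1], rtol=1e-12)

    def test_empty_second_view_reduces_to_single_view(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, 40, 0.12)
        empty = GraphView(g.catalog, frozenset(), "pe")
        y = random_labels(rng, g.catalog, 6, 2).assignment
        est = MultiViewLabelPropagation().fit([g, empty], y)
        single = MultiViewLabelPropagation().fit([g], y)
        np.testing.assert_array_equal(est.transduction_, single.transduction_)
        assert est.alpha_[1] == est.alpha_max  # empty view trace vanishes

    def test_labeled_rows_stay_clamped(self):
        rng = np.random.default_rng(9)
        g1 = random_graph(rng, 30, 0.15)
        g2 = random_graph(rng, 30, 0.1, catalog=g1.catalog)
        y = random_labels(rng, g1.catalog, 6, 3).assignment
        est = MultiViewLabelPropagation().fit([g1, g2], y)
        lab = np.flatnonzero(y >= 0)
        onehot = np.zeros((lab.size, est.classes_.size))
        onehot[np.arange(lab.size), y[lab]] = 1.0
        np.testing.assert_array_equal(est.label_distributions_[lab], onehot)
        np.testing.assert_array_equal(est.transduction_[lab], y[lab])

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(10)
        g1 = random_graph(rng, 60, 0.1)
        g2 = random_graph(rng, 60, 0.05, catalog=g1.catalog)
        y = random_labels(rng, g1.catalog, 10, 3).assignment
        est = MultiViewLabelPropagation().fit([g1, g2], y)
        diffs = np.diff(est.objective_trace_)
        assert (diffs <= 1e-9).all()

    def test_vertex_permutation_invariance(self):
        rng = np.random.default_rng(11)
        n = 40
        g1 = random_graph(rng, n, 0.12)
        g2 = random_graph(rng, n, 0.06, catalog=g1.catalog)
        y = random_labels(rng, g1.catalog, 8, 2).assignment
        base = MultiViewLabelPropagation().fit([g1, g2], y).transduction_

        perm = rng.permutation(n)
        inv = np.argsort(perm)

        def permuted(g):
            edges = frozenset(
                (min(inv[a], inv[b]), max(inv[a], inv[b])) for a, b in g.edges
            )
            return GraphView(g.catalog, edges, g.kind)

        yp = y[perm]
        got = MultiViewLabelPropagation().fit([permuted(g1), permuted(g2)], yp)
        np.testing.assert_array_equal(got.transduction_[inv], base)

    def test_fig2_style_dead_end_rescue(self):
        # 12 vertices: cluster A {0..4}, cluster B {5..9}, dead end {10,11}
        # joined to A only by PE edges; seeds at 1 (A) and 6 (B).
        cat = make_catalog(12)
        asm = GraphView(cat, frozenset(
            {(0, 1), (1, 2), (2, 3), (3, 4), (0, 2),
             (5, 6), (6, 7), (7, 8), (8, 9), (5, 7), (10, 11)}
        ))
        pe = GraphView(cat, frozenset({(2, 10), (3, 11)}), "pe")
        y = np.full(12, -1)
        y[1], y[6] = 0, 1
        st = LabelState(cat, y, ("A", "B"))
        final, alpha, trace = multi_view_propagate(asm, pe, st)
        assert final.assignment[10] == 0 and final.assignment[11] == 0
        # assembly-only ablation cannot reach the dead end at all
        empty = GraphView(cat, frozenset(), "pe")
        only, _, _ = multi_view_propagate(asm, empty, st)
        assert only.assignment[10] == -1 and only.assignment[11] == -1

    def test_isolated_everywhere_stays_unlabeled(self):
        cat = make_catalog(3)
        g1 = GraphView(cat, frozenset({(0, 1)}))
        g2 = GraphView(cat, frozenset(), "pe")
        st = LabelState(cat, np.array([0, -1, -1]), ("a",))
        final, _, _ = multi_view_propagate(g1, g2, st)
        assert final.assignment[2] == -1 and final.assignment[1] == 0

    def test_no_labels_is_an_error(self):
        g = GraphView(make_catalog(3), frozenset({(0, 1)}))
        with pytest.raises(ValueError, match="no initial labels"):
            MultiViewLabelPropagation().fit([g], np.array([-1, -1, -1]))


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self):
        est = MultiViewLabelPropagation(tol=1e-5, max_iter=17)
        params = est.get_params()
        assert params["tol"] == 1e-5 and params["max_iter"] == 17
        c = clone(est)
        assert c.get_params() == params
        c.set_params(max_iter=3)
        assert c.max_iter == 3 and est.max_iter == 17

    def test_fit_predict_matches_transduction(self):
        rng = np.random.default_rng(12)
        g = random_graph(rng, 20, 0.2)
        y = random_labels(rng, g.catalog, 4, 2).assignment
        est = MultiViewLabelPropagation()
        pred = est.fit_predict([g], y)
        np.testing.assert_array_equal(pred, est.transduction_)
        np.testing.assert_array_equal(est.predict(), pred)

    def test_refiner_exposes_round_counts(self):
        rng = np.random.default_rng(13)
        g1 = random_graph(rng, 30, 0.15)
        g2 = random_graph(rng, 30, 0.05, catalog=g1.catalog)
        y = random_labels(rng, g1.catalog, 8, 2).assignment
        ref = BinRefiner().fit([g1, g2], y)
        assert hasattr(ref, "removed_round1_") and hasattr(ref, "removed_round2_")
        assert ref.alpha_.shape == (2,)


class TestRunPipeline:
    def test_reduces_to_single_view_when_pe_empty_and_unambiguous(self):
        cat = make_catalog(5)
        g1 = GraphView(cat, frozenset({(0, 1), (1, 2), (3, 4)}))
        empty = GraphView(cat, frozenset(), "pe")
        st = LabelState(cat, np.array([0, -1, -1, 1, -1]), ("a", "b"))
        final, report = run_pipeline(g1, empty, st)
        single, _, _ = multi_view_propagate(g1, empty, st)
        np.testing.assert_array_equal(final.assignment, single.assignment)
        assert report["removed_round1"] == 0

    def test_all_labels_mutually_ambiguous_raises_with_guidance(self):
        cat = make_catalog(2)
        g1 = GraphView(cat, frozenset({(0, 1)}))
        g2 = GraphView(cat, frozenset(), "pe")
        st = LabelState(cat, np.array([0, 1]), ("a", "b"))
        with pytest.raises(ValueError, match="ambiguous"):
            run_pipeline(g1, g2, st)

    def test_refinement_not_worse_than_propagation_alone(self, tmp_path):
        # separated scenario with 10% label noise: correctness among labeled
        # predictions must not drop below the no-refinement ablation
        from mvgbin.simulate import ScenarioSpec, generate_scenario

        full, abl = [], []
        for seed in range(3):
            b = generate_scenario(
                ScenarioSpec(seed=seed, p_inter=0.0, pe_p_inter=0.0,
                             label_error_rate=0.1),
                tmp_path / str(seed),
            )
            y0 = b.initial.assignment
            unl = y0 == -1
            truth = b.truth_species
            final, _ = run_pipeline(b.assembly_view, b.pe_view, b.initial)
            prop = MultiViewLabelPropagation().fit(
                [b.assembly_view, b.pe_view], y0
            ).transduction_

            def correct_among_labeled(pred):
                mask = unl & (pred != -1)
                return (pred[mask] == truth[mask]).mean()

            full.append(correct_among_labeled(final.assignment))
            abl.append(correct_among_labeled(prop))
        assert np.mean(full) >= np.mean(abl) - 1e-12
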