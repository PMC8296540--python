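"""Auto-weighted multi-view label propagation and ambiguity removal.

The binning refinement solves, over ``m`` graph views sharing one vertex set,

    argmin_{F_u}  sum_i sqrt( tr(F^T L_i F) )   s.t.  F_l = Y_l,

where ``L_i = D_i^{-1/2} (D_i - W_i) D_i^{-1/2}`` is the normalized Laplacian
of view ``i`` and ``F = [F_l; F_u]`` is an n x s label indicator with the
labeled block clamped to the one-hot initial labels ``Y_l``.  Introducing
per-view weights turns this into alternating updates:

    F_u      <-  solve  L_uu F_u = -L_ul Y_l,   L = sum_i alpha_i L_i
    alpha_i  <-  1 / ( 2 sqrt( tr(F^T L_i F) ) )

with ``alpha_i`` initialized to ``1/m``.  A view that fits the current labels
well (small trace) earns a larger weight, so graph reliability is learned
rather than set by hand.  Final labels are the row-wise argmax of ``F``;
vertices unreachable from every label keep no label.

Isolated vertices (degree 0 in a view) get an all-zero Laplacian row in that
view — the view is simply uninformative there — which keeps the linear system
solvable per connected component of the union graph.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, ClassifierMixin

from .containers import UNLABELED, GraphView, LabelState
from .pe_graph import combine_graphs

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100
DEFAULT_ALPHA_MAX = 1e6
_RESIDUAL_RTOL = 1e-8


# ---------------------------------------------------------------------------
# linear-algebra primitives
# ---------------------------------------------------------------------------

def normalized_laplacian(adjacency) -> sp.csr_matrix:
    """``D^{-1/2} (D - W) D^{-1/2}`` with all-zero rows for isolated vertices."""
    W = sp.csr_matrix(adjacency, dtype=float)
    degree = np.asarray(W.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(degree)
    nz = degree > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(degree[nz])
    Dinv = sp.diags(inv_sqrt)
    eye = sp.diags(nz.astype(float))  # diagonal 1 only where degree > 0
    return (eye - Dinv @ W @ Dinv).tocsr()


@dataclass
class LaplacianView:
    """Normalized Laplacian of one view with its labeled/unlabeled partition.

    Blocks correspond to a labeled-first vertex permutation: ``L_ll`` over the
    labeled ordinals, ``L_uu`` over the unlabeled ones, with
    ``L_ul = L_lu.T``.
    """

    adjacency: sp.csr_matrix
    laplacian: sp.csr_matrix
    labeled: np.ndarray
    unlabeled: np.ndarray

    @property
    def L_ll(self) -> sp.csr_matrix:
        return self.laplacian[self.labeled][:, self.labeled]

    @property
    def L_lu(self) -> sp.csr_matrix:
        return self.laplacian[self.labeled][:, self.unlabeled]

    @property
    def L_ul(self) -> sp.csr_matrix:
        return self.laplacian[self.unlabeled][:, self.labeled]

    @property
    def L_uu(self) -> sp.csr_matrix:
        return self.laplacian[self.unlabeled][:, self.unlabeled]


def build_laplacian(graph: GraphView | sp.spmatrix, labeled: np.ndarray) -> LaplacianView:
    """Build the normalized Laplacian of a view and partition it.

    ``labeled`` lists the labeled vertex ordinals; the unlabeled block keeps
    the remaining vertices in ascending order.
    """
    W = graph.adjacency() if isinstance(graph, GraphView) else sp.csr_matrix(graph)
    labeled = np.asarray(labeled, dtype=np.int64)
    mask = np.zeros(W.shape[0], dtype=bool)
    mask[labeled] = True
    unlabeled = np.flatnonzero(~mask)
    return LaplacianView(W, normalized_laplacian(W), labeled, unlabeled)


def _harmonic_solve(
    laplacians: list[sp.csr_matrix],
    union_adj: sp.csr_matrix,
    alpha: np.ndarray,
    labeled: np.ndarray,
    Y_l: np.ndarray,
) -> np.ndarray:
    """Solve the clamped combined-Laplacian system per connected component.

    Returns the full ``n x s`` matrix ``F`` with labeled rows set to ``Y_l``
    and rows of components without any labeled vertex left at zero.
    """
    n = laplacians[0].shape[0]
    s = Y_l.shape[1]
    L = sum(a * Lap for a, Lap in zip(alpha, laplacians)).tocsr()
    F = np.zeros((n, s))
    F[labeled] = Y_l
    labeled_mask = np.zeros(n, dtype=bool)
    labeled_mask[labeled] = True
    _, comp = connected_components(union_adj, directed=False)
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        lab = members[labeled_mask[members]]
        unl = members[~labeled_mask[members]]
        if lab.size == 0 or unl.size == 0:
            continue
        A = L[unl][:, unl].tocsc()
        B = L[unl][:, lab]
        rhs = -B @ F[lab]
        X = spsolve(A, sp.csc_matrix(rhs))
        X = np.asarray(X.todense() if sp.issparse(X) else X).reshape(unl.size, s)
        residual = np.linalg.norm(A @ X - rhs)
        if residual > _RESIDUAL_RTOL * max(1.0, np.linalg.norm(rhs)):
            raise RuntimeError(
                "harmonic system solve failed on a labeled component "
                f"(residual {residual:.2e}); the Laplacian block is singular"
            )
        F[unl] = X
    return F


def solve_harmonic(
    views: list[LaplacianView], alpha, Y_l: np.ndarray
) -> np.ndarray:
    """Clamped solve of the weighted multi-view system; returns ``F_u``.

    All views must share the same labeled/unlabeled partition.  Rows are in
    the order of ``views[0].unlabeled``.
    """
    first = views[0]
    for v in views[1:]:
        if not np.array_equal(v.labeled, first.labeled):
            raise ValueError("views must share the labeled-first partition")
    union = sum(v.adjacency for v in views)
    F = _harmonic_solve(
        [v.laplacian for v in views], union.tocsr(), np.asarray(alpha, float),
        first.labeled, np.asarray(Y_l, float),
    )
    return F[first.unlabeled]


def view_traces(laplacians: list[sp.csr_matrix], F: np.ndarray) -> np.ndarray:
    """``tr(F^T L_i F)`` for each view (clipped at 0 against round-off)."""
    return np.array([max(float(np.sum(F * (L @ F))), 0.0) for L in laplacians])


def update_alpha(
    views: list[LaplacianView] | list[sp.csr_matrix],
    F: np.ndarray,
    alpha_max: float = DEFAULT_ALPHA_MAX,
) -> np.ndarray:
    """Per-view weights ``alpha_i = 1 / (2 sqrt(tr(F^T L_i F)))``.

    A vanishing trace (view perfectly consistent with F) would blow up the
    weight; it is capped at ``alpha_max`` instead.  Weights are deliberately
    not renormalized.
    """
    laps = [v.laplacian if isinstance(v, LaplacianView) else v for v in views]
    traces = view_traces(laps, F)
    alpha = np.empty(len(laps))
    for i, tr in enumerate(traces):
        root = np.sqrt(tr)
        alpha[i] = alpha_max if root <= 1.0 / (2.0 * alpha_max) else 1.0 / (2.0 * root)
    return alpha


# ---------------------------------------------------------------------------
# ambiguity removal
# ---------------------------------------------------------------------------

def remove_ambiguous_labels(
    adjacency, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop labels that disagree with their closest labeled neighbourhood.

    For every labeled vertex ``v``, a breadth-first search finds the minimum
    hop distance to any *other* labeled vertex in ``v``'s component; ``v`` is
    ambiguous when any label at that distance differs from ``v``'s own.  All
    marks are computed against the input labeling and removed simultaneously.
    Labeled vertices with no labeled companion in their component are kept.

    Returns ``(y_cleaned, marked_indices)``.
    """
    W = sp.csr_matrix(adjacency)
    y = np.asarray(y, dtype=np.int64)
    n = W.shape[0]
    indptr, indices = W.indptr, W.indices
    labeled = np.flatnonzero(y != UNLABELED)
    labeled_set = y != UNLABELED
    marked = []
    for v in labeled:
        visited = np.zeros(n, dtype=bool)
        visited[v] = True
        frontier = [v]
        ambiguous = False
        found = False
        while frontier and not found:
            nxt = []
            for u in frontier:
                for w in indices[indptr[u]:indptr[u + 1]]:
                    if not visited[w]:
                        visited[w] = True
                        nxt.append(w)
            if not nxt:
                break
            hits = [w for w in nxt if labeled_set[w]]
            if hits:
                found = True
                ambiguous = any(y[w] != y[v] for w in hits)
            frontier = nxt
        if ambiguous:
            marked.append(v)
    y_new = y.copy()
    marked = np.asarray(marked, dtype=np.int64)
    y_new[marked] = UNLABELED
    return y_new, marked


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_adjacency(view) -> sp.csr_matrix:
    W = view.adjacency() if isinstance(view, GraphView) else sp.csr_matrix(view, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("adjacency matrices must be square")
    if (W != W.T).nnz:
        raise ValueError("adjacency matrices must be symmetric")
    W = W.tolil()
    W.setdiag(0)  # propagation ignores self-loops
    W = W.tocsr()
    W.eliminate_zeros()
    return W


def _validate_views(X) -> list[sp.csr_matrix]:
    if isinstance(X, (GraphView, sp.spmatrix, np.ndarray)):
        X = [X]
    views = [_as_adjacency(v) for v in X]
    if not views:
        raise ValueError("at least one graph view is required")
    n = views[0].shape[0]
    for v in views[1:]:
        if v.shape[0] != n:
            raise ValueError("all views must share the same vertex set")
    return views


class MultiViewLabelPropagation(ClassifierMixin, BaseEstimator):
    """Transductive semi-supervised classifier over multiple graph views.

    Fit on ``X = [W_1, ..., W_m]`` (square symmetric adjacency matrices or
    :class:`~mvgbin.containers.GraphView` objects over one shared vertex set)
    and a label vector ``y`` with ``-1`` marking unlabeled vertices.  View
    weights and the harmonic label scores are updated alternately until the
    weights stabilize.

    Parameters
    ----------
    tol : float
        Convergence threshold on the maximum relative change of the view
        weights between iterations.
    max_iter : int
        Iteration cap for the alternating updates.
    alpha_max : float
        Cap applied to a view weight when its trace term vanishes.

    Attributes
    ----------
    classes_ : ndarray
        Sorted distinct input labels (excluding -1).
    alpha_ : ndarray of shape (m,)
        Learned view weights.
    label_distributions_ : ndarray of shape (n, s)
        Final score matrix ``F`` (labeled rows one-hot).
    transduction_ : ndarray of shape (n,)
        Predicted label per vertex; -1 where no label is reachable.
    objective_trace_ : list of float
        ``sum_i sqrt(tr(F^T L_i F))`` after each harmonic solve.
    n_iter_ : int
        Number of alternating iterations performed.
    """

    def __init__(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        alpha_max: float = DEFAULT_ALPHA_MAX,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_max = alpha_max

    def fit(self, X, y):
        views = _validate_views(X)
        n = views[0].shape[0]
        y = np.asarray(y)
        if y.shape != (n,):
            raise ValueError(f"y must have shape ({n},), got {y.shape}")
        self.classes_ = np.unique(y[y != UNLABELED])
        if self.classes_.size == 0:
            raise ValueError("no initial labels: at least one vertex must be labeled")
        s = self.classes_.size
        class_index = {c: k for k, c in enumerate(self.classes_)}
        labeled = np.flatnonzero(y != UNLABELED)
        Y_l = np.zeros((labeled.size, s))
        Y_l[np.arange(labeled.size), [class_index[c] for c in y[labeled]]] = 1.0

        laplacians = [normalized_laplacian(W) for W in views]
        union = sum(views).tocsr()
        m = len(views)
        alpha = np.full(m, 1.0 / m)
        trace_log: list[float] = []
        alpha_log: list[np.ndarray] = []
        n_iter = 0
        F = None
        for n_iter in range(1, self.max_iter + 1):
            F = _harmonic_solve(laplacians, union, alpha, labeled, Y_l)
            traces = view_traces(laplacians, F)
            trace_log.append(float(np.sum(np.sqrt(traces))))
            new_alpha = update_alpha(laplacians, F, self.alpha_max)
            alpha_log.append(new_alpha.copy())
            rel = np.max(np.abs(new_alpha - alpha) / np.maximum(np.abs(alpha), 1e-300))
            alpha = new_alpha
            if rel < self.tol:
                break

        self.alpha_ = alpha
        self.alpha_trace_ = alpha_log
        self.objective_trace_ = trace_log
        self.n_iter_ = n_iter
        self.label_distributions_ = F

        transduction = np.full(n, UNLABELED, dtype=y.dtype if y.dtype.kind == "i" else np.int64)
        reachable = F.max(axis=1) > 1e-12
        transduction[reachable] = self.classes_[np.argmax(F[reachable], axis=1)]
        transduction[labeled] = y[labeled]  # clamped vertices keep their input labels
        self.transduction_ = transduction
        return self

    def predict(self, X=None):
        """Return the transductive labels (the fitted vertex set only)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "transduction_")
        return self.transduction_

    def fit_predict(self, X, y):
        return self.fit(X, y).transduction_


class BinRefiner(ClassifierMixin, BaseEstimator):
    """Full binning-refinement pipeline over assembly and PE views.

    Three stages: (1) ambiguous labels are removed on the first (assembly)
    view only, keeping as many labels as possible before propagation;
    (2) auto-weighted multi-view propagation labels the remaining vertices;
    (3) a second ambiguity-removal round runs on the union of all views,
    stripping propagated labels that conflict locally.  Vertices may end up
    unlabeled in the final output.

    Attributes mirror :class:`MultiViewLabelPropagation`, plus
    ``removed_round1_`` / ``removed_round2_`` (vertex ordinals whose labels
    each round dropped).
    """

    def __init__(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        alpha_max: float = DEFAULT_ALPHA_MAX,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_max = alpha_max

    def fit(self, X, y):
        views = _validate_views(X)
        y = np.asarray(y)
        y1, removed1 = remove_ambiguous_labels(views[0], y)
        if not np.any(y1 != UNLABELED):
            raise ValueError(
                "all initial labels were mutually ambiguous on the assembly "
                "graph; nothing left to propagate — check the initial binning"
            )
        mv = MultiViewLabelPropagation(
            tol=self.tol, max_iter=self.max_iter, alpha_max=self.alpha_max
        ).fit(views, y1)
        union = sum(views)
        y2, removed2 = remove_ambiguous_labels(union, mv.transduction_)

        self.propagator_ = mv
        self.classes_ = mv.classes_
        self.alpha_ = mv.alpha_
        self.objective_trace_ = mv.objective_trace_
        self.n_iter_ = mv.n_iter_
        self.label_distributions_ = mv.label_distributions_
        self.removed_round1_ = removed1
        self.removed_round2_ = removed2
        self.transduction_ = y2
        return self

    def predict(self, X=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "transduction_")
        return self.transduction_

    def fit_predict(self, X, y):
        return self.fit(X, y).transduction_


# ---------------------------------------------------------------------------
# functional wrappers over GraphView / LabelState
# ---------------------------------------------------------------------------

def remove_ambiguous(graph: GraphView, state: LabelState) -> LabelState:
    """Label-state wrapper around :func:`remove_ambiguous_labels`."""
    y_new, _ = remove_ambiguous_labels(graph.adjacency(), state.assignment)
    return state.with_assignment(y_new)


def multi_view_propagate(
    g1: GraphView,
    g2: GraphView,
    state: LabelState,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha_max: float = DEFAULT_ALPHA_MAX,
) -> tuple[LabelState, np.ndarray, list[float]]:
    """Propagate labels over two views; returns (labels, alpha, objective trace)."""
    est = MultiViewLabelPropagation(tol=tol, max_iter=max_iter, alpha_max=alpha_max)
    est.fit([g1, g2], state.assignment)
    return state.with_assignment(est.transduction_), est.alpha_, est.objective_trace_


def run_pipeline(
    g1: GraphView,
    g2: GraphView,
    initial: LabelState,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha_max: float = DEFAULT_ALPHA_MAX,
) -> tuple[LabelState, dict]:
    """Run the three-stage refinement; returns final labels and a run report."""
    if g1.catalog.ids != g2.catalog.ids:
        raise ValueError("views must share one contig catalog")
    est = BinRefiner(tol=tol, max_iter=max_iter, alpha_max=alpha_max)
    est.fit([g1, g2], initial.assignment)
    final = initial.with_assignment(est.transduction_)
    combined = combine_graphs(g1, g2)
    report = {
        "n_contigs": initial.catalog.n,
        "n_initial_labels": int(initial.n_labeled),
        "removed_round1": int(est.removed_round1_.size),
        "removed_round2": int(est.removed_round2_.size),
        "n_final_labels": int(final.n_labeled),
        "alpha": [float(a) for a in est.alpha_],
        "n_iter": int(est.n_iter_),
        "objective_trace": [float(v) for v in est.objective_trace_],
        "n_edges_assembly": g1.n_edges,
        "n_edges_pe": g2.n_edges,
        "n_edges_combined": combined.n_edges,
    }
    return final, report
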