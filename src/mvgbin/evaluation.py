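"""Binning assessment matrix and the four standard metrics.

Predicted bins and ground-truth species are cross-tabulated into a
``(k+1) x (s+1)`` contingency matrix: row ``k+1`` collects unbinned contigs
and column ``s+1`` contigs without a truth annotation.  With
``N = sum_{i<=k} sum_{j<=s} n_ij`` (binned *and* annotated contigs):

    Precision = (1/N) sum_i max_j n_ij
    Recall    = (1 / (N + sum_j n_{k+1,j})) sum_j max_i n_ij
    F1        = 2 P R / (P + R)
    ARI       = ( sum_ij C(n_ij,2) - t ) /
                ( (1/2)(sum_i C(a_i,2) + sum_j C(b_j,2)) - t ),
    t         = sum_i C(a_i,2) sum_j C(b_j,2) / C(N,2)

where ``a_i``/``b_j`` are row/column sums over the ``k x s`` block and
``C(.,2)`` the pair count.  Unannotated contigs are excluded throughout, as
the summation limits dictate; unbinned-but-annotated contigs inflate only the
recall denominator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .containers import UNLABELED, ContigCatalog, LabelState


@dataclass(frozen=True)
class AssessmentMatrix:
    """Contingency counts of predicted bins (rows) vs truth species (columns).

    ``counts`` has shape ``(k+1, s+1)``: the last row holds unbinned contigs,
    the last column unannotated ones.
    """

    counts: np.ndarray
    bin_names: tuple[str, ...]
    species_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.bin_names) + 1, len(self.species_names) + 1):
            raise ValueError("counts must be (k+1) x (s+1)")
        if c.min() < 0:
            raise ValueError("counts must be non-negative")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)

    @property
    def k(self) -> int:
        return len(self.bin_names)

    @property
    def s(self) -> int:
        return len(self.species_names)

    @property
    def core(self) -> np.ndarray:
        """The k x s block of binned-and-annotated contigs."""
        return self.counts[: self.k, : self.s]

    @property
    def N(self) -> int:
        return int(self.core.sum())


def build_assessment(
    pred: LabelState | Mapping[str, str],
    truth: Mapping[str, str],
    catalog: ContigCatalog,
) -> AssessmentMatrix:
    """Cross-tabulate predictions against truth over the whole catalog.

    Group order is first appearance in catalog order (bins) and in the truth
    mapping restricted to catalog order (species), so the matrix is
    deterministic.
    """
    if isinstance(pred, LabelState):
        pred_map = pred.as_dict()
    else:
        pred_map = {c: str(b) for c, b in pred.items()}
    bins: dict[str, int] = {}
    species: dict[str, int] = {}
    for cid in catalog.ids:
        if cid in pred_map and pred_map[cid] not in bins:
            bins[pred_map[cid]] = len(bins)
        if cid in truth and str(truth[cid]) not in species:
            species[str(truth[cid])] = len(species)
    k, s = len(bins), len(species)
    counts = np.zeros((k + 1, s + 1), dtype=np.int64)
    for cid in catalog.ids:
        i = bins[pred_map[cid]] if cid in pred_map else k
        j = species[str(truth[cid])] if cid in truth else s
        counts[i, j] += 1
    return AssessmentMatrix(counts, tuple(bins), tuple(species))


def precision(m: AssessmentMatrix) -> float:
    """Fraction of binned contigs in their bin's majority species; NaN if N=0."""
    if m.N == 0:
        return float("nan")
    if m.s == 0:
        return float("nan")
    return float(m.core.max(axis=1).sum() / m.N)


def recall(m: AssessmentMatrix) -> float:
    """Per-species majority recovery over all annotated contigs; NaN if empty."""
    unbinned_annotated = int(m.counts[m.k, : m.s].sum())
    denom = m.N + unbinned_annotated
    if denom == 0:
        return float("nan")
    if m.k == 0:
        return 0.0
    return float(m.core.max(axis=0).sum() / denom)


def f1(m: AssessmentMatrix) -> float:
    """Harmonic mean of precision and recall; NaN when both vanish."""
    p, r = precision(m), recall(m)
    if np.isnan(p) or np.isnan(r) or p + r == 0:
        return float("nan")
    return 2.0 * p * r / (p + r)


def _pairs(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def ari(m: AssessmentMatrix) -> float:
    """Adjusted Rand Index over the k x s block (chance-corrected agreement).

    Computed from the contingency counts directly; C(1,2) = C(0,2) = 0.
    Returns NaN for N < 2.  A zero denominator occurs only when both
    partitions are single blocks; 1.0 is returned there (full agreement).
    """
    core = m.core
    N = m.N
    if N < 2:
        return float("nan")
    sum_cells = _pairs(core).sum()
    a = _pairs(core.sum(axis=1)).sum()
    b = _pairs(core.sum(axis=0)).sum()
    t = a * b / _pairs(np.array([N]))[0]
    denom = 0.5 * (a + b) - t
    if denom == 0:
        return 1.0
    return float((sum_cells - t) / denom)


def evaluate(
    pred: LabelState | Mapping[str, str],
    truth: Mapping[str, str],
    catalog: ContigCatalog,
) -> dict:
    """All four metrics plus the assessment matrix, JSON-friendly."""
    m = build_assessment(pred, truth, catalog)
    return {
        "precision": precision(m),
        "recall": recall(m),
        "f1": f1(m),
        "ari": ari(m),
        "n_bins": m.k,
        "n_species": m.s,
        "n_binned_annotated": m.N,
        "matrix": m.counts.tolist(),
        "bin_names": list(m.bin_names),
        "species_names": list(m.species_names),
    }
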