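"""Shared in-memory containers for contig graphs and bin labels.

The contig catalog is the single authority for vertex identity: both graph
views (assembly overlap and paired-end linkage) are defined over the same
ordered set of contigs, addressed by ordinal position.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from Bio import SeqIO

UNLABELED = -1

EdgeSet = frozenset  # of (i, j) tuples with i < j


def _normalize_edges(edges: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    out = set()
    for a, b in edges:
        if a == b:
            continue
        out.add((a, b) if a < b else (b, a))
    return frozenset(out)


@dataclass(frozen=True)
class ContigCatalog:
    """Ordered contig catalog: the shared vertex set of all graph views.

    Parameters
    ----------
    ids :
        Unique contig names, in a fixed order defining ordinals ``0..n-1``.
    lengths :
        Contig lengths in bases (``>= 1``).
    sequences :
        Optional mapping from contig id to nucleotide sequence; when present,
        sequence lengths must match ``lengths``.
    """

    ids: tuple[str, ...]
    lengths: np.ndarray
    sequences: Mapping[str, str] | None = None
    index: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        object.__setattr__(self, "ids", ids)
        lengths = np.asarray(self.lengths, dtype=np.int64)
        object.__setattr__(self, "lengths", lengths)
        if len(ids) != len(set(ids)):
            raise ValueError("contig ids must be unique")
        if lengths.shape != (len(ids),):
            raise ValueError("lengths must align with ids")
        if len(ids) and lengths.min() < 1:
            raise ValueError("contig lengths must be >= 1")
        if self.sequences is not None:
            for cid, seq in self.sequences.items():
                if len(seq) != lengths[ids.index(cid)]:
                    raise ValueError(f"sequence length mismatch for contig {cid!r}")
        object.__setattr__(self, "index", {cid: i for i, cid in enumerate(ids)})

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.index

    def length_of(self, contig_id: str) -> int:
        return int(self.lengths[self.index[contig_id]])

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int] | tuple[str, int, str | None]]
    ) -> "ContigCatalog":
        ids, lengths, seqs = [], [], {}
        for rec in records:
            cid, length = rec[0], rec[1]
            ids.append(cid)
            lengths.append(length)
            if len(rec) > 2 and rec[2] is not None:
                seqs[cid] = rec[2]
        return cls(tuple(ids), np.asarray(lengths, dtype=np.int64), seqs or None)

    @classmethod
    def from_fasta(cls, path) -> "ContigCatalog":
        records = [
            (rec.id, len(rec.seq), str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls.from_records(records)


@dataclass(frozen=True)
class UnitigGraph:
    """Unitig-level assembly graph plus contig-to-unitig walks.

    Assemblers emit overlap graphs over unitigs (unambiguous paths); contigs
    are walks over unitigs after repeat resolution.  ``contig_paths`` records
    those walks so the graph can be projected onto contigs.
    """

    unitig_ids: frozenset[str]
    edges: frozenset[tuple[str, str]]
    contig_paths: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "unitig_ids", frozenset(self.unitig_ids))
        norm = set()
        for a, b in self.edges:
            if a == b:
                continue
            norm.add((a, b) if a < b else (b, a))
        object.__setattr__(self, "edges", frozenset(norm))
        paths = {c: tuple(p) for c, p in self.contig_paths.items()}
        object.__setattr__(self, "contig_paths", paths)
        known = self.unitig_ids
        for a, b in self.edges:
            if a not in known or b not in known:
                missing = sorted({a, b} - known)
                raise ValueError(f"edge references unknown unitig(s): {missing}")
        for contig, path in paths.items():
            unknown = [u for u in path if u not in known]
            if unknown:
                raise ValueError(
                    f"contig path {contig!r} names unknown unitig(s): {sorted(set(unknown))}"
                )


@dataclass(frozen=True)
class GraphView:
    """One undirected, unweighted graph over the contig catalog.

    ``kind`` distinguishes the assembly-overlap view, the paired-end linkage
    view and their union ("combined").  Edges are stored once as ordinal
    pairs ``(i, j)`` with ``i < j``; self-loops are dropped.
    """

    catalog: ContigCatalog
    edges: frozenset[tuple[int, int]]
    kind: str = "assembly"

    def __post_init__(self) -> None:
        edges = _normalize_edges(self.edges)
        object.__setattr__(self, "edges", edges)
        n = self.catalog.n
        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) outside catalog of size {n}")

    @property
    def n(self) -> int:
        return self.catalog.n

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix."""
        n = self.n
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols = zip(*self.edges)
        rows, cols = np.asarray(rows), np.asarray(cols)
        data = np.ones(len(rows))
        a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
        return (a + a.T).tocsr()

    def edge_ids(self) -> list[tuple[str, str]]:
        """Edges as sorted contig-id pairs, lexicographically ordered."""
        ids = self.catalog.ids
        pairs = [tuple(sorted((ids[i], ids[j]))) for i, j in self.edges]
        return sorted(pairs)

    @classmethod
    def from_id_pairs(
        cls, catalog: ContigCatalog, pairs: Iterable[tuple[str, str]], kind: str = "assembly"
    ) -> "GraphView":
        idx = catalog.index
        return cls(catalog, frozenset((idx[a], idx[b]) for a, b in pairs), kind)


@dataclass(frozen=True)
class LabelState:
    """Partial bin assignment over the catalog.

    ``assignment[i]`` is a dense group index in ``0..s-1`` or ``UNLABELED``
    (-1).  ``group_names`` preserves the original bin identifiers in
    first-appearance order so labels round-trip through CSV.
    """

    catalog: ContigCatalog
    assignment: np.ndarray
    group_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64).copy()
        a.setflags(write=False)
        object.__setattr__(self, "assignment", a)
        names = tuple(str(g) for g in self.group_names)
        if not names and a.size and a.max() >= 0:
            names = tuple(f"bin_{k}" for k in range(int(a.max()) + 1))
        object.__setattr__(self, "group_names", names)
        if a.shape != (self.catalog.n,):
            raise ValueError("assignment must have one entry per contig")
        if a.size and (a.min() < UNLABELED or (a.max() >= 0 and a.max() >= len(names))):
            raise ValueError("assignment indices out of range of group_names")

    @property
    def s(self) -> int:
        """Number of groups."""
        return len(self.group_names)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.assignment != UNLABELED

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    def indicator(self) -> np.ndarray:
        """One-hot l x s indicator over the labeled subset, in catalog order."""
        lab = np.flatnonzero(self.labeled_mask)
        Y = np.zeros((lab.size, self.s))
        Y[np.arange(lab.size), self.assignment[lab]] = 1.0
        return Y

    def with_assignment(self, assignment: Sequence[int]) -> "LabelState":
        return LabelState(self.catalog, np.asarray(assignment), self.group_names)

    def as_dict(self) -> dict[str, str]:
        """Labeled contigs as {contig_id: group_name}."""
        return {
            self.catalog.ids[i]: self.group_names[g]
            for i, g in enumerate(self.assignment)
            if g != UNLABELED
        }

    @classmethod
    def from_dict(
        cls, catalog: ContigCatalog, labels: Mapping[str, str]
    ) -> "LabelState":
        """Build from {contig_id: bin_name}; bins indexed in first-appearance order."""
        groups: dict[str, int] = {}
        assignment = np.full(catalog.n, UNLABELED, dtype=np.int64)
        for cid, bin_name in labels.items():
            key = str(bin_name)
            if key not in groups:
                groups[key] = len(groups)
            assignment[catalog.index[cid]] = groups[key]
        return cls(catalog, assignment, tuple(groups))
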