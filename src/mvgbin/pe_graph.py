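"""Paired-end linkage graph construction from read alignments.

Contigs that share uniquely aligned read pairs (one mate on each contig) are
candidate neighbours even without sequence overlap, which is how small
components cut off from the main assembly graph ("dead ends") get
reconnected.  Chimeric pairs — mates mapping far apart for artifactual
reasons — are suppressed by a positional filter: a link is kept only when at
least half of its supporting pairs have both mates within one insert size of
a contig end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pysam

from .containers import ContigCatalog, GraphView

#: mapping-quality floor below which an alignment is not considered unique
DEFAULT_MAPQ = 10
#: outer distances beyond this are discarded as artifacts during IS estimation
DEFAULT_IS_CAP = 10_000
#: minimal number of usable same-contig pairs for insert-size estimation
DEFAULT_MIN_PAIRS = 100
#: minimal read-pair support for a PE edge
DEFAULT_MIN_READS = 3

Span = tuple[str, int, int]  # (contig_id, start, end), half-open 0-based


class InsufficientPairsError(RuntimeError):
    """Too few usable pairs for insert-size estimation."""


@dataclass
class MatePairTable:
    """Unique alignments of both mates, joined by read name.

    ``pairs`` maps read name -> {1: span, 2: span} keeping only primary,
    non-supplementary alignments at or above the mapping-quality floor.
    Duplicate (name, mate) records are counted once.
    """

    pairs: dict[str, dict[int, Span]] = field(default_factory=dict)
    n_records: int = 0

    def add(self, name: str, mate: int, span: Span) -> None:
        slot = self.pairs.setdefault(name, {})
        if mate not in slot:
            slot[mate] = span
        self.n_records += 1

    def complete_pairs(self):
        """Yield (name, span1, span2) for reads with both mates uniquely aligned."""
        for name, mates in self.pairs.items():
            if 1 in mates and 2 in mates:
                yield name, mates[1], mates[2]


@dataclass
class PELinkEvidence:
    """Per-contig-pair read-name support and the estimated insert size.

    ``pair_support`` maps an unordered ordinal pair ``(i, j)`` (``i < j``) to
    the set of read names with one mate uniquely aligned to each contig;
    ``pair_spans`` holds each supporting pair's aligned intervals in the same
    key order.  ``pair_near_end_count`` is filled by :func:`build_pe_graph`.
    """

    insert_size: float | None = None
    pair_support: dict[tuple[int, int], set[str]] = field(default_factory=dict)
    pair_spans: dict[tuple[int, int], dict[str, tuple[tuple[int, int], tuple[int, int]]]] = field(
        default_factory=dict
    )
    pair_near_end_count: dict[tuple[int, int], int] = field(default_factory=dict)


def load_alignments(path, mapq: int = DEFAULT_MAPQ) -> MatePairTable:
    """Read a SAM/BAM file into a mate table of unique alignments.

    Uniqueness means: mapped, primary, not supplementary, MAPQ >= ``mapq``.
    Mates are joined by read name, so any sort order is accepted.
    """
    table = MatePairTable()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_paired:
                raise ValueError(
                    f"{path}: unpaired record {rec.query_name!r}; paired-end "
                    f"alignments are required (name-sorted input recommended)"
                )
            if rec.mapping_quality < mapq:
                continue
            mate = 1 if rec.is_read1 else 2
            end = rec.reference_end
            if end is None:
                end = rec.reference_start + (rec.query_length or 1)
            table.add(
                rec.query_name, mate, (rec.reference_name, rec.reference_start, end)
            )
    return table


def estimate_insert_size(
    table: MatePairTable,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    cap: int = DEFAULT_IS_CAP,
) -> float:
    """Median outer distance of uniquely aligned same-contig pairs.

    The outer distance is rightmost end of the downstream mate minus leftmost
    start of the upstream mate; distances beyond ``cap`` are discarded as
    artifacts before taking the median.
    """
    distances = []
    for _, (c1, s1, e1), (c2, s2, e2) in table.complete_pairs():
        if c1 != c2:
            continue
        outer = max(e1, e2) - min(s1, s2)
        if 0 < outer <= cap:
            distances.append(outer)
    if len(distances) < min_pairs:
        raise InsufficientPairsError(
            f"only {len(distances)} usable same-contig pairs (need >= {min_pairs}); "
            f"supply the library insert size manually with --insert-size"
        )
    distances.sort()
    mid = len(distances) // 2
    if len(distances) % 2:
        return float(distances[mid])
    return (distances[mid - 1] + distances[mid]) / 2.0


def collect_pair_support(table: MatePairTable, catalog: ContigCatalog) -> PELinkEvidence:
    """Collect read-name sets for every cross-contig pair of unique mates.

    Same-contig pairs are excluded; alignments to contigs outside the catalog
    are ignored.
    """
    ev = PELinkEvidence()
    for name, (c1, s1, e1), (c2, s2, e2) in table.complete_pairs():
        if c1 == c2 or c1 not in catalog or c2 not in catalog:
            continue
        i, j = catalog.index[c1], catalog.index[c2]
        if i < j:
            key, spans = (i, j), ((s1, e1), (s2, e2))
        else:
            key, spans = (j, i), ((s2, e2), (s1, e1))
        ev.pair_support.setdefault(key, set()).add(name)
        ev.pair_spans.setdefault(key, {})[name] = spans
    return ev


def _near_end(span: tuple[int, int], length: int, insert_size: float) -> bool:
    """True when the aligned interval lies within IS bases of either contig end."""
    start, end = span
    return end <= insert_size or start >= length - insert_size


def build_pe_graph(
    evidence: PELinkEvidence,
    catalog: ContigCatalog,
    min_reads: int = DEFAULT_MIN_READS,
) -> GraphView:
    """Apply the chimera filter and support threshold to produce the PE view.

    An edge ``{i, j}`` is added when the pair has at least ``min_reads``
    supporting read pairs and at least half of them (ceiling at odd counts)
    pass the positional test: each mate entirely within ``insert_size`` bases
    of one of its contig's two ends.  Contigs shorter than twice the insert
    size pass the test at any position, since the two end windows cover them.
    """
    if evidence.insert_size is None or evidence.insert_size <= 0:
        raise ValueError("evidence.insert_size must be set and positive")
    is_ = evidence.insert_size
    lengths = catalog.lengths
    edges = set()
    for (i, j), names in evidence.pair_support.items():
        spans = evidence.pair_spans.get((i, j), {})
        near = sum(
            1
            for name in names
            if name in spans
            and _near_end(spans[name][0], int(lengths[i]), is_)
            and _near_end(spans[name][1], int(lengths[j]), is_)
        )
        evidence.pair_near_end_count[(i, j)] = near
        if len(names) >= min_reads and near >= math.ceil(len(names) / 2):
            edges.add((i, j))
    return GraphView(catalog, frozenset(edges), kind="pe")


def pe_graph_from_alignments(
    path,
    catalog: ContigCatalog,
    insert_size: float | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    mapq: int = DEFAULT_MAPQ,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[GraphView, PELinkEvidence]:
    """One-stop construction of the PE view from a SAM/BAM file."""
    table = load_alignments(path, mapq=mapq)
    evidence = collect_pair_support(table, catalog)
    if insert_size is None:
        insert_size = estimate_insert_size(table, min_pairs=min_pairs)
    evidence.insert_size = float(insert_size)
    return build_pe_graph(evidence, catalog, min_reads=min_reads), evidence


def combine_graphs(g1: GraphView, g2: GraphView) -> GraphView:
    """Edge union of two views over the same catalog."""
    if g1.catalog.ids != g2.catalog.ids:
        raise ValueError("cannot combine graphs over different catalogs")
    return GraphView(g1.catalog, g1.edges | g2.edges, kind="combined")
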