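"""Parsers for assembly-graph and label formats.

Supported inputs:

* SPAdes-dialect **fastg** (as emitted by ``megahit_toolkit contig2fastg``):
  header lines ``>NAME[:NBR1,NBR2,...];`` where a trailing ``'`` marks a
  reverse-complement orientation.  Orientation is collapsed — the propagation
  algorithm is orientation-blind.
* **GFA1** ``S``/``L`` lines plus an optional SPAdes ``contigs.paths`` file
  mapping each contig to its walk of signed unitig ids.
* Bin label **CSV** (``contig_id,bin_id``; header optional) as produced by
  MaxBin2/MetaBAT2/CONCOCT-style binners.

Segment names in fastg headers often carry ``_length_<n>_cov_<x>`` suffixes;
these are stripped by :data:`FASTG_SUFFIX_RE` so that the contig catalog
remains the authority for canonical ids.
"""
from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from pathlib import Path

import numpy as np

from .containers import UNLABELED, ContigCatalog, GraphView, LabelState, UnitigGraph

#: stripped from fastg segment names: trailing length/coverage annotation.
FASTG_SUFFIX_RE = re.compile(r"_length_\d+_cov_[\d.]+$")

_HEADER_TOKENS = {"contig", "contig_id", "id", "name"}


class GraphParseError(ValueError):
    """Raised on malformed graph files, naming the offending line."""


def normalize_segment_name(name: str) -> str:
    """Canonical segment id: orientation mark and length/cov suffix removed."""
    name = name.strip()
    if name.endswith("'"):
        name = name[:-1]
    return FASTG_SUFFIX_RE.sub("", name)


def read_fastg(path) -> UnitigGraph:
    """Parse a SPAdes-dialect fastg file into an undirected unitig graph.

    Every segment becomes a unitig; every adjacency declaration becomes an
    undirected edge with orientation collapsed.  Because MEGAHIT-style fastg
    segments *are* contigs, ``contig_paths`` maps each segment to the
    singleton walk of itself.
    """
    segments: set[str] = set()
    neighbor_refs: list[tuple[str, str, int]] = []  # (src, dst, line_no)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line.startswith(">"):
                continue  # sequence line
            if not line.endswith(";"):
                raise GraphParseError(
                    f"{path}: malformed fastg header at line {line_no}: missing ';'"
                )
            body = line[1:-1]
            name_part, _, nbr_part = body.partition(":")
            name = normalize_segment_name(name_part)
            if not name:
                raise GraphParseError(
                    f"{path}: malformed fastg header at line {line_no}: empty name"
                )
            segments.add(name)
            if nbr_part:
                for raw in nbr_part.split(","):
                    nbr = normalize_segment_name(raw)
                    if not nbr:
                        raise GraphParseError(
                            f"{path}: malformed fastg header at line {line_no}: "
                            f"empty neighbor name"
                        )
                    neighbor_refs.append((name, nbr, line_no))
    dangling = sorted({nbr for _, nbr, _ in neighbor_refs if nbr not in segments})
    if dangling:
        raise GraphParseError(
            f"{path}: adjacency references missing segment(s): {dangling}"
        )
    edges = {(a, b) if a < b else (b, a) for a, b, _ in neighbor_refs if a != b}
    return UnitigGraph(
        frozenset(segments), frozenset(edges), {s: (s,) for s in sorted(segments)}
    )


def read_gfa(path, paths_path=None) -> UnitigGraph:
    """Parse GFA1 ``S``/``L`` lines, optionally with a SPAdes contigs.paths file.

    Link orientations are collapsed to undirected edges.  When no paths file
    is given, each segment is its own contig.
    """
    segments: set[str] = set()
    links: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise GraphParseError(f"{path}: truncated S line at line {line_no}")
                segments.add(fields[1])
            elif tag == "L":
                if len(fields) < 5:
                    raise GraphParseError(f"{path}: truncated L line at line {line_no}")
                links.append((fields[1], fields[3], line_no))
    for a, b, line_no in links:
        missing = [u for u in (a, b) if u not in segments]
        if missing:
            raise GraphParseError(
                f"{path}: L line {line_no} references unknown segment(s): {missing}"
            )
    edges = {(a, b) if a < b else (b, a) for a, b, _ in links if a != b}
    if paths_path is None:
        contig_paths = {s: (s,) for s in sorted(segments)}
    else:
        contig_paths = read_contig_paths(paths_path)
        for contig, walk in contig_paths.items():
            unknown = sorted({u for u in walk if u not in segments})
            if unknown:
                raise GraphParseError(
                    f"{paths_path}: contig {contig!r} path names unknown unitig(s): "
                    f"{unknown}"
                )
    return UnitigGraph(frozenset(segments), frozenset(edges), contig_paths)


def read_contig_paths(path) -> dict[str, tuple[str, ...]]:
    """Parse a SPAdes ``contigs.paths`` file into contig -> unitig walk.

    The dialect alternates a contig-name line with one or more path lines of
    comma-separated signed unitig ids; a trailing ``;`` continues the path on
    the next line (gapped walk).  Reverse-complement records (names ending in
    ``'``) are skipped; signs are stripped.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    paths: dict[str, tuple[str, ...]] = {}
    i = 0
    while i < len(lines):
        name = lines[i]
        i += 1
        walk: list[str] = []
        while i < len(lines):
            seg_line = lines[i]
            i += 1
            for part in seg_line.rstrip(";").split(";"):
                walk.extend(u.strip().rstrip("+-") for u in part.split(",") if u.strip())
            if not seg_line.endswith(";"):
                break
        if name.endswith("'"):
            continue
        paths[name] = tuple(walk)
    return paths


def unitig_to_contig_graph(
    ug: UnitigGraph, catalog: ContigCatalog, min_unitig_links: int = 1
) -> GraphView:
    """Project the unitig graph onto contigs.

    Contigs ``i`` and ``j`` are linked when at least ``min_unitig_links``
    unitig-graph edges have one endpoint on contig ``i``'s walk and the other
    on contig ``j``'s.  A unitig shared by both walks does not by itself
    create an edge, and self-loops are dropped.
    """
    missing = [cid for cid in catalog.ids if cid not in ug.contig_paths]
    if missing:
        raise ValueError(
            f"catalog contig(s) missing from contig paths: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    membership: dict[str, list[int]] = {}
    for cid in catalog.ids:
        ordinal = catalog.index[cid]
        for u in ug.contig_paths[cid]:
            membership.setdefault(u, []).append(ordinal)
    link_count: Counter[tuple[int, int]] = Counter()
    for a, b in ug.edges:
        for ci in membership.get(a, ()):
            for cj in membership.get(b, ()):
                if ci != cj:
                    link_count[(ci, cj) if ci < cj else (cj, ci)] += 1
    edges = frozenset(p for p, c in link_count.items() if c >= min_unitig_links)
    return GraphView(catalog, edges, kind="assembly")


def read_labels(path, catalog: ContigCatalog) -> LabelState:
    """Read an initial-binning CSV (``contig_id,bin_id``) into a LabelState.

    Bins are mapped to dense group indices in first-appearance order.
    Contigs absent from the file stay unlabeled; rows naming contigs outside
    the catalog are skipped with a warning.  A contig listed twice with
    conflicting bins is a hard error.
    """
    groups: dict[str, int] = {}
    assignment = np.full(catalog.n, UNLABELED, dtype=np.int64)
    seen: dict[str, str] = {}
    skipped: list[str] = []
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            cid = row[0].strip()
            if len(row) < 2 or not row[1].strip():
                raise ValueError(f"{path}: row {row_no} has no bin id")
            bin_name = row[1].strip()
            if cid not in catalog:
                if not (row_no == 1 and cid.lower() in _HEADER_TOKENS):
                    skipped.append(cid)
                continue
            if cid in seen:
                if seen[cid] != bin_name:
                    raise ValueError(
                        f"{path}: contig {cid!r} listed with conflicting bins "
                        f"{seen[cid]!r} and {bin_name!r}"
                    )
                continue
            seen[cid] = bin_name
            if bin_name not in groups:
                groups[bin_name] = len(groups)
            assignment[catalog.index[cid]] = groups[bin_name]
    if skipped:
        warnings.warn(
            f"{path}: skipped {len(skipped)} label row(s) for contigs not in the "
            f"catalog (e.g. {skipped[:3]})",
            stacklevel=2,
        )
    return LabelState(catalog, assignment, tuple(groups))


def write_labels(state: LabelState, path) -> None:
    """Write labeled contigs as ``contig_id,bin_id`` CSV in catalog order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["contig_id", "bin_id"])
        for i, g in enumerate(state.assignment):
            if g != UNLABELED:
                writer.writerow([state.catalog.ids[i], state.group_names[g]])


def write_edge_list(view: GraphView, path, header_comment: str = "") -> None:
    """Serialize a graph view as a TSV edge list (lexicographic, one per line)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for a, b in view.edge_ids():
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path, catalog: ContigCatalog, kind: str = "assembly") -> GraphView:
    """Read a TSV edge list produced by :func:`write_edge_list`."""
    pairs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphParseError(f"{path}: bad edge at line {line_no}")
            for cid in parts:
                if cid not in catalog:
                    raise GraphParseError(
                        f"{path}: line {line_no} names unknown contig {cid!r}"
                    )
            pairs.append((parts[0], parts[1]))
    return GraphView.from_id_pairs(catalog, pairs, kind)
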