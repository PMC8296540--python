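"""Deterministic synthetic scenarios with planted ground truth.

The generator emulates the structures the binning refiner consumes: a contig
catalog with log-normal lengths, a planted species partition, an
assembly-overlap view drawn as a planted-partition graph, dead-end components
carved off the main assembly graph and reattachable only through paired-end
links, a PE view realized as toy SAM records (near-end mate placement for
true links, mid-contig placement for planted chimeras, same-contig pairs for
insert-size estimation), and partial initial labels with a controllable
error rate.  Every artifact is a pure function of the seed, byte for byte.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .containers import ContigCatalog, GraphView, LabelState, UnitigGraph

_BASES = np.array(list("ACGT"))


def largest_remainder_sizes(proportions, n: int) -> np.ndarray:
    """Apportion ``n`` items to groups by the largest-remainder rule."""
    p = np.asarray(proportions, dtype=float)
    if p.min() < 0 or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("proportions must be non-negative and sum to 1")
    quotas = p * n
    sizes = np.floor(quotas).astype(np.int64)
    short = n - int(sizes.sum())
    if short:
        order = np.argsort(-(quotas - sizes), kind="stable")
        sizes[order[:short]] += 1
    return sizes


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic binning scenario.

    Defaults describe a 120-contig, 3-species community with intra-species
    assembly-edge probability 0.3 against 0.02 between species, two 4-contig
    dead-end components, 10% of contigs initially labeled with a 10% label
    error rate, and a Normal(400, 30) insert-size library of 100 bp reads.
    """

    n_contigs: int = 120
    n_species: int = 3
    species_proportions: tuple[float, ...] | None = None  # equal when None
    length_log_mean: float = math.log(2500.0)
    length_log_sigma: float = 0.35
    min_length: int = 1500
    p_intra: float = 0.3
    p_inter: float = 0.02
    pe_p_intra: float = 0.10
    pe_p_inter: float = 0.005
    n_dead_ends: int = 2
    dead_end_size: int = 4
    label_fraction: float = 0.1
    label_error_rate: float = 0.0
    insert_size_mean: float = 400.0
    insert_size_sd: float = 30.0
    read_length: int = 100
    pe_support: int = 4
    chimeric_rate: float = 0.02
    n_insert_pairs: int = 300
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.species_proportions is None:
            return np.full(self.n_species, 1.0 / self.n_species)
        return np.asarray(self.species_proportions, dtype=float)

    def species_sizes(self) -> np.ndarray:
        return largest_remainder_sizes(self.proportions(), self.n_contigs)

    def validate(self) -> None:
        probs = (
            self.p_intra, self.p_inter, self.pe_p_intra, self.pe_p_inter,
            self.label_fraction, self.label_error_rate, self.chimeric_rate,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_species < 1 or self.n_contigs < self.n_species:
            raise ValueError("need at least one contig per species")
        if len(self.proportions()) != self.n_species:
            raise ValueError("species_proportions length must equal n_species")
        sizes = self.species_sizes()
        need = np.zeros(self.n_species, dtype=np.int64)
        for d in range(self.n_dead_ends):
            need[d % self.n_species] += self.dead_end_size
        spare = sizes - need
        if self.n_dead_ends and (spare < 2).any():
            raise ValueError(
                "infeasible dead-end spec: a species would have fewer than 2 "
                "contigs left in the main graph"
            )


def three_strain_preset(n_contigs: int = 1000, seed: int = 0) -> ScenarioSpec:
    """A 3-cluster scenario with an extremely imbalanced community.

    Cluster proportions 0.90% / 9.01% / 90.09% mimic a mixture of a low-,
    medium- and high-abundance strain; contig counts follow by
    largest-remainder rounding.
    """
    spec = ScenarioSpec(
        n_contigs=n_contigs,
        n_species=3,
        species_proportions=(0.0090, 0.0901, 0.9009),
        seed=seed,
    )
    spec.validate()
    return spec


@dataclass
class Bundle:
    """Generated scenario: file paths plus the planted in-memory truth."""

    spec: ScenarioSpec
    catalog: ContigCatalog
    truth_species: np.ndarray  # species index per contig
    species_names: tuple[str, ...]
    initial: LabelState
    assembly_view: GraphView
    pe_view: GraphView
    unitig_graph: UnitigGraph
    dead_end_vertices: frozenset[int]
    chimeric_pairs: frozenset[tuple[int, int]]
    files: dict[str, Path] = field(default_factory=dict)

    def truth_map(self) -> dict[str, str]:
        return {
            self.catalog.ids[i]: self.species_names[sp]
            for i, sp in enumerate(self.truth_species)
        }

    def truth_state(self) -> LabelState:
        return LabelState(self.catalog, self.truth_species, self.species_names)


def generate_scenario(spec: ScenarioSpec, out_dir) -> Bundle:
    """Realize a scenario and write the full input bundle under ``out_dir``.

    Emits FASTA, fastg, GFA1 + contig paths, SAM, initial-label and truth
    CSVs plus a JSON manifest of the planted structures.  Identical specs
    (including the seed) produce byte-identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = spec.n_contigs
    s = spec.n_species
    read = spec.read_length

    # --- catalog and planted partition -----------------------------------
    sizes = spec.species_sizes()
    species = np.repeat(np.arange(s), sizes)
    species_names = tuple(f"species_{k}" for k in range(s))
    ids = tuple(f"contig_{i:05d}" for i in range(n))
    lengths = np.maximum(
        np.round(rng.lognormal(spec.length_log_mean, spec.length_log_sigma, n)),
        spec.min_length,
    ).astype(np.int64)
    seqs = {
        cid: "".join(_BASES[rng.integers(0, 4, size=int(L))])
        for cid, L in zip(ids, lengths)
    }
    catalog = ContigCatalog(ids, lengths, seqs)

    # --- dead-end components ----------------------------------------------
    dead_components: list[list[int]] = []
    used = np.zeros(n, dtype=bool)
    for d in range(spec.n_dead_ends):
        sp = d % s
        pool = [i for i in np.flatnonzero(species == sp)[::-1] if not used[i]]
        members = sorted(pool[: spec.dead_end_size])
        used[members] = True
        dead_components.append(members)
    dead = frozenset(i for comp in dead_components for i in comp)
    is_dead = np.zeros(n, dtype=bool)
    is_dead[list(dead)] = True

    # --- assembly view: planted partition, dead ends carved off -----------
    iu, ju = np.triu_indices(n, k=1)
    same = species[iu] == species[ju]
    involves_dead = is_dead[iu] | is_dead[ju]
    draw_a = (rng.random(iu.size) < np.where(same, spec.p_intra, spec.p_inter))
    assembly_edges = {
        (int(a), int(b)) for a, b in zip(iu[draw_a & ~involves_dead], ju[draw_a & ~involves_dead])
    }
    for comp in dead_components:  # internal chain keeps each dead end connected
        for a, b in zip(comp, comp[1:]):
            assembly_edges.add((a, b))
        for x in range(len(comp)):
            for y in range(x + 2, len(comp)):
                if rng.random() < spec.p_intra:
                    assembly_edges.add((comp[x], comp[y]))
    assembly_view = GraphView(catalog, frozenset(assembly_edges), "assembly")

    # --- PE view: planted links + dead-end attachments --------------------
    draw_p = (rng.random(iu.size) < np.where(same, spec.pe_p_intra, spec.pe_p_inter))
    pe_edges = {
        (int(a), int(b)) for a, b in zip(iu[draw_p & ~involves_dead], ju[draw_p & ~involves_dead])
    }
    for comp in dead_components:
        sp = species[comp[0]]
        main_same = np.flatnonzero((species == sp) & ~is_dead)
        n_attach = len(comp) // 2 + 1
        attach_members = rng.choice(comp, size=min(n_attach, len(comp)), replace=False)
        for m in sorted(int(x) for x in attach_members):
            target = int(rng.choice(main_same))
            pe_edges.add((m, target) if m < target else (target, m))
    pe_view = GraphView(catalog, frozenset(pe_edges), "pe")

    # --- planted chimeric links (to be rejected by the positional filter) --
    taken = assembly_edges | pe_edges
    cross_idx = np.flatnonzero(~same & ~involves_dead)
    candidates = [
        (int(iu[k]), int(ju[k])) for k in cross_idx if (int(iu[k]), int(ju[k])) not in taken
    ]
    n_chim = min(max(1, round(spec.chimeric_rate * n)), len(candidates))
    chim_idx = rng.choice(len(candidates), size=n_chim, replace=False) if candidates else []
    chimeric = frozenset(candidates[int(k)] for k in np.sort(chim_idx))

    # --- SAM records -------------------------------------------------------
    margin = int(spec.insert_size_mean * 0.7)  # conservative near-end window
    mid_floor = int(spec.insert_size_mean + 5 * spec.insert_size_sd)
    records: list[tuple] = []  # (name, contig_i, pos_i, contig_j, pos_j, same_contig, outer)
    counter = 0

    def near_end_pos(L: int) -> int:
        if rng.random() < 0.5:
            return int(rng.integers(0, max(1, margin - read)))
        return int(rng.integers(max(0, L - margin), max(1, L - read + 1)))

    for _ in range(spec.n_insert_pairs):
        isize = int(np.clip(round(rng.normal(spec.insert_size_mean, spec.insert_size_sd)),
                            2 * read + 10, None))
        c = int(rng.integers(0, n))
        if lengths[c] <= isize:
            c = int(np.argmax(lengths))
        start = int(rng.integers(0, lengths[c] - isize + 1))
        records.append((f"pair{counter:06d}", c, start, c, start + isize - read, True, isize))
        counter += 1
    for (a, b) in sorted(pe_edges):
        for _ in range(spec.pe_support):
            records.append(
                (f"pair{counter:06d}", a, near_end_pos(int(lengths[a])),
                 b, near_end_pos(int(lengths[b])), False, 0)
            )
            counter += 1
    for (a, b) in sorted(chimeric):
        for _ in range(spec.pe_support):
            pa = int(rng.integers(mid_floor, max(mid_floor + 1, lengths[a] - mid_floor - read + 1)))
            pb = int(rng.integers(mid_floor, max(mid_floor + 1, lengths[b] - mid_floor - read + 1)))
            records.append((f"pair{counter:06d}", a, pa, b, pb, False, 0))
            counter += 1

    # --- initial labels ----------------------------------------------------
    # Stratified over species: an initial binner only emits nonempty bins, so
    # every group contributes at least one seed label.
    n_labeled = max(s, round(spec.label_fraction * n))
    pools = [np.flatnonzero((species == sp) & ~is_dead) for sp in range(s)]
    pool_sizes = np.array([p.size for p in pools])
    quota = largest_remainder_sizes(pool_sizes / pool_sizes.sum(), n_labeled)
    quota = np.maximum(quota, 1)
    quota = np.minimum(quota, pool_sizes)
    labeled = np.sort(
        np.concatenate([
            rng.choice(pool, size=int(q), replace=False)
            for pool, q in zip(pools, quota)
        ])
    )
    initial_assignment = np.full(n, -1, dtype=np.int64)
    for v in labeled:
        sp = int(species[v])
        if s > 1 and rng.random() < spec.label_error_rate:
            others = [k for k in range(s) if k != sp]
            sp = int(rng.choice(others))
        initial_assignment[v] = sp
    initial = LabelState(catalog, initial_assignment, species_names)

    # --- unitig realization of the assembly view ---------------------------
    unitig_counter = 0
    contig_unitigs: dict[str, list[str]] = {}
    for cid in ids:
        k = int(rng.integers(1, 4))
        contig_unitigs[cid] = [f"u{unitig_counter + t}" for t in range(k)]
        unitig_counter += k
    unitig_edges: set[tuple[str, str]] = set()
    for cid, walk in contig_unitigs.items():
        for a, b in zip(walk, walk[1:]):
            unitig_edges.add((a, b) if a < b else (b, a))
    for (a, b) in sorted(assembly_edges):
        ua, ub = contig_unitigs[ids[a]][-1], contig_unitigs[ids[b]][0]
        unitig_edges.add((ua, ub) if ua < ub else (ub, ua))
    all_unitigs = frozenset(u for walk in contig_unitigs.values() for u in walk)
    unitig_graph = UnitigGraph(
        all_unitigs, frozenset(unitig_edges),
        {cid: tuple(walk) for cid, walk in contig_unitigs.items()},
    )

    files = _write_bundle_files(
        out_dir, spec, catalog, species, species_names, assembly_view, pe_view,
        chimeric, dead, contig_unitigs, unitig_edges, records, initial,
    )
    return Bundle(
        spec=spec, catalog=catalog, truth_species=species,
        species_names=species_names, initial=initial,
        assembly_view=assembly_view, pe_view=pe_view, unitig_graph=unitig_graph,
        dead_end_vertices=dead, chimeric_pairs=chimeric, files=files,
    )


def _write_bundle_files(
    out_dir, spec, catalog, species, species_names, assembly_view, pe_view,
    chimeric, dead, contig_unitigs, unitig_edges, records, initial,
):
    ids, lengths = catalog.ids, catalog.lengths
    files = {
        "fasta": out_dir / "contigs.fasta",
        "fastg": out_dir / "assembly.fastg",
        "gfa": out_dir / "assembly.gfa",
        "paths": out_dir / "contigs.paths",
        "sam": out_dir / "alignments.sam",
        "labels": out_dir / "initial_labels.csv",
        "truth": out_dir / "truth.csv",
        "manifest": out_dir / "manifest.json",
    }

    with open(files["fasta"], "w") as fh:
        for cid in ids:
            fh.write(f">{cid}\n{catalog.sequences[cid]}\n")

    # fastg: contig-level, with length/cov suffixes and orientation marks
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(ids))}
    for a, b in sorted(assembly_view.edges):
        neighbors[a].append(b)
        neighbors[b].append(a)
    with open(files["fastg"], "w") as fh:
        for i, cid in enumerate(ids):
            name = f"{cid}_length_{lengths[i]}_cov_10.0"
            nbrs = ",".join(
                f"{ids[j]}_length_{lengths[j]}_cov_10.0" + ("'" if (i + j) % 2 else "")
                for j in neighbors[i]
            )
            header = f">{name}:{nbrs};" if nbrs else f">{name};"
            fh.write(header + "\n" + catalog.sequences[cid] + "\n")

    with open(files["gfa"], "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        all_unitigs = sorted(
            {u for walk in contig_unitigs.values() for u in walk},
            key=lambda u: int(u[1:]),
        )
        for u in all_unitigs:
            fh.write(f"S\t{u}\t*\n")
        for a, b in sorted(unitig_edges):
            oa = "+" if (len(a) + len(b)) % 2 == 0 else "-"
            fh.write(f"L\t{a}\t{oa}\t{b}\t+\t*\n")

    with open(files["paths"], "w") as fh:
        for cid in ids:
            walk = contig_unitigs[cid]
            signed = [u + ("+" if t % 2 == 0 else "-") for t, u in enumerate(walk)]
            fh.write(cid + "\n")
            if len(signed) >= 3:  # exercise the gapped-walk continuation syntax
                fh.write(",".join(signed[:2]) + ";\n" + ",".join(signed[2:]) + "\n")
            else:
                fh.write(",".join(signed) + "\n")
            rev = [u + ("-" if t % 2 == 0 else "+") for t, u in enumerate(reversed(walk))]
            fh.write(cid + "'\n" + ",".join(rev) + "\n")

    read = spec.read_length
    with open(files["sam"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, L in zip(ids, lengths):
            fh.write(f"@SQ\tSN:{cid}\tLN:{L}\n")
        cigar = f"{read}M"
        for name, ci, pi, cj, pj, same_contig, outer in records:
            ca, cb = ids[ci], ids[cj]
            if same_contig:
                f1, f2, rnext, tlen = 99, 147, "=", outer
            else:
                f1, f2, rnext, tlen = 97, 145, cb, 0
            rnext2 = "=" if same_contig else ca
            fh.write(f"{name}\t{f1}\t{ca}\t{pi + 1}\t60\t{cigar}\t{rnext}\t{pj + 1}\t{tlen}\t*\t*\n")
            fh.write(f"{name}\t{f2}\t{cb}\t{pj + 1}\t60\t{cigar}\t{rnext2}\t{pi + 1}\t{-tlen}\t*\t*\n")

    with open(files["labels"], "w") as fh:
        fh.write("contig_id,bin_id\n")
        for i, g in enumerate(initial.assignment):
            if g >= 0:
                fh.write(f"{ids[i]},{species_names[g]}\n")

    with open(files["truth"], "w") as fh:
        fh.write("contig_id,species_id\n")
        for i, sp in enumerate(species):
            fh.write(f"{ids[i]},{species_names[sp]}\n")

    manifest = {
        "seed": spec.seed,
        "spec": asdict(spec),
        "assembly_edges": assembly_view.edge_ids(),
        "pe_edges": pe_view.edge_ids(),
        "chimeric_pairs": sorted(
            [sorted((ids[a], ids[b])) for a, b in chimeric]
        ),
        "dead_end_contigs": sorted(ids[i] for i in dead),
    }
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return files
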