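# Methods

## Model

The refiner treats contig binning as transductive semi-supervised
classification over m = 2 graph views sharing one vertex set (the contig
catalog): the assembly-overlap view G₁ and the paired-end linkage view G₂.
Both are undirected and unweighted (W entries in {0, 1}); orientation
information in fastg/GFA inputs is parsed and discarded because the
propagation model is orientation-blind, and self-loops are dropped because
they cannot move label mass under the normalized Laplacian
Lᵢ = Dᵢ^(−1/2)(Dᵢ − Wᵢ)Dᵢ^(−1/2).

With l labeled vertices (one-hot Y_l over s groups) the objective

    argmin_{F_u}  Σᵢ √(tr(Fᵀ Lᵢ F))   s.t. F_l = Y_l

is minimized by alternating a clamped harmonic solve on the weighted
combined Laplacian L = Σ αᵢ Lᵢ with the weight update
αᵢ = 1/(2√(tr(Fᵀ Lᵢ F))), starting from αᵢ = 1/m. The square root in the
objective is what makes the weights self-calibrating: a view with a small
smoothness penalty (its edges agree with the current labels) receives a
large weight at the next solve.

**Sign of the harmonic update.** The stationarity condition of
tr(Fᵀ L F) under the clamp is L_uu F_u = −L_ul Y_l. An equivalent form
without the minus sign circulates in the literature but repels label mass
(the single-label sanity case yields negative scores); this implementation
uses the stationarity solution, and the unit tests pin the positive-mass
behavior on hand-solved 3- and 4-vertex paths.

**Isolated vertices.** A vertex with degree 0 in a view has no defined
D^(−1/2) entry; the convention here is an all-zero Laplacian row — the view
is simply uninformative for that vertex. This keeps every diagonal block of
L_uu restricted to a labeled component strictly positive definite (zero
rows never enter such a component), so the per-component sparse direct
solves cannot be singular; a residual check at relative 1e−8 guards the
claim at run time. Components of the union graph containing no labeled
vertex keep all-zero score rows and surface as unbinned output, never as a
forced guess.

**Convergence and ties.** Iteration stops when the maximum relative change
of α drops below `tol` (default 1e−4) or after `max_iter` (default 100)
rounds. When a view's trace term vanishes (a graph perfectly consistent
with F, e.g. an edgeless view), its weight is capped at `alpha_max`
(default 1e6) instead of diverging; weights are deliberately not
renormalized, since only their ratio enters the solve. Row-wise argmax
breaks ties toward the lowest group index; rows with all scores below
1e−12 stay unlabeled.

## Ambiguity removal

A labeled vertex v is *ambiguous* when the set of labels carried by its
closest labeled vertices — minimum hop distance within v's component,
excluding v itself — contains a label different from v's own. All marks are
computed against the input labeling and removed simultaneously (a
mark-then-sweep pass, not a cascade), so the result is order-independent.
Labeled vertices with no labeled companion in their component are kept.
The pipeline applies this twice: on the assembly view alone before
propagation (the PE view is noisier and would cost too many seed labels),
and on the combined view afterwards. The second round may leave contigs
permanently unlabeled; that is intended behavior for a refiner that prefers
abstention to contradiction.

## PE graph construction

Alignments are read with pysam; a record counts as *unique* when it is
mapped, primary, not supplementary, and has MAPQ ≥ 10 (configurable — the
notion of "uniquely aligned" needs an operational criterion). Mates are
joined by read name, so any sort order works, at an in-memory cost of one
table entry per read pair. Duplicate (name, mate) records count once.

The insert size IS is the median outer distance (downstream mate's right
end minus upstream mate's left start) over unique same-contig pairs, after
discarding distances above 10 kb as artifacts; the median is robust to the
residual tail. At least `min_pairs` (default 100) usable pairs are
required, otherwise the caller must supply `--insert-size`.

A candidate link {i, j} collects the read names with one unique mate on
each contig. The chimera filter keeps the link only when at least
⌈|RS|/2⌉ of those pairs are *near-end*: each mate's aligned interval lies
entirely within IS bases of one of its contig's two ends (either end — an
orientation-blind graph cannot distinguish head from tail). For contigs
shorter than 2·IS the two windows cover everything and the test is
vacuously true, which is correct: on a short contig no position is far
from an end. A support floor `min_reads` (default 3) stops single spurious
pairs from creating edges; set it to 1 for the permissive reading.

## Assembly graph construction

fastg (SPAdes dialect, as emitted by `megahit_toolkit contig2fastg`) and
GFA1 + SPAdes `contigs.paths` are parsed by hand — they are small
line-oriented formats; segment names are canonicalized by stripping
orientation marks and trailing `_length_<n>_cov_<x>` annotations, with the
catalog as the authority for ids. The unitig graph is projected onto
contigs: an edge {i, j} appears when at least `min_unitig_links` (default
1) unitig edges have one endpoint on each contig's walk. The default reads
"two unitigs connect to each other and belong to the two contigs" as the
two *endpoints of one unitig edge*; requiring two or more distinct unitig
edges is available via the option but disconnects most real graphs. A
unitig shared by two contig walks does not by itself link them. Catalog
contigs absent from the graph file remain as isolated vertices — they may
still gain PE edges.

## Evaluation

The assessment matrix is the (k+1)×(s+1) cross-tabulation of predicted
bins versus ground-truth species, with the extra row for unbinned and the
extra column for unannotated contigs. Precision, Recall, F1 and ARI follow
the printed summation limits exactly: unannotated contigs are excluded
from every formula, unbinned-but-annotated contigs inflate only the recall
denominator, and ARI is computed on the k×s block by pair counting. The
ARI denominator vanishes only when both partitions are a single block
(k = s = 1, a 0/0 case); 1.0 is returned there by the usual
perfect-agreement convention. Degenerate inputs (N = 0, N < 2) yield NaN,
reported as NA.

## Synthetic scenarios

`ScenarioSpec` defaults describe the benchmark community: n = 120 contigs,
s = 3 species of equal proportions, log-normal contig lengths (median
2.5 kb, floor 1.5 kb so mid-contig read placement is well defined),
intra-species assembly-edge probability 0.3 versus 0.02 between species,
PE-view probabilities 0.10/0.005, two 4-contig dead-end components carved
off the assembly graph and re-attached to same-species main-graph contigs
by PE links only, 10% of contigs seeded with labels, insert sizes
Normal(400, 30), 100 bp reads, 4 supporting read pairs per planted PE
link, and a 2% chimeric-pair rate realized as mid-contig placements that
the positional filter must reject. Label sampling is stratified so every
species seeds at least one label — an initial binner only emits nonempty
bins. Label corruption defaults to 0 and is switched to 10% in the
refinement-ablation scenario. A `three_strain_preset` reproduces an
extremely imbalanced community (0.90% / 9.01% / 90.09%, largest-remainder
rounding: 9/90/901 contigs at n = 1000).

Alignments are synthesized directly as SAM records (names, flags,
positions) rather than produced by an aligner, since graph construction
reads nothing else; sequences are random nucleotides. One RNG stream per
bundle makes every file a pure function of the seed, byte for byte.

Two structural regimes matter in testing. The *default* regime
(p_inter = 0.02) produces a single dense blob in which species subgraphs
are heavily interlinked — a stress test for propagation, but a regime the
closest-labeled-vertex removal heuristic was never meant for: with ~32
cross-species edges per species pair, most vertices have a
differently-labeled vertex among their closest labeled neighbors, and the
removal rounds strip labels wholesale. The *separated* regime
(p_inter = 0, the idealized "one subgraph per species" structure) is where
dead-end rescue and the value of post-propagation refinement are measured.
Passing tests in these regimes demonstrates the mechanics — weight
learning, dead-end reconnection, chimera filtering, error removal — on
graphs with planted truth; they do not certify performance on real
assemblies, whose repeat structure, coverage imbalance and alignment noise
the generator does not emulate.

## Problem sizes and numerics

Test and acceptance runs use n ≤ 200 graphs and 5–20 seed replicates per
property, with dense NumPy linear algebra as the independent oracle for
the sparse solver (agreement to 1e−6), per-vertex BFS as the oracle for
ambiguity removal, and pair-counting ARI cross-checked against
scikit-learn on exploded label vectors. The alternating objective is
asserted non-increasing with 1e−9 slack. Linear systems are solved per
connected component with SuperLU (`scipy.sparse.linalg.spsolve`); the
whole pipeline is deterministic given its inputs — no randomness exists
outside the scenario generator.

## Known limitations

- Two views are wired through the CLI; the solver itself accepts any
  number of adjacency matrices.
- Removal plus propagation can leave contigs unlabeled; downstream tools
  expecting a total assignment must handle absences.
- The number of groups s is inherited from the initial binner; the method
  cannot create or merge bins.
- Graphs are unweighted; overlap lengths and PE support counts beyond the
  threshold are not exploited.
- The BFS in ambiguity removal is O(l·(n+m)) — fine up to the ~10⁴-vertex
  graphs this tool targets, not tuned beyond that.
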