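# Methods

## The model

A *gene family history* is a rooted gene tree T whose internal vertices
are labeled speciation (𝔰), duplication (𝔡) or transfer origin (𝔱), with
a set Ē of *transfer edges* (each leaving a 𝔱 vertex) and a surjective
map σ from the genes at the leaves to a species set Σ.  Removing the
transfer edges yields the *transfer-free forest*; σ_Ē(v) denotes the
species of the leaves reachable from v inside its forest component.
Admissible inputs satisfy the observability axioms: every internal
vertex has out-degree ≥ 2 (O1), every 𝔱 vertex retains both a transfer
and a non-transfer out-edge (O2), speciation children have pairwise
disjoint σ_Ē sets and transfer-edge endpoints have disjoint σ_Ē sets
(O3).  These axioms describe what survives in data after gene loss: an
event without two surviving witness lineages leaves no trace.

A *reconciliation* μ embeds T into a species tree S: leaves anchor to
their species (M1), speciations map to lca_S(σ_Ē(·)) with pairwise
incomparable children images (M2.i/iv), duplications and transfers map
to species edges (M2.ii), transfer-edge endpoints map incomparably
(M2.iii), and vertical descent preserves the species-tree order (M3).
It is *time-consistent* if there are strictly increasing (root-to-leaf)
time maps τ_T, τ_S with τ_T = τ_S∘μ on speciations and leaves (B1) and
each edge-mapped vertex timed strictly inside its host edge's interval
(B2).  The package decides, for a given (T;t,σ), whether a
time-consistent species tree exists, and builds a binary one plus μ and
(τ_T, τ_S) when it does.

## Informative triplets and the timing graph

Two structures carry all the information:

* **Informative triplets R(T;t,σ)** — species triplets σ(a)σ(b)|σ(c)
  (species pairwise distinct) forced either by a speciation at the
  forest-lca of {a,b,c} or by a,b lying under one endpoint and c under
  the other endpoint of a transfer edge.  Any admissible species tree
  must display all of R.  R is materialized explicitly; it can reach
  Θ(n³) triplets and that bound is tight for this representation.

* **The timing graph A(T,S)** — a digraph on V(T) ∪ V(S) with one edge
  per gene-tree edge after substituting speciation/leaf endpoints by
  their LCA-map images (A1), the species-tree edges (A2), an edge from
  each 𝔡/𝔱 vertex to its LCA-map image (A3), and, per transfer edge
  (u,v), an edge from lca_S(μ̂(u), μ̂(v)) back to u (A4) — the donor
  lineage must predate the divergence separating donor and recipient.

S admits a time-consistent reconciliation with T exactly when S
displays R **and** A(T,S) is acyclic.  `verify_solution` checks both
conditions directly.

## The solver

Starting from the star tree over the observed species (or a
user-supplied almost binary tree), the solver repeatedly applies *good
split refinements*: a non-binary cherry x is resolved by bipartitioning
its children so that (a) the refined tree still agrees with R and (b)
every in-neighbor of x in the refreshed A(T,S) already belongs to the
maximal topological sort — i.e. the refinement strictly extends the
sortable vertex set.  Candidate bipartitions are read off an undirected
guidance graph on the cherry's leaves, an extension of the BUILD/Aho
graph: two species are joined when separating them would contradict a
triplet whose outgroup also lies under the cherry (C1), or would route
a timing edge into the cherry from an unsorted duplication/transfer
vertex (C2, C4), or would put a self-loop on it (C3).  Any bipartition
across which no edge runs yields a good split; if every admissible
cherry's graph is connected, the instance has no solution at all.  Each
split turns exactly one cherry into a resolved binary vertex, so the
loop runs at most |Σ| − 2 times; on a binary tree the two
characterizing conditions are checked outright.  The member set of the
maximal topological sort is independent of Kahn tie-breaking; the
implementation fixes ties (species before genes, then lexicographic)
only to make runs reproducible.

The per-iteration work recomputes A(T,S), the sort and the per-cherry
graphs from scratch: with O(n) iterations this stays within the
method's cubic budget, which is dominated by materializing R anyway.
Cross-iteration caching of the cherry graphs would be an optimization,
not a correctness requirement, and is not implemented.

## Constructing μ and the time maps

For a verified pair the embedding and the times are built **jointly**.
The naive choice — always mapping a 𝔡/𝔱 vertex to the species edge
entering lca_S(σ_Ē(·)) — satisfies M1–M3 but is not always
time-consistent: a transfer chain can force a vertex's time above that
edge's upper end even though A(T,S) is acyclic.  The package therefore
linearizes a strict-precedence digraph whose nodes are the species
vertices plus the edge-mapped gene vertices, with arcs for: every
species edge; every gene-tree edge (speciations and leaves collapsed
onto their LCA-map images); an upper bound u → μ̂(u) per edge-mapped
vertex; and a fork-separation lower bound z → u whenever u's lineage
must be incomparable with another lineage diverging at z (between
children of a speciation, and across each transfer edge).  Every valid
time assignment linearizes this digraph, so it is acyclic exactly when
the pair verifies.  Integer ranks of a topological order give exact
times; sinks are peeled gene-first so each edge-mapped vertex receives
the largest admissible time and lands on the lowest admissible species
edge — the canonical entering edge whenever that is feasible, a higher
edge (up to the conceptual planted edge above the root) when not.
Vertices mapping above the root go to the planted edge, represented as
`(None, root)`; it never becomes a materialized vertex.

All times are integers and all order checks exact; no floating-point
tolerances exist anywhere in the package.  Both constructions have
independent literal checkers (`check_reconciliation`,
`check_time_assignment`) that return violations as data; a checker
failure after a verified precondition is treated as an internal error.

## Synthetic instances

`simulate_instance` grows a gene tree inside a random timed binary
species tree (Kingman-style topology, leaves at time 1, distinct
internal times in (0,1)).  Along each gene lineage, duplication,
transfer and loss events arrive at exponential waiting times; a
transfer jumps to a species branch alive at the transfer time, chosen
uniformly, so a genuine time-consistent history exists by construction.
Defaults — 8 species, rates 0.3/0.3/0.3 per lineage per unit height —
give moderately sized observable families (tens of genes) with a
realistic mix of event kinds, comparable to rate settings in common
duplication-transfer-loss simulation studies; rates are interpretable
as expected events per gene per root-to-leaf path.

The observable tree is extracted by pruning lost subtrees, suppressing
single-child vertices, and handling 𝔱 vertices by the observability
rationale: if the transferred copy died, the vertex is suppressed into
its vertical child; if the *donor-side* lineage died, the transferred
subtree is discarded too, because no trace of the transfer would remain
and keeping it would require a transfer flag on a suppressed composite
edge whose tail is not a 𝔱 vertex.  This post-processing provably
restores O1–O3, and the true species tree (restricted to species with
surviving genes) remains a witness solution.  The simulator emulates
event placement and loss; it does **not** emulate estimation noise in
event labels, rate heterogeneity across lineages, replacement transfers
or incomplete species sampling — so passing tests demonstrate
correctness of the decision procedure on admissible inputs, not
robustness to misannotated real data.  Crafted generators complement
it: `conflicting_caterpillars` produces valid transfer-free instances
whose triplet sets are usually incompatible (genuine negatives), and
`relabel_perturbation` rewires leaf species while preserving the
axioms.

## Worked-example fixture

The bundled `fig1_fixture` is a binary nine-leaf gene tree over species
{A,B,C,D} with four transfer events, whose informative triplets are
exactly {AB|D, AC|D}.  The least-resolved displaying tree ((A,B,C),D)
admits a reconciliation but no time-consistent one (its timing graph
contains a five-vertex cycle through the transfer chain), while the
refinement (((A,B),C),D) verifies; the solver reproduces the
star → ((A,B,C),D) → (((A,B),C),D) run, and the star-tree guidance
graph has four vertices and exactly two edges whose components split
off D.  Each of these properties is asserted individually by the test
suite, so the fixture cannot drift from its documented behavior.

## Problem sizes and determinism

The shipped checks use: 300 mixed instances with 3–5 species for the
exhaustive-oracle comparison (all 3/15/105 binary species trees per
instance), 200 simulated instances with 4–20 species for the
completeness and embedding round-trip study, 100 transfer-free
instances for the BUILD reduction, and 200 instances with ≤ 12 leaves
for the triplet brute-force comparison; the full suite and the
reproduction script each run in well under a minute on one CPU.  A
single integer seed drives every stochastic choice through one named
`random.Random` stream per instance, so all reported numbers are
bit-reproducible.

## Known limitations

* One solution is returned, not the (possibly exponentially many) set
  of all time-consistent species trees, and no least-resolved
  (non-binary) solution is derived by edge contraction.
* Event labels and transfer flags are taken as ground truth; no error
  correction of noisy labelings is attempted.
* R(T;t,σ) is materialized, so memory grows as Θ(n³) in the worst case.
* Cost-based (parsimony) reconciliation variants are out of scope.
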