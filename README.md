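# gtcons — time-consistent species trees from event-labeled gene trees

Gene family histories can be estimated directly from sequence data as
*event-labeled gene trees*: rooted trees whose internal vertices are
annotated as speciations (𝔰), duplications (𝔡) or horizontal-transfer
origins (𝔱), with transfer edges flagged and each gene assigned to its
species.  Such a history is biologically feasible only if some species
tree S exists into which the gene tree can be embedded so that no gene
lineage travels backwards in time.  With horizontal transfer involved,
most reconciliation questions are NP-hard; this one is not.  `gtcons`
implements the polynomial-time decision-and-construction algorithm for
the *gene tree consistency* (GTC) problem: given (T; t, σ) — and
optionally an almost binary species tree to refine — decide whether a
time-consistent species tree exists, and if so return a binary one
together with the reconciliation map μ and explicit time maps τ_T, τ_S.

The method rests on two facts.  First, the gene tree forces a set of
*informative species triplets* R(T;t,σ): σ(a)σ(b)|σ(c) whenever ab|c is
displayed inside one component of the transfer-free forest below a
speciation lca, or a,b sit on one side and c on the other side of a
transfer edge.  Second, a digraph A(T,S) on V(T) ∪ V(S) (edge classes
A1–A4) encodes all "must happen before" constraints between gene and
species vertices.  A species tree S admits a time-consistent
reconciliation **iff S displays R(T;t,σ) and A(T,S) is acyclic**.  The
solver starts from the star tree and greedily applies *good split
refinements* — cherry bipartitions read off a BUILD-style guidance
graph (conditions C1–C4) — each of which preserves solvability and
strictly extends the maximal topological sort of A(T,S); if no good
split exists before the tree is binary, no solution exists at all.

## Worked example

The bundled worked example (`gtcons.fig1_fixture`) is a binary gene
tree over species A–D with four transfers whose informative triplets
are {AB|D, AC|D}:

```python
from gtcons import (fig1_fixture, informative_triplets, verify_solution,
                    solve, GtcInstance)

gt, S_least, S_mid = fig1_fixture()
print(sorted(map(str, informative_triplets(gt))))
print(verify_solution(gt, S_least), verify_solution(gt, S_mid))
res = solve(GtcInstance(gt))
print(res.status, res.species_tree.to_newick())
```

prints

```
['A,B|D', 'A,C|D']
False True
solved (((A,B),C),D);
```

`False True` is the instructive part: the least-resolved tree
((A,B,C),D) displays both triplets, so a reconciliation exists — but
its timing graph is cyclic, so no time assignment does; the refinement
(((A,B),C),D) supports a time-consistent map, and the solver finds
exactly that tree from the star in two splits (off D, then off C).

The same workflow is available from the shell; exit codes are 0 =
solved, 3 = no solution, 2 = invalid input:

```sh
gtcons triplets --gene-tree family.nhx            # one "A,B|C" per line
gtcons validate --gene-tree family.nhx            # observability axioms O1-O3
gtcons solve    --gene-tree family.nhx --out species.nwk --trace trace.tsv
gtcons check    --gene-tree family.nhx --species-tree species.nwk
gtcons simulate --n-species 8 --seed 1 --out sim  # DTL test instance
```

Gene trees are NHX-annotated Newick: `[&&NHX:ev=S|D|T]` on internal
vertices, `xfer=1` on the child end of transfer edges, and leaf species
as `S=<name>` tags or a two-column TSV (`--species-map`).

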