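# orthocorrect

Correction of orthology/paralogy relation graphs and event-labeled gene
trees against a species tree.

## The problem

A gene family Γ evolves inside a species tree *S* through speciations and
duplications. Its history can be written as a *DS-tree*: a rooted gene tree
whose internal nodes are labeled **Spec** or **Dup**. Following Fitch, two
genes are *orthologs* when the event at their lowest common ancestor is a
speciation, *paralogs* when it is a duplication, so a DS-tree induces a full
partition of gene pairs. Many pipelines work in the opposite direction: they
assert pairwise relations directly (from sequence similarity, synteny or
functional annotation) and represent them as a **relation graph** *R* —
genes as vertices, orthology as edges, paralogy as non-edges.

The converse direction can fail in two ways:

* *R* is **satisfiable** (realizable by *some* DS-tree) iff it contains no
  induced path on four vertices (iff it is a cograph); the realizing tree is
  the cotree, with join nodes labeled Spec and union nodes labeled Dup.
* *R* is ***S*-consistent** (realizable by a DS-tree that agrees with the
  species tree, i.e. every speciation's children map to separated species
  nodes under the LCA-mapping) iff, in addition, *S* displays every species
  triplet *s(x)s(y)|s(z)* induced by a 3-vertex induced path *x–z–y* of *R*
  (the set *P₃(R)*).

Real relation sets are noisy and usually violate both conditions, which
raises minimum-correction problems. All four studied here are NP-hard, but
they are perfectly solvable at the scale of a single gene family. This
package is for people who want exact answers at that scale, executable
versions of the reductions behind the hardness results, and seeded synthetic
ground truth to test against.

## What is implemented

* **Checkers and constructions** — Newick I/O for species trees and
  DS-trees, LCA machinery, triplet display, LCA-mapping, Fitch relations,
  both consistency checks (tree-level and graph-level), cotree realization,
  least-resolved speciation contraction, and the constructive route from an
  *S*-consistent graph to an *S*-consistent DS-tree.
* **Relation-preserving surgery** — binary refinement of multifurcations
  and single-leaf grafting, both leaving every existing orthology/paralogy
  relation and consistency intact.
* **Exact correctors** (branch and bound over *bad subgraphs*: induced P4s
  and contradictory 3-paths) — minimum edge removal, minimum editing (each
  P4 admits six single-pair editings, each contradictory 3-path three),
  maximum node consistency; plus exhaustive solvers for the two gene-tree
  correction problems (maximum preserved homology relations, maximum
  preserved clades) under partial constraint sets.
* **Approximation** — bad-subgraph elimination: repeatedly delete every
  edge incident to a bad subgraph; removes at most **4·Δ(R)** times the
  optimal number of edges, where Δ(R) is the maximum degree.
* **Gadget generators** — executable reductions: exact 3-cover → minimum
  edge removal (with certificate verifier), maximum independent set →
  maximum node consistency (with forward/backward mappings), node
  consistency → clade correction (caterpillar blocks), and the clique-tree
  construction linking edge removal to homology correction.
* **Simulation** — seeded duplication histories drawn along a species tree
  (always consistent by construction) and independent per-pair relation
  noise, for ground-truth experiments.

## Worked example

A relation graph asserting the orthology path `a1–b1–c1–d1` over four
species with species tree `(((a,b),c),d)` cannot come from any gene
history — the four genes induce a P4:

```python
import orthocorrect as oc

S = oc.parse_newick("(((a,b),c),d);")
genes = {"a1": "a", "b1": "b", "c1": "c", "d1": "d"}
R = oc.RelationGraph(genes, genes, [("a1", "b1"), ("b1", "c1"), ("c1", "d1")])

print("satisfiable:", oc.is_satisfiable(R))
print("bad subgraph:", oc.find_bad_subgraph(R, S))

fix = oc.min_edge_removal_exact(R, S)
print("minimum removals:", fix.objective)
print("edit script:", list(fix.edits))
print("corrected history:", fix.witness.newick())

keep = oc.max_node_consistency_exact(R, S)
print("max consistent genes:", keep.objective, keep.retained)
```

prints

```
satisfiable: False
bad subgraph: BadSubgraph(kind='p4', vertices=('a1', 'b1', 'c1', 'd1'), triplet=None)
minimum removals: 1
edit script: [(('b1', 'c1'), 'delete')]
corrected history: ((a1,b1)S,(c1,d1)S)D;
max consistent genes: 3 ('a1', 'c1', 'd1')
```

Deleting `b1–c1` is the unique single-edge repair: removing `a1–b1` would
leave the path `b1–c1–d1`, whose induced triplet *bd|c* the species tree
does not display, and symmetrically for `c1–d1`. The corrected witness is a
duplication over two speciation cherries — an ancestral duplication followed
by two independent speciations — which induces exactly the repaired
relation set. Alternatively, dropping the single gene `b1` keeps three genes
whose induced relations are consistent as they stand.

A command-line surface wraps the same functions (`orthocorrect check-sat`,
`check-consistency`, `correct-edges`, `correct-nodes`, `correct-tree`,
`gadget`, `simulate`); see `orthocorrect --help`.

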