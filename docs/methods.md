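# Methods

This note documents the model, the algorithmic and numerical choices, the
synthetic-data generator, and the problem sizes at which the test suite and
the acceptance script operate. It states no empirical result that the tests
or `scripts/acceptance.py` do not themselves compute.

## Model and assumptions

All trees are rooted. Internal nodes have at least two children; only the
root may have exactly two neighbors overall. A **species tree** *S* is a
rooted tree over a species set; a **DS-tree** (G, ev) is a rooted gene tree
whose internal nodes carry an event label in {Dup, Spec} and whose leaves
(genes) map to species through a total map *s*. Branch lengths, unrooted
trees and horizontal transfer are out of scope: the relation formalism only
distinguishes duplication from speciation.

Two structural facts anchor everything:

* **LCA-mapping.** Each gene-tree node maps to the lca in *S* of its
  descendant leaves' species. A speciation node is consistent when its
  children map to pairwise *separated* nodes — implemented exactly as
  lca(a, b) ∉ {a, b}. A DS-tree is *S*-consistent when every speciation
  node is. A corollary is enforced at construction time: two same-species
  genes can only coalesce at a duplication, so `DSTree` validation rejects
  any speciation node whose child subtrees share a species, independently
  of any species tree.
* **Graph-level characterization.** A full relation set, encoded as a graph
  *R* (orthology = edges), is satisfiable iff *R* is P4-free, and
  *S*-consistent iff additionally *S* displays every triplet of *P₃(R)*,
  the species triplets induced by 3-vertex induced paths. Both directions
  are constructive here: the cotree of a P4-free graph (join → Spec,
  union → Dup), made least-resolved by contracting Spec–Spec edges, is the
  realizing witness, and the package verifies it rather than trusting the
  construction.

Triplet display is computed by lca arithmetic — *ab|c* is displayed iff
lca(a, b) is a strict descendant of lca(a, b, c) — and cross-checked in the
tests against an independent restriction-based route.

## Solvers

**Bad subgraphs.** An induced subgraph is *bad* if it is a P4 or a 3-vertex
induced path whose species triplet *S* does not display. A graph is
consistent iff it has no bad subgraph. The detector scans 4-subsets in
lexicographic order (P4s first), then 3-paths; it is deterministic, so every
solver is. On graphs above 12 active vertices a cotree decomposition settles
P4-freeness first, so the quartic scan only runs when a P4 is guaranteed to
exist; this makes consistency checks on already-consistent inputs cheap
(the dominant case when screening simulated ground truth).

**Branch and bound.** Minimum edge removal branches on one of the 3 edges
of a P4 or the 2 edges of a contradictory 3-path; minimum editing on the 6
editings of a P4 (3 deletions, 3 insertions) or the 3 of a contradictory
3-path; maximum node consistency deletes one of the 4 (respectively 3)
vertices. Correctness of the branching rests on the candidate pairs being
*all* pairs within the bad subgraph: any solution must change at least one
of them, or the subgraph stays bad. Choices that matter:

* A pair is never edited twice along a branch (a frozen-pair set), which
  prevents cycles; insertions between same-species genes are pruned, since
  such pairs are paralogs by definition — this can reduce the editing
  branching factor below six.
* The incumbent is initialized from the bad-subgraph elimination heuristic,
  an admissible upper bound that tightens pruning from the start.
* Branch order is lexicographic in gene identifiers, and among equal-cost
  optima the lexicographically smallest script (or deleted-gene set) is
  returned; the problems themselves do not prescribe a tie-break, so this
  is a reproducibility choice.

**Exhaustive tree correctors.** The two gene-tree problems are solved by
enumeration, with hard caps (default 6 genes) and errors beyond them rather
than silent heuristics. Maximum homology correction enumerates every full
relation graph extending the constraints — valid because the objective
depends only on the corrected tree's relation set, and consistent relation
sets and consistent trees are interchangeable through the constructive
characterization. Maximum clade correction enumerates rooted binary
topologies when *S* is binary: binary refinement preserves relations and
consistency and only ever adds clades, so a binary optimum exists. For
non-binary *S* the search falls back to all rooted multifurcating
topologies. On each topology the labeling is forced — lcas of
orthology-constrained pairs must be Spec, of paralogy-constrained or
same-species pairs Dup, conflicts make the topology infeasible — and every
unforced node is labeled Dup, which can never violate consistency.

**Approximation.** While a bad subgraph exists, delete every edge incident
to its vertices. Each round costs at most 4·Δ(R) edges against at least one
edge any optimal solution must remove from that subgraph, giving the
4·Δ(R) guarantee. The heuristic isolates many vertices in practice; it is
used as an incumbent and a guaranteed fallback, not as a recommended
corrector.

## Surgery

Binary refinement resolves a duplication node by chaining its children
under nested Dup nodes, and a speciation node by splitting its children
according to which child of its mapped species node they descend into;
both preserve every pairwise relation and consistency, and require a binary
species tree (the speciation split follows that bipartition). Grafting a
new gene *x* orthologous to a partner *y* follows a deterministic case
order: connect above the root when the whole tree maps strictly below
lca_S(s(x), s(y)); otherwise the first existing node (in preorder) whose
attachment satisfies all postconditions; otherwise subdivide the edge below
the lowest ancestor of *y* mapping at or above that species lca, inserting
a speciation below a duplication or a duplication below a speciation as the
case requires. The case order among multiple valid grafting points is a
package choice for determinism, not forced by the construction. Every graft
is verified against its three postconditions before being returned.

## Gadget generators

The reductions are generated exactly as constructed, with the degrees of
freedom the constructions leave open resolved deterministically:

* **Exact 3-cover → edge removal.** Species blocks W, X₁..X_r (size
  α = C(3t, 2)) and Y₁..Y_r (size r²α); the internal shapes of the three
  species subtrees are unspecified by the construction and default to
  left-leaning caterpillars. The certificate verifier removes exactly
  3α(r−t) + (α−3t) edges for an exact cover and re-checks consistency.
* **Independent set → node consistency.** m genes per input vertex, blocks
  as cliques, cross edges only at equal index; the block subtrees and the
  backbone ("any binary tree") default to balanced shapes. The backward
  mapping extracts the largest equal-index class among multi-gene blocks.
  Note the reduction's forward direction gives a *lower bound* m·|V′| on
  the optimum, not its exact value: disjoint cross-block edges can push the
  optimum higher (a triangle input has optimum 4, not 3), which the tests
  assert by brute force.
* **Node consistency → clade correction.** Caterpillar blocks of n−1+α
  leaves (α = n(n−1−k)+2k) with the n−1 deepest leaves carrying one
  constraint each; the spine orientation (deepest leaves first) is the
  package's convention. The input gene tree is labeled all-Dup, which is
  trivially consistent; the objective ignores labels.
* **Clique tree → homology correction.** A copy of *S* with all-Spec
  labels, empty orthology constraints, paralogy constraints on the
  complement of E(R); the tests confirm the resulting optimum equals
  C(n,2) − |P| − (minimum edge-removal cost of R).

Clade counting includes the root clade and excludes singleton leaf clades,
so a binary tree on L leaves has L−1 clades; this convention is what makes
the gadget's printed clade counts come out exactly.

## Synthetic data

`simulate_history` draws a gene family top-down along *S*: at each step a
lineage duplicates with probability *p* (both copies continue at the same
species node, labeled Dup) or follows the species bifurcation (labeled
Spec; at a species leaf it becomes an extant gene). Defaults: 6 species,
duplication probability 0.2 — a modest rate giving families of roughly one
to four copies per species, typical of small paralog families — and
relation-flip probability 0.05 per pair for noise. Every simulated history
is consistent by construction, so solvers must return zero cost on derived
graphs; this closes the loop between generator and correctors and is tested
over 1000 seeded draws. Losses are not simulated: the relation formalism
never represents them, and deleting extant leaves is all a loss could do
here, exposed as an optional leaf-dropout probability (default 0). The
perturbation model is independent per-pair noise; real inference errors are
correlated (within clusters of similar sequences), so passing recovery
tests on this generator shows solver correctness, not robustness to
structured error.

All randomness flows from a single mandatory seed per run; CLI manifests
record it.

## Problem sizes used by the suite

Exhaustive sweeps run at desk scale: all labeled graphs on ≤5 vertices for
the realizability equivalences; all 64 four-gene graphs crossed with all 15
binary four-species topologies for the three-way solver/brute-force
agreement, plus a seeded 60-instance sample of the five-gene × 105-topology
cross; the approximation bound and the acceptance script use 100 seeded
eight-gene instances at edge probability 0.5, with the exact reference
certified by bounded brute force in the test; constructive-surgery suites
use 200 seeded instances each; the zero-correction sweep uses 1000 seeded
draws. The worked exact-3-cover instance (t = 2, r = 4, 1026 genes,
~130k edges) is built and verified in full.

## Known limitations

* The exact graph solvers are exponential in the worst case; they are meant
  for single families (tens of genes when nearly consistent, ~8–10 genes
  for dense noisy graphs). The tree correctors are capped at 6 genes.
* P4 witnesses are located by the quartic scan; linear-time modular
  decomposition would find one faster but is unnecessary at these sizes.
* `ConstraintSet` inputs must be internally coherent (disjoint O/P,
  no same-species orthology); transitivity of orthology across constraint
  chains is *not* enforced beyond what consistency itself implies.
* The simulator draws duplications as a per-step Bernoulli process, not
  from a calibrated birth–death model; rates are parameters, not estimates.
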