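"""Hardness-reduction gadget generators and certificate verifiers.

These constructions embed classic hard problems into the correction problems
and are useful both as stress instances and as executable checks that the
reductions' forward and backward mappings behave as intended:

* exact 3-cover -> minimum edge removal (:func:`x3c_instance`,
  :func:`x3c_certificate`);
* maximum independent set -> maximum node consistency
  (:func:`mis_instance`, :func:`mis_extract_independent_set`);
* maximum node consistency -> maximum clade correction
  (:func:`mcc_instance`);
* minimum edge removal -> maximum homology correction
  (:func:`clique_tree_instance`).

Subtree topologies the constructions leave open (the internal shape of the
species blocks) default to deterministic caterpillars or balanced trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Optional

from .relations import ConstraintSet, GraphError, RelationGraph, is_s_consistent_graph
from .trees import DUP, SPEC, DSTree, Node, SpeciesTree, TreeError, pair

__all__ = [
    "X3CInstance",
    "MISInstance",
    "MCCInstance",
    "CliqueTreeInstance",
    "x3c_instance",
    "x3c_certificate",
    "mis_instance",
    "mis_extract_independent_set",
    "mcc_instance",
    "clique_tree_instance",
]


# ---------------------------------------------------------------------------
# tree builders
# ---------------------------------------------------------------------------

def _caterpillar(labels: list) -> Node:
    """Left-leaning caterpillar: ((((l1,l2),l3),l4)...); l1, l2 deepest."""
    if len(labels) == 1:
        return Node(labels[0])
    node = Node()
    node.add(Node(labels[0]))
    node.add(Node(labels[1]))
    for lab in labels[2:]:
        parent = Node()
        parent.add(node)
        parent.add(Node(lab))
        node = parent
    return node


def _balanced(labels: list) -> Node:
    if len(labels) == 1:
        return Node(labels[0])
    mid = len(labels) // 2
    node = Node()
    node.add(_balanced(labels[:mid]))
    node.add(_balanced(labels[mid:]))
    return node


def _connect(t1: Node, t2: Node) -> Node:
    root = Node()
    root.add(t1)
    root.add(t2)
    return root


def _add_clique(R: RelationGraph, members: list) -> None:
    for u, v in combinations(members, 2):
        R.add_edge(u, v)


# ---------------------------------------------------------------------------
# Exact 3-cover -> minimum edge removal
# ---------------------------------------------------------------------------

@dataclass
class X3CInstance:
    """Edge-removal instance built from an exact-3-cover instance (W, Z).

    The species set is W plus r blocks X_i (size alpha = C(3t, 2)) and r
    blocks Y_i (size r^2 * alpha); the relation graph has the 2r+1 cliques
    W, X_1..X_r, Y_1..Y_r, all X_i-Y_i edges, and all X_i-Z_i edges. An
    exact cover exists iff the graph can be made S-consistent by deleting at
    most ``budget`` = 3*alpha*(r-t) + (alpha-3t) edges.
    """

    W: tuple
    Z: tuple
    t: int
    r: int
    alpha: int
    X: tuple  # r tuples of species names
    Y: tuple
    E1: frozenset
    E2: frozenset
    S: SpeciesTree
    R: RelationGraph
    budget: int


def x3c_instance(W: Iterable[str], Z: Iterable[Iterable[str]]) -> X3CInstance:
    W = tuple(sorted(str(w) for w in W))
    Z = tuple(tuple(sorted(str(z) for z in zs)) for zs in Z)
    if len(set(W)) != len(W) or len(W) % 3 != 0:
        raise GraphError("W must be a duplicate-free set of size 3t")
    t = len(W) // 3
    r = len(Z)
    if r < t:
        raise GraphError("need at least t candidate triples (r >= t)")
    wset = set(W)
    for zs in Z:
        if len(set(zs)) != 3 or not set(zs) <= wset:
            raise GraphError(f"each Z_i must be a 3-element subset of W (got {zs})")
    alpha = comb(3 * t, 2)
    X = tuple(
        tuple(f"x{i}_{j}" for j in range(1, alpha + 1)) for i in range(1, r + 1)
    )
    Y = tuple(
        tuple(f"y{i}_{j}" for j in range(1, r * r * alpha + 1))
        for i in range(1, r + 1)
    )
    species = list(W) + [s for xi in X for s in xi] + [s for yi in Y for s in yi]
    if len(set(species)) != len(species):
        raise GraphError("W labels collide with generated X/Y species names")

    s_w = _caterpillar(list(W))
    s_x = _caterpillar([s for xi in X for s in xi])
    s_y = _caterpillar([s for yi in Y for s in yi])
    S = SpeciesTree(_connect(_connect(s_y, s_w), s_x))

    # one gene per species; gene and species share the name
    R = RelationGraph(species, {s: s for s in species})
    _add_clique(R, list(W))
    for xi in X:
        _add_clique(R, list(xi))
    for yi in Y:
        _add_clique(R, list(yi))
    E1 = set()
    E2 = set()
    for i in range(r):
        for x in X[i]:
            for w in Z[i]:
                R.add_edge(x, w)
                E1.add(pair(x, w))
            for y in Y[i]:
                R.add_edge(x, y)
                E2.add(pair(x, y))
    budget = 3 * alpha * (r - t) + (alpha - 3 * t)
    return X3CInstance(
        W=W, Z=Z, t=t, r=r, alpha=alpha, X=X, Y=Y,
        E1=frozenset(E1), E2=frozenset(E2), S=S, R=R, budget=budget,
    )


def x3c_certificate(inst: X3CInstance, Zprime: Iterable[Iterable[str]]) -> RelationGraph:
    """Corrected relation graph for an exact cover Z': all X_i-Z_i edges are
    removed for Z_i not in Z', and the only surviving W-clique edges are the
    Z_i triangles with Z_i in Z'. Exactly ``budget`` edges are removed and
    the result is verified S-consistent."""
    Zprime = {tuple(sorted(str(z) for z in zs)) for zs in Zprime}
    for zs in Zprime:
        if zs not in set(inst.Z):
            raise GraphError(f"{zs} is not one of the candidate triples")
    covered = [w for zs in Zprime for w in zs]
    if len(covered) != len(inst.W) or set(covered) != set(inst.W):
        raise GraphError("Z' must be an exact cover (a partition of W)")

    Rp = inst.R.copy()
    removed = 0
    for i, zi in enumerate(inst.Z):
        if zi in Zprime:
            continue
        for x in inst.X[i]:
            for w in zi:
                if Rp.has_edge(x, w):
                    Rp.remove_edge(x, w)
                    removed += 1
    keep = {pair(u, v) for zs in Zprime for u, v in combinations(zs, 2)}
    for u, v in combinations(inst.W, 2):
        if pair(u, v) not in keep and Rp.has_edge(u, v):
            Rp.remove_edge(u, v)
            removed += 1
    assert removed == inst.budget, (
        f"certificate removed {removed} edges, budget is {inst.budget}"
    )
    check = is_s_consistent_graph(Rp, inst.S)
    if not check:
        raise AssertionError(f"certificate graph not S-consistent: {check.violation}")
    return Rp


# ---------------------------------------------------------------------------
# Maximum independent set -> maximum node consistency
# ---------------------------------------------------------------------------

@dataclass
class MISInstance:
    """Node-consistency instance from a graph H on m vertices: one clique
    I(v_i) of m genes per vertex, cross edges {r_{i,t}, r_{j,t}} for every
    H-edge {v_i, v_j} and every index t; n = m^2 genes, one per species."""

    vertices: tuple  # vertices of H, sorted
    edges: frozenset  # edges of H
    m: int
    gene_sets: dict  # H-vertex -> tuple of genes I(v)
    S: SpeciesTree
    R: RelationGraph


def mis_instance(H) -> MISInstance:
    """Build the instance from H given as a networkx graph or as a
    (vertices, edges) pair."""
    if hasattr(H, "nodes") and hasattr(H, "edges"):
        vertices = sorted(str(v) for v in H.nodes)
        edges = {pair(str(u), str(v)) for u, v in H.edges if u != v}
    else:
        vs, es = H
        vertices = sorted(str(v) for v in vs)
        edges = {pair(str(u), str(v)) for u, v in es if u != v}
    m = len(vertices)
    if m == 0:
        raise GraphError("H must have at least one vertex")
    gene_sets = {
        v: tuple(f"r{i}_{j}" for j in range(1, m + 1))
        for i, v in enumerate(vertices, start=1)
    }
    blocks = [_balanced(list(gene_sets[v])) if m > 1 else Node(gene_sets[v][0])
              for v in vertices]
    S = SpeciesTree(_balanced_over(blocks))
    genes = [g for v in vertices for g in gene_sets[v]]
    R = RelationGraph(genes, {g: g for g in genes})
    for v in vertices:
        _add_clique(R, list(gene_sets[v]))
    for u, v in edges:
        for t in range(m):
            R.add_edge(gene_sets[u][t], gene_sets[v][t])
    return MISInstance(
        vertices=tuple(vertices), edges=frozenset(edges), m=m,
        gene_sets=gene_sets, S=S, R=R,
    )


def _balanced_over(subtrees: list) -> Node:
    if len(subtrees) == 1:
        return subtrees[0]
    mid = len(subtrees) // 2
    node = Node()
    node.add(_balanced_over(subtrees[:mid]))
    node.add(_balanced_over(subtrees[mid:]))
    return node


def mis_extract_independent_set(inst: MISInstance, solution: Iterable[str]) -> frozenset:
    """Backward mapping: from an S-consistent retained gene set of size >= km
    recover an independent set of H of size >= k, via the largest index class
    R^j among the multi-gene blocks."""
    solution = set(solution)
    unknown = solution - set(inst.R.genes)
    if unknown:
        raise GraphError(f"unknown genes in solution: {sorted(unknown)[:5]}")
    sub = inst.R.induced(solution)
    check = is_s_consistent_graph(sub, inst.S)
    if not check:
        raise GraphError(
            f"solution does not induce an S-consistent subgraph: {check.violation}"
        )
    retained = {
        v: [g for g in inst.gene_sets[v] if g in solution] for v in inst.vertices
    }
    best_j: Optional[int] = None
    best_class: list = []
    for j in range(inst.m):
        cls = [
            v
            for v in inst.vertices
            if len(retained[v]) > 1 and inst.gene_sets[v][j] in solution
        ]
        if len(cls) > len(best_class):
            best_j, best_class = j, cls
    if best_class:
        return frozenset(best_class)
    # no multi-gene block: any single retained gene names an independent vertex
    for v in inst.vertices:
        if retained[v]:
            return frozenset([v])
    return frozenset()


# ---------------------------------------------------------------------------
# Maximum node consistency -> maximum clade correction
# ---------------------------------------------------------------------------

@dataclass
class MCCInstance:
    """Clade-correction instance from a node-consistency instance (R, S, k):
    a binary backbone over n caterpillar blocks T_i of n-1+alpha leaves (all
    of species s(v_i)), whose n-1 deepest leaves l_{i,j} carry one constraint
    each; alpha = n(n-1-k)+2k and the clade target is k' = k(alpha+n-2)."""

    source_R: RelationGraph
    S: SpeciesTree
    k: int
    alpha: int
    G: DSTree
    constraints: ConstraintSet
    k_prime: int
    deep_leaves: dict  # v_i -> tuple of the n-1 deep leaves l_{i,j} (j order)
    block_leaves: dict  # v_i -> tuple of all leaves of T_i


def mcc_instance(R: RelationGraph, S: SpeciesTree, k: int) -> MCCInstance:
    n = R.n
    if k > n:
        raise GraphError(f"k={k} exceeds the number of genes n={n}")
    species_values = list(R.species.values())
    if len(set(species_values)) != n:
        raise GraphError("the source instance must have one gene per species")
    alpha = n * (n - 1 - k) + 2 * k
    verts = list(R.genes)

    deep_leaves: dict = {}
    block_leaves: dict = {}
    blocks = []
    for v in verts:
        others = [u for u in verts if u != v]
        deep = tuple(f"l_{v}_{u}" for u in others)
        fillers = tuple(f"f_{v}_{j}" for j in range(1, alpha + 1))
        labels = list(deep) + list(fillers)  # deepest first
        blocks.append(_caterpillar(labels))
        deep_leaves[v] = deep
        block_leaves[v] = tuple(labels)
    root = _balanced_over(blocks)
    species_map = {
        leaf: R.species[v] for v in verts for leaf in block_leaves[v]
    }
    for node in _iter_internal(root):
        node.event = DUP
    G = DSTree(root, species_map)

    leaf_of = {
        (v, u): f"l_{v}_{u}" for v in verts for u in verts if u != v
    }
    O = []
    P = []
    for u, v in combinations(verts, 2):
        a, b = leaf_of[(u, v)], leaf_of[(v, u)]
        if R.has_edge(u, v):
            O.append((a, b))
        else:
            P.append((a, b))
    constraints = ConstraintSet(O=O, P=P)
    k_prime = k * (alpha + n - 2)
    return MCCInstance(
        source_R=R, S=S, k=k, alpha=alpha, G=G, constraints=constraints,
        k_prime=k_prime, deep_leaves=deep_leaves, block_leaves=block_leaves,
    )


def _iter_internal(root: Node):
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            yield node
            stack.extend(node.children)


# ---------------------------------------------------------------------------
# Minimum edge removal -> maximum homology correction
# ---------------------------------------------------------------------------

@dataclass
class CliqueTreeInstance:
    """Homology-correction instance from (R, S): the gene tree mimics S with
    all-speciation labels (its relation graph is a clique), O is empty and P
    is the complement of E(R); breaking a minimum of orthologies to satisfy
    P is exactly the minimum edge removal problem on (R, S)."""

    G: DSTree
    S: SpeciesTree
    constraints: ConstraintSet


def clique_tree_instance(R: RelationGraph, S: SpeciesTree) -> CliqueTreeInstance:
    by_species = {}
    for g in R.genes:
        sp = R.species[g]
        if sp in by_species:
            raise GraphError("genes must be in bijection with the species leaves")
        by_species[sp] = g
    if set(by_species) != set(S.leaf_labels):
        raise GraphError("genes must be in bijection with the species leaves")
    from .trees import copy_subtree

    root = copy_subtree(S.root)
    for node in _iter_internal(root):
        node.event = SPEC
    for node in _iter_leaves(root):
        node.label = by_species[node.label]
    species_map = {g: sp for sp, g in by_species.items()}
    G = DSTree(root, species_map)
    P = [
        pair(u, v)
        for u, v in combinations(sorted(R.genes), 2)
        if not R.has_edge(u, v)
    ]
    return CliqueTreeInstance(G=G, S=S, constraints=ConstraintSet(P=P))


def _iter_leaves(root: Node):
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            yield node
        else:
            stack.extend(node.children)
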