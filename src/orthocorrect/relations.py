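"""Relation graphs: orthology as edges, paralogy as non-edges.

A full set of orthology/paralogy relations over a gene family is represented
as a simple undirected graph whose vertices are genes. The graph is
*satisfiable* — realizable by some event-labeled gene tree — exactly when it
is P4-free (a cograph); the realizing tree is the cotree, with join nodes
labeled Spec and union nodes labeled Dup. The graph is *S-consistent* —
realizable by a gene tree that agrees with the species tree S — exactly when,
in addition, S displays every species triplet induced by a 3-vertex induced
path of the graph (the set ``P3(R)``).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional

import numpy as np

from .trees import (
    DUP,
    SPEC,
    ConsistencyCheck,
    DSTree,
    Node,
    SpeciesTree,
    TreeError,
    Triplet,
    displays_triplet,
    is_s_consistent_tree,
    pair,
    relations_of,
)

__all__ = [
    "RelationGraph",
    "ConstraintSet",
    "GraphError",
    "UnsatisfiableError",
    "relation_graph_of",
    "find_induced_p4",
    "is_satisfiable",
    "p3_triplets",
    "is_s_consistent_graph",
    "build_ds_tree",
    "least_resolved",
    "build_s_consistent_tree",
]


class GraphError(ValueError):
    """Invalid relation-graph input."""


class UnsatisfiableError(GraphError):
    """Raised when a realization is requested for a non-realizable graph.

    Carries a witness: an induced P4 (quadruple) for unsatisfiable graphs, or
    a non-displayed triplet for satisfiable but S-inconsistent ones.
    """

    def __init__(self, message: str, witness=None):
        super().__init__(message)
        self.witness = witness


class RelationGraph:
    """Simple undirected graph on genes; an edge is an orthology assertion,
    a non-edge a paralogy assertion. Two genes of the same species are never
    orthologous, so same-species edges are rejected at construction and on
    every edit."""

    def __init__(self, genes: Iterable[str], species_of: dict, edges: Iterable = ()):
        self.genes: tuple = tuple(sorted(set(genes)))
        missing = [g for g in self.genes if g not in species_of]
        if missing:
            raise GraphError(f"genes without species: {missing[:5]}")
        self.species = {g: species_of[g] for g in self.genes}
        self.adj: dict[str, set] = {g: set() for g in self.genes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic structure ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.genes)

    def has_edge(self, u: str, v: str) -> bool:
        return v in self.adj[u]

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise GraphError(f"self-loop on {u!r}")
        if u not in self.adj or v not in self.adj:
            raise GraphError(f"unknown gene in edge ({u!r}, {v!r})")
        if self.species[u] == self.species[v]:
            raise GraphError(
                f"{u!r} and {v!r} belong to the same species and cannot be orthologs"
            )
        self.adj[u].add(v)
        self.adj[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def edges(self) -> list:
        return sorted(pair(u, v) for u in self.genes for v in self.adj[u] if u < v)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adj.values()) // 2

    def degree(self, g: str) -> int:
        return len(self.adj[g])

    def max_degree(self) -> int:
        return max((len(s) for s in self.adj.values()), default=0)

    def copy(self) -> "RelationGraph":
        g = RelationGraph(self.genes, self.species)
        for u in self.genes:
            g.adj[u] = set(self.adj[u])
        return g

    def induced(self, subset: Iterable[str]) -> "RelationGraph":
        keep = set(subset)
        g = RelationGraph(keep, self.species)
        for u in keep:
            g.adj[u] = self.adj[u] & keep
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RelationGraph)
            and self.genes == other.genes
            and self.species == other.species
            and self.adj == other.adj
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RelationGraph(n={self.n}, m={self.n_edges})"

    # -- interop -----------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for v in self.genes:
            g.add_node(v, species=self.species[v])
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g, species_attr: str = "species") -> "RelationGraph":
        species = {v: g.nodes[v][species_attr] for v in g.nodes}
        return cls(g.nodes, species, g.edges)


class ConstraintSet:
    """A partial set of orthology (O) and paralogy (P) constraints on gene
    pairs. O and P must be disjoint, and a same-species pair may only appear
    in P (same-species genes are always paralogs)."""

    def __init__(self, O: Iterable = (), P: Iterable = ()):
        self.O: frozenset = frozenset(pair(u, v) for u, v in O)
        self.P: frozenset = frozenset(pair(u, v) for u, v in P)
        if self.O & self.P:
            raise GraphError(
                f"contradictory constraints (in both O and P): {sorted(self.O & self.P)[:3]}"
            )
        for u, v in self.O | self.P:
            if u == v:
                raise GraphError(f"constraint on a single gene {u!r}")

    def validate_species(self, species_of: dict) -> None:
        for u, v in self.O:
            if species_of[u] == species_of[v]:
                raise GraphError(
                    f"orthology constraint on same-species pair ({u!r}, {v!r})"
                )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ConstraintSet(|O|={len(self.O)}, |P|={len(self.P)})"


def relation_graph_of(G: DSTree) -> RelationGraph:
    """The relation graph R(G): vertices are the genes of G, edges its
    orthologous pairs."""
    rel = relations_of(G)
    return RelationGraph(G.genes, G.species, rel.orthologs)


# ---------------------------------------------------------------------------
# P4 machinery and satisfiability
# ---------------------------------------------------------------------------

def _p4_order(R: RelationGraph, quad) -> Optional[tuple]:
    """If the four vertices induce a P4, return them in path order
    (endpoints-first orientation with the smaller endpoint leading)."""
    sub = {v: R.adj[v] & set(quad) for v in quad}
    degs = sorted(len(sub[v]) for v in quad)
    if degs != [1, 1, 2, 2]:
        return None
    ends = sorted(v for v in quad if len(sub[v]) == 1)
    a = ends[0]
    b = next(iter(sub[a]))
    c = next(iter(sub[b] - {a}))
    d = next(iter(sub[c] - {b}))
    if d != ends[1] or a in sub[c] or a in sub[d] or b in sub[d]:
        return None
    return (a, b, c, d)


def find_induced_p4(R: RelationGraph, within: Optional[Iterable[str]] = None):
    """First induced path on four vertices in lexicographic scan order, as an
    ordered quadruple (a, b, c, d) with edges ab, bc, cd; None if P4-free."""
    pool = sorted(within) if within is not None else R.genes
    for quad in combinations(pool, 4):
        ordered = _p4_order(R, quad)
        if ordered is not None:
            return ordered
    return None


def _components(R: RelationGraph, subset: list) -> list:
    remaining = set(subset)
    comps = []
    for seed in subset:
        if seed not in remaining:
            continue
        comp = {seed}
        remaining.discard(seed)
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            new = R.adj[v] & remaining
            comp |= new
            remaining -= new
            frontier.extend(new)
        comps.append(sorted(comp))
    return comps


def _co_components(R: RelationGraph, subset: list) -> list:
    """Connected components of the complement of R[subset], without
    materializing the complement (BFS over the unvisited set)."""
    remaining = set(subset)
    comps = []
    for seed in subset:
        if seed not in remaining:
            continue
        comp = {seed}
        remaining.discard(seed)
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            new = remaining - R.adj[v]
            comp |= new
            remaining &= R.adj[v]
            frontier.extend(new)
        comps.append(sorted(comp))
    return comps


def is_satisfiable(R: RelationGraph) -> bool:
    """A full relation set is realizable by some DS-tree iff its graph is
    P4-free. Decided by attempting the cotree decomposition (polynomial),
    which agrees with the quartic induced-P4 scan."""
    return _cotree_root(R) is not None


def _cotree_root(R: RelationGraph):
    """Cotree of R as a Node tree (join -> Spec, union -> Dup), or None if R
    is not a cograph. Children are ordered by their smallest leaf."""
    if R.n == 0:
        raise GraphError("empty gene family")
    from .trees import postorder

    root_holder = Node(event=DUP)  # placeholder parent for the true root
    work: list[tuple] = [(list(R.genes), root_holder)]
    while work:
        sub, parent = work.pop()
        if len(sub) == 1:
            parent.add(Node(sub[0]))
            continue
        comps = _components(R, sub)
        if len(comps) > 1:
            node = parent.add(Node(event=DUP))
            kids = comps
        else:
            cocomps = _co_components(R, sub)
            if len(cocomps) == 1:
                return None  # connected and co-connected: not a cograph
            node = parent.add(Node(event=SPEC))
            kids = cocomps
        for k in kids:
            work.append((k, node))
    root = root_holder.children[0]
    root.parent = None
    # deterministic child order: smallest descendant leaf first
    smallest: dict[int, str] = {}
    for node in postorder(root):
        if node.is_leaf:
            smallest[id(node)] = node.label
        else:
            node.children.sort(key=lambda c: smallest[id(c)])
            smallest[id(node)] = smallest[id(node.children[0])]
    return root


def build_ds_tree(R: RelationGraph) -> DSTree:
    """Realize a satisfiable relation graph as a DS-tree: the cotree of R,
    with series (join) nodes labeled Spec and parallel (union) nodes labeled
    Dup. Raises :class:`UnsatisfiableError` with an induced-P4 witness when R
    is not P4-free."""
    root = _cotree_root(R)
    if root is None:
        witness = find_induced_p4(R)
        raise UnsatisfiableError(
            f"relation graph is not satisfiable: induced P4 {witness}", witness
        )
    return DSTree(root, dict(R.species))


def p3_triplets(R: RelationGraph) -> frozenset:
    """The species triplets induced by 3-vertex induced paths of R:
    s(x)s(y)|s(z) for every z adjacent to both x and y, with xy a non-edge
    and s(x) != s(y)."""
    if R.n > 80:
        return _p3_triplets_dense(R)
    out: set = set()
    for z in R.genes:
        nb = sorted(R.adj[z])
        for i in range(len(nb)):
            x = nb[i]
            ax = R.adj[x]
            sx = R.species[x]
            for j in range(i + 1, len(nb)):
                y = nb[j]
                if y in ax:
                    continue
                if sx == R.species[y]:
                    continue
                out.add(Triplet(sx, R.species[y], R.species[z]))
    return frozenset(out)


def _p3_triplets_dense(R: RelationGraph) -> frozenset:
    idx = {g: i for i, g in enumerate(R.genes)}
    n = R.n
    A = np.zeros((n, n), dtype=bool)
    for u in R.genes:
        iu = idx[u]
        for v in R.adj[u]:
            A[iu, idx[v]] = True
    species = [R.species[g] for g in R.genes]
    out: set = set()
    for z in range(n):
        nb = np.flatnonzero(A[z])
        if nb.size < 2:
            continue
        sub = A[np.ix_(nb, nb)]
        ii, jj = np.nonzero(~sub)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i >= j:
                continue
            x, y = int(nb[i]), int(nb[j])
            if species[x] == species[y]:
                continue
            out.add(Triplet(species[x], species[y], species[z]))
    return frozenset(out)


def is_s_consistent_graph(R: RelationGraph, S: SpeciesTree) -> ConsistencyCheck:
    """R is S-consistent iff it is satisfiable and S displays every triplet
    of P3(R). On failure the violation is ("p4", quadruple) or
    ("triplet", Triplet)."""
    for sp in set(R.species.values()):
        if sp not in S.leaf_labels:
            raise TreeError(f"species {sp!r} not present in the species tree")
    if not is_satisfiable(R):
        return ConsistencyCheck(False, ("p4", find_induced_p4(R)))
    for t in sorted(p3_triplets(R), key=str):
        if not displays_triplet(S, t):
            return ConsistencyCheck(False, ("triplet", t))
    return ConsistencyCheck(True, None)


def least_resolved(G: DSTree) -> DSTree:
    """Contract every speciation node into its speciation parent until no
    speciation has a speciation child. The induced orthology/paralogy
    relations are unchanged (the event at every leaf pair's lca is
    preserved)."""
    root = G.copy().root
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        if node.event == SPEC:
            # absorb Spec children (repeatedly, as grandchildren may be Spec)
            changed = True
            while changed:
                changed = False
                new_children: list[Node] = []
                for c in node.children:
                    if not c.is_leaf and c.event == SPEC:
                        new_children.extend(c.children)
                        changed = True
                    else:
                        new_children.append(c)
                node.children = new_children
            for c in node.children:
                c.parent = node
        stack.extend(node.children)
    return DSTree(root, dict(G.species))


def build_s_consistent_tree(R: RelationGraph, S: SpeciesTree) -> DSTree:
    """Realize an S-consistent relation graph as an S-consistent DS-tree.

    The satisfying cotree is made least-resolved in terms of speciation; when
    S displays all triplets of P3(R), that tree passes the speciation-node
    separation check against S. Raises :class:`UnsatisfiableError` carrying
    the violating P4 or triplet otherwise.
    """
    check = is_s_consistent_graph(R, S)
    if not check:
        raise UnsatisfiableError(
            f"relation graph is not S-consistent: {check.violation}", check.violation
        )
    G = least_resolved(build_ds_tree(R))
    verify = is_s_consistent_tree(G, S)
    assert verify.ok, "least-resolved realization must be S-consistent"
    return G
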