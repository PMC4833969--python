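"""Shared fixtures and independent oracle helpers.

The oracle helpers re-derive the definitions from scratch (quartic induced-P4
scans, restriction-based triplet display, nested-tuple tree evaluation) so
that solver and checker tests compare two independent routes to the same
answer.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import orthocorrect as oc


# ---------------------------------------------------------------------------
# Reconstructed worked example: species tree displaying ab|c, a consistent
# relation graph R, an unsatisfiable R' (induced P4 on {c1,b1,d1,a2}) and a
# satisfiable-but-inconsistent R'' (path a1-b1-c1 inducing ac|b).
# ---------------------------------------------------------------------------

SPECIES_NEWICK = "(((a,b),c),d);"
GENE_SPECIES = {"a1": "a", "a2": "a", "b1": "b", "c1": "c", "d1": "d"}


@pytest.fixture(scope="session")
def fig_species_tree() -> oc.SpeciesTree:
    return oc.parse_newick(SPECIES_NEWICK)


@pytest.fixture(scope="session")
def fig_gene_tree() -> oc.DSTree:
    return oc.parse_newick(
        "((((a1,b1)S,c1)S,d1)S,a2)D;", kind="ds", species_map=GENE_SPECIES
    )


@pytest.fixture(scope="session")
def fig_R(fig_gene_tree) -> oc.RelationGraph:
    return oc.relation_graph_of(fig_gene_tree)


@pytest.fixture(scope="session")
def fig_R_prime() -> oc.RelationGraph:
    """Unsatisfiable: {c1, b1, d1, a2} induce a P4."""
    return oc.RelationGraph(
        GENE_SPECIES, GENE_SPECIES, [("c1", "b1"), ("b1", "d1"), ("d1", "a2")]
    )


@pytest.fixture(scope="session")
def fig_R_double_prime() -> oc.RelationGraph:
    """Satisfiable but S-inconsistent: path a1-b1-c1 induces ac|b while the
    species tree displays ab|c."""
    sp = {"a1": "a", "b1": "b", "c1": "c"}
    return oc.RelationGraph(sp, sp, [("a1", "b1"), ("b1", "c1")])


# ---------------------------------------------------------------------------
# Random instance generators
# ---------------------------------------------------------------------------

def random_tree_with_multifurcations(n_leaves: int, rng) -> oc.SpeciesTree:
    """Random rooted tree, possibly multifurcating: random binary topology
    with random internal edges contracted."""
    S = oc.random_species_tree(n_leaves, rng)
    root = S.root
    # contract each non-root internal node with probability 1/2
    changed = True
    while changed:
        changed = False
        for node in list(_preorder(root)):
            if node.parent is None or node.is_leaf:
                continue
            if rng.random() < 0.4:
                parent = node.parent
                i = parent.children.index(node)
                parent.children[i:i + 1] = node.children
                for c in node.children:
                    c.parent = parent
                changed = True
                break
    return oc.SpeciesTree(root)


def _preorder(root):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def contract_same_event_edges(G: oc.DSTree, rng, prob: float = 0.5) -> oc.DSTree:
    """Contract random Dup-Dup and Spec-Spec edges: relations and
    S-consistency are preserved, the result is generally non-binary."""
    root = G.copy().root
    changed = True
    while changed:
        changed = False
        for node in list(_preorder(root)):
            if node.parent is None or node.is_leaf:
                continue
            if node.event == node.parent.event and rng.random() < prob:
                parent = node.parent
                i = parent.children.index(node)
                parent.children[i:i + 1] = node.children
                for c in node.children:
                    c.parent = parent
                changed = True
                break
    return oc.DSTree(root, dict(G.species))


def random_consistent_family(seed: int, n_species: int = 6,
                             dup_p: float = 0.25):
    """(S, G) with G a simulated S-consistent history."""
    rng = np.random.default_rng(seed)
    S = oc.random_species_tree(n_species, rng)
    G = oc.simulate_history(S, oc.SimConfig(seed=seed, duplication_probability=dup_p))
    return S, G


def random_relation_graph(n: int, p: float, seed: int) -> oc.RelationGraph:
    """Random graph on n genes in n distinct species (edge probability p)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    sp = {g: f"s{i}" for i, g in enumerate(genes)}
    edges = [
        (genes[i], genes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return oc.RelationGraph(genes, sp, edges)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_displays(S: oc.SpeciesTree, a: str, b: str, out: str) -> bool:
    """Triplet display decided by actual restriction, independently of the
    lca-arithmetic implementation."""
    sub = S.restrict({a, b, out})
    la, lb = sub.leaf(a), sub.leaf(b)
    return sub.lca2(la, lb) is not sub.root


_DISPLAY_CACHE: dict = {}


def _displayed_cached(S, a, b, out) -> bool:
    key = (id(S), a, b, out) if a <= b else (id(S), b, a, out)
    hit = _DISPLAY_CACHE.get(key)
    if hit is None:
        hit = oracle_displays(S, a, b, out)
        _DISPLAY_CACHE[key] = hit
    return hit


def oracle_is_p4_free(vertices, edges) -> bool:
    eset = {frozenset(e) for e in edges}
    for quad in combinations(sorted(vertices), 4):
        sub = [frozenset(p) for p in combinations(quad, 2) if frozenset(p) in eset]
        if len(sub) != 3:
            continue
        deg = {v: sum(1 for e in sub if v in e) for v in quad}
        if sorted(deg.values()) == [1, 1, 2, 2]:
            # three edges, degrees of a path, no cycle possible: it is a P4
            return False
    return True


def oracle_consistent(vertices, edges, species, S) -> bool:
    """Definition-level S-consistency of a relation graph: P4-free and every
    3-path species triplet displayed by S (display via restriction)."""
    if not oracle_is_p4_free(vertices, edges):
        return False
    adj = {v: set() for v in vertices}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    for z in vertices:
        for x, y in combinations(sorted(adj[z]), 2):
            if y in adj[x] or species[x] == species[y]:
                continue
            if not _displayed_cached(S, species[x], species[y], species[z]):
                return False
    return True


# ---------------------------------------------------------------------------
# Nested-tuple evaluation of labeled binary trees (oracle for realizability
# and tree-correction problems; independent of the package's tree classes)
# ---------------------------------------------------------------------------

def tuple_binary_topologies(leaves):
    items = sorted(leaves)
    trees = [items[0]]
    for leaf in items[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_tuple_insert(t, leaf))
        trees = nxt
    return trees


def _tuple_insert(t, x):
    out = [(t, x)]
    if isinstance(t, tuple):
        a, b = t
        out.extend((a2, b) for a2 in _tuple_insert(a, x))
        out.extend((a, b2) for b2 in _tuple_insert(b, x))
    return out


def tuple_leaves(t):
    if isinstance(t, str):
        return [t]
    return [x for part in t for x in tuple_leaves(part)]


def tuple_internal_count(t) -> int:
    if isinstance(t, str):
        return 0
    return 1 + sum(tuple_internal_count(p) for p in t)


def evaluate_labeled_tree(topo, labels, species, S):
    """For a binary nested-tuple topology and a tuple of D/S labels (preorder
    over internal nodes), return (ortholog pair frozenset, consistency bool,
    clade frozenset). Consistency is the speciation-separation condition,
    computed from scratch."""
    counter = [0]

    def walk(t):
        # returns (leafset, ok_so_far, orths, clades)
        if isinstance(t, str):
            return [t], True, set(), set()
        my_label = labels[counter[0]]
        counter[0] += 1
        parts = [walk(p) for p in t]
        leafsets = [p[0] for p in parts]
        ok = all(p[1] for p in parts)
        orths = set().union(*(p[2] for p in parts))
        clades = set().union(*(p[3] for p in parts))
        merged = [x for ls in leafsets for x in ls]
        clades.add(frozenset(merged))
        if my_label == "S":
            for i in range(len(leafsets)):
                for j in range(i + 1, len(leafsets)):
                    for x in leafsets[i]:
                        for y in leafsets[j]:
                            orths.add(frozenset((x, y)))
            if ok:
                mapped = [
                    S.lca_leaves({species[x] for x in ls}) for ls in leafsets
                ]
                for i in range(len(mapped)):
                    for j in range(i + 1, len(mapped)):
                        if not S.separated(mapped[i], mapped[j]):
                            ok = False
            # same-species pair under a speciation lca is structurally invalid
            for i in range(len(leafsets)):
                for j in range(i + 1, len(leafsets)):
                    si = {species[x] for x in leafsets[i]}
                    sj = {species[x] for x in leafsets[j]}
                    if si & sj:
                        ok = False
        return merged, ok, orths, clades

    _, ok, orths, clades = walk(topo)
    return frozenset(orths), ok, frozenset(clades)


def all_labelings(n_internal: int):
    for mask in range(1 << n_internal):
        yield tuple("S" if mask >> i & 1 else "D" for i in range(n_internal))
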