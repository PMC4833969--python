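"""Rooted species trees and event-labeled (duplication/speciation) gene trees.

The two central objects are :class:`SpeciesTree` — a rooted tree whose leaves
are species — and :class:`DSTree` — a rooted gene tree whose internal nodes are
labeled ``Dup`` or ``Spec`` and whose leaves (genes) carry a species assignment.
A DS-tree induces a full partition of gene pairs into orthologs (pairs whose
lowest common ancestor is a speciation) and paralogs (duplication), following
Fitch's terminology.

All trees are rooted; internal nodes have at least two children (the root may
have exactly two). Trees store children in order, but every semantic operation
here (LCA, relations, consistency, clades) is independent of child order.
Traversals are iterative throughout so that deep caterpillar trees do not hit
the interpreter recursion limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional

import dendropy

DUP = "D"
SPEC = "S"

__all__ = [
    "DUP",
    "SPEC",
    "Node",
    "SpeciesTree",
    "DSTree",
    "Triplet",
    "RelationSet",
    "TreeError",
    "parse_newick",
    "lca",
    "restrict",
    "displays_triplet",
    "lca_mapping",
    "relations_of",
    "is_s_consistent_tree",
    "ConsistencyCheck",
    "common_clades",
    "find_witness_pair",
]


class TreeError(ValueError):
    """Malformed or invariant-violating tree input."""


class Node:
    """A node of a rooted tree.

    ``label`` holds the leaf identifier (species or gene name); ``event`` holds
    the Dup/Spec label on internal nodes of a DS-tree and is ``None`` elsewhere.
    """

    __slots__ = ("children", "parent", "label", "event")

    def __init__(self, label: Optional[str] = None, event: Optional[str] = None):
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.label = label
        self.event = event

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node(event={self.event!r}, n_children={len(self.children)})"


def preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def postorder(root: Node) -> Iterator[Node]:
    out: list[Node] = []
    stack = [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return reversed(out)


def leaves_of(root: Node) -> list[Node]:
    return [n for n in preorder(root) if n.is_leaf]


def copy_subtree(root: Node) -> Node:
    """Deep copy of a subtree (new Node objects, same labels/events)."""
    new_root = Node(root.label, root.event)
    stack = [(root, new_root)]
    while stack:
        old, new = stack.pop()
        for child in old.children:
            c = new.add(Node(child.label, child.event))
            stack.append((child, c))
    return new_root


def _write_newick(root: Node, internal_label) -> str:
    parts: list[str] = []
    stack: list[object] = [root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            parts.append(item)
            continue
        node = item
        if node.is_leaf:
            parts.append(node.label or "")
            continue
        parts.append("(")
        stack.append(")" + (internal_label(node) or ""))
        k = len(node.children)
        for i, child in enumerate(reversed(node.children)):
            stack.append(child)
            if i != k - 1:
                stack.append(",")
    return "".join(parts) + ";"


class _RootedTree:
    """Shared indexing (parents, depths, leaf lookup) for rooted trees."""

    def __init__(self, root: Node):
        self.root = root
        self._depth: dict[int, int] = {}
        self._leaf_by_label: dict[str, Node] = {}
        self._lca_cache: dict[tuple, Node] = {}
        self._index()

    def _index(self) -> None:
        self._depth.clear()
        self._leaf_by_label.clear()
        self._depth[id(self.root)] = 0
        self.root.parent = None
        stack = [self.root]
        n_nodes = 0
        while stack:
            node = stack.pop()
            n_nodes += 1
            d = self._depth[id(node)]
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("unlabeled leaf")
                if node.label in self._leaf_by_label:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                self._leaf_by_label[node.label] = node
            else:
                if len(node.children) < 2:
                    raise TreeError("internal node with fewer than two children")
                for child in node.children:
                    child.parent = node
                    self._depth[id(child)] = d + 1
                    stack.append(child)
        self._n_nodes = n_nodes

    # -- basic accessors ---------------------------------------------------
    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self._leaf_by_label)

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise TreeError(f"no leaf labeled {label!r}") from None

    def leaves(self) -> list[Node]:
        return leaves_of(self.root)

    def nodes(self) -> list[Node]:
        return list(preorder(self.root))

    def internal_nodes(self) -> list[Node]:
        return [n for n in preorder(self.root) if not n.is_leaf]

    def depth(self, node: Node) -> int:
        return self._depth[id(node)]

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- lowest common ancestors -------------------------------------------
    def lca2(self, u: Node, v: Node) -> Node:
        # trees are immutable after construction, so pairwise lcas are cached
        key = (id(u), id(v)) if id(u) <= id(v) else (id(v), id(u))
        hit = self._lca_cache.get(key)
        if hit is not None:
            return hit
        du, dv = self._depth[id(u)], self._depth[id(v)]
        while du > dv:
            u = u.parent
            du -= 1
        while dv > du:
            v = v.parent
            dv -= 1
        while u is not v:
            u = u.parent
            v = v.parent
        self._lca_cache[key] = u
        return u

    def lca(self, nodes: Iterable[Node]) -> Node:
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise TreeError("lca of an empty node set is undefined") from None
        for node in it:
            acc = self.lca2(acc, node)
        return acc

    def lca_leaves(self, labels: Iterable[str]) -> Node:
        return self.lca(self.leaf(x) for x in labels)

    def separated(self, u: Node, v: Node) -> bool:
        """Neither node an ancestor of the other: lca(u, v) not in {u, v}."""
        a = self.lca2(u, v)
        return a is not u and a is not v

    def is_ancestor(self, u: Node, v: Node) -> bool:
        """True iff u is an (inclusive) ancestor of v."""
        return self.lca2(u, v) is u

    # -- clades ------------------------------------------------------------
    def clades(self) -> frozenset:
        """Leaf-label sets of all internal nodes (root included, singleton
        leaf clades excluded)."""
        sets: dict[int, set] = {}
        out = []
        for node in postorder(self.root):
            if node.is_leaf:
                sets[id(node)] = {node.label}
            else:
                acc: set = set()
                for child in node.children:
                    acc |= sets.pop(id(child))
                sets[id(node)] = acc
                out.append(frozenset(acc))
        return frozenset(out)


class SpeciesTree(_RootedTree):
    """A rooted species tree over a species set; leaves are species names."""

    def newick(self) -> str:
        return _write_newick(self.root, lambda n: None)

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(copy_subtree(self.root))

    def restrict(self, labels: Iterable[str]) -> "SpeciesTree":
        return SpeciesTree(_restrict_root(self, labels))

    def displays(self, triplet: "Triplet") -> bool:
        return displays_triplet(self, triplet)


class DSTree(_RootedTree):
    """An event-labeled gene tree: internal nodes carry Dup/Spec, leaves are
    genes, and ``species`` maps each gene to its species.

    Validation enforces the structural corollary of reconciliation: two genes
    of the same species can only coalesce at a duplication, so no speciation
    node may have two children whose subtrees share a species.
    """

    def __init__(self, root: Node, species: dict):
        super().__init__(root)
        missing = self.leaf_labels - set(species)
        if missing:
            raise TreeError(f"genes without species assignment: {sorted(missing)[:5]}")
        self.species = {g: species[g] for g in self.leaf_labels}
        self._validate_events()

    def _validate_events(self) -> None:
        species_below: dict[int, set] = {}
        for node in postorder(self.root):
            if node.is_leaf:
                species_below[id(node)] = {self.species[node.label]}
                continue
            if node.event not in (DUP, SPEC):
                raise TreeError(
                    f"internal node lacks a D/S event label (got {node.event!r})"
                )
            child_sets = [species_below.pop(id(c)) for c in node.children]
            if node.event == SPEC:
                seen: set = set()
                for cs in child_sets:
                    if seen & cs:
                        raise TreeError(
                            "speciation node has two same-species descendants in "
                            "distinct child subtrees (their lca must be a duplication)"
                        )
                    seen |= cs
                species_below[id(node)] = seen
            else:
                acc: set = set()
                for cs in child_sets:
                    acc |= cs
                species_below[id(node)] = acc

    @property
    def genes(self) -> frozenset:
        return self.leaf_labels

    def event(self, node: Node) -> str:
        return node.event

    def newick(self) -> str:
        return _write_newick(self.root, lambda n: n.event)

    def copy(self) -> "DSTree":
        return DSTree(copy_subtree(self.root), dict(self.species))

    def restrict(self, genes: Iterable[str]) -> "DSTree":
        keep = set(genes)
        return DSTree(_restrict_root(self, keep), {g: self.species[g] for g in keep})


@dataclass(frozen=True)
class Triplet:
    """A rooted species triplet ``ab|out``: a and b are closer to each other
    than either is to ``out``. Stored with ``a < b`` for canonical equality."""

    a: str
    b: str
    out: str

    def __post_init__(self):
        if len({self.a, self.b, self.out}) != 3:
            raise TreeError("triplet species must be pairwise distinct")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    def __str__(self) -> str:
        return f"{self.a}{self.b}|{self.out}"


class RelationSet(NamedTuple):
    """Full orthology/paralogy partition of the gene pairs of a DS-tree."""

    orthologs: frozenset
    paralogs: frozenset


class ConsistencyCheck(NamedTuple):
    """Boolean result carrying the first violating node (or witness) if any."""

    ok: bool
    violation: object = None

    def __bool__(self) -> bool:
        return self.ok


def pair(x: str, y: str) -> tuple:
    """Canonical unordered gene pair."""
    return (x, y) if x <= y else (y, x)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, kind: str = "species", species_map: Optional[dict] = None):
    """Parse a Newick string into a :class:`SpeciesTree` or :class:`DSTree`.

    For ``kind="ds"`` every internal node must carry a ``D`` or ``S`` label
    immediately after its closing parenthesis, and ``species_map`` must map
    every gene (leaf) to its species.
    """
    if kind not in ("species", "ds"):
        raise ValueError(f"kind must be 'species' or 'ds', got {kind!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        root = Node()
        stack = [(dnode, root)]
        while stack:
            dn, n = stack.pop()
            kids = dn.child_nodes()
            if not kids:
                n.label = dn.taxon.label if dn.taxon else dn.label
                if n.label is None:
                    raise TreeError("leaf without a label")
            else:
                if kind == "ds":
                    if dn.label not in (DUP, SPEC):
                        raise TreeError(
                            "internal node of a DS-tree must be labeled 'D' or 'S'"
                            f" (got {dn.label!r})"
                        )
                    n.event = dn.label
                for dc in kids:
                    stack.append((dc, n.add(Node())))
        return root

    seed = dtree.seed_node
    # dendropy may wrap a trailing-semicolon tree in a unary seed node
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]
    root = convert(seed)
    if kind == "species":
        return SpeciesTree(root)
    if not root.children:
        # single-gene family: a lone leaf
        if species_map is None or root.label not in species_map:
            raise TreeError("DS-tree requires a gene-to-species map covering all genes")
        return DSTree(root, species_map)
    if species_map is None:
        raise TreeError("DS-tree requires a gene-to-species map")
    return DSTree(root, species_map)


def _restrict_root(tree: _RootedTree, labels: Iterable[str]) -> Node:
    keep = set(labels)
    if not keep:
        raise TreeError("cannot restrict a tree to an empty leaf set")
    unknown = keep - tree.leaf_labels
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)[:5]}")
    top = tree.lca_leaves(keep)

    def prune(old: Node) -> Optional[Node]:
        # returns the restricted copy of the subtree at `old`, with degree-2
        # (single-child) internal nodes contracted; None when nothing is kept
        built: dict[int, Optional[Node]] = {}
        for node in postorder(old):
            if node.is_leaf:
                built[id(node)] = (
                    Node(node.label, node.event) if node.label in keep else None
                )
                continue
            kids = [built.pop(id(c)) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                built[id(node)] = None
            elif len(kids) == 1:
                built[id(node)] = kids[0]
            else:
                n = Node(node.label, node.event)
                for k in kids:
                    n.add(k)
                built[id(node)] = n
        return built[id(old)]

    new_root = prune(top)
    assert new_root is not None
    return new_root


# ---------------------------------------------------------------------------
# Spec-level operations (thin functional surface over the classes)
# ---------------------------------------------------------------------------

def lca(tree: _RootedTree, nodes: Iterable[Node]) -> Node:
    """Deepest common ancestor of a non-empty node set; lca({u}) = u."""
    return tree.lca(nodes)


def restrict(tree, labels: Iterable[str]):
    """Restriction of a tree to a leaf subset: rooted at the subset's lca,
    other leaves removed, degree-two internal nodes contracted."""
    return tree.restrict(labels)


def displays_triplet(S: SpeciesTree, t: Triplet) -> bool:
    """True iff S displays ab|out, i.e. in S restricted to the three species,
    lca(a, b) is not the root. Computed via two lca queries: displayed iff
    lca(a, b) is a strict descendant of lca(a, b, out)."""
    la = S.leaf(t.a)
    lb = S.leaf(t.b)
    lo = S.leaf(t.out)
    ab = S.lca2(la, lb)
    return S.lca2(ab, lo) is not ab


def lca_mapping(G: DSTree, S: SpeciesTree) -> dict:
    """The LCA-mapping s_G: each leaf maps to its species' leaf in S, each
    internal node to the lca in S of its descendant leaves' species.

    Returns a dict from G's nodes to S's nodes.
    """
    for sp in set(G.species.values()):
        if sp not in S.leaf_labels:
            raise TreeError(f"species {sp!r} not present in the species tree")
    mapping: dict[int, Node] = {}
    result: dict[Node, Node] = {}
    for node in postorder(G.root):
        if node.is_leaf:
            m = S.leaf(G.species[node.label])
        else:
            m = S.lca(mapping.pop(id(c)) for c in node.children)
        mapping[id(node)] = m
        result[node] = m
    return result


def relations_of(G: DSTree) -> RelationSet:
    """Full orthology/paralogy partition: a pair is orthologous iff the event
    at its lca is a speciation, paralogous iff a duplication."""
    orth: set = set()
    para: set = set()
    below: dict[int, list] = {}
    for node in postorder(G.root):
        if node.is_leaf:
            below[id(node)] = [node.label]
            continue
        kids = [below.pop(id(c)) for c in node.children]
        bucket = orth if node.event == SPEC else para
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for x in kids[i]:
                    for y in kids[j]:
                        bucket.add(pair(x, y))
        merged = [x for k in kids for x in k]
        below[id(node)] = merged
    return RelationSet(frozenset(orth), frozenset(para))


def is_s_consistent_tree(G: DSTree, S: SpeciesTree) -> ConsistencyCheck:
    """Check that every speciation node of G has children mapping (via the
    LCA-mapping) to pairwise separated nodes of S. Returns the first
    violating speciation node on failure."""
    smap = lca_mapping(G, S)
    for node in preorder(G.root):
        if node.is_leaf or node.event != SPEC:
            continue
        mapped = [smap[c] for c in node.children]
        for i in range(len(mapped)):
            for j in range(i + 1, len(mapped)):
                if not S.separated(mapped[i], mapped[j]):
                    return ConsistencyCheck(False, node)
    return ConsistencyCheck(True, None)


def common_clades(G: _RootedTree, H: _RootedTree) -> int:
    """Number of clades (internal-node leaf sets, root included, singletons
    excluded) shared by two trees on the same leaf set. A binary tree on L
    leaves has L-1 such clades."""
    if G.leaf_labels != H.leaf_labels:
        raise TreeError("common_clades requires identical leaf sets")
    return len(G.clades() & H.clades())


def find_witness_pair(G: DSTree, S: SpeciesTree, v: Node):
    """For an internal node v of G, find leaves x, y of the subtree at v with
    lca_S(s(x), s(y)) = s_G(v) and lca_G(x, y) = v. Such a pair always exists;
    the lexicographically first one is returned."""
    if v.is_leaf:
        raise TreeError("witness pairs are defined for internal nodes")
    smap = lca_mapping(G, S)
    target = smap[v]
    labels = sorted(n.label for n in leaves_of(v))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            x, y = labels[i], labels[j]
            if G.lca2(G.leaf(x), G.leaf(y)) is not v:
                continue
            if S.lca2(S.leaf(G.species[x]), S.leaf(G.species[y])) is target:
                return (x, y)
    raise AssertionError("witness pair must exist for every internal node")
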