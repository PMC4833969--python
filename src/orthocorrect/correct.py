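"""Correction problems for relation graphs and gene trees.

Four problems are solved exactly at desk scale, plus one approximation:

* minimum edge removal — fewest orthology edges to delete so the graph
  becomes consistent with the species tree;
* minimum editing — fewest edge deletions *and* insertions;
* maximum node consistency — largest gene subset whose induced relation
  graph is consistent;
* maximum homology / maximum clade correction — given a consistent gene tree
  and partial constraints, find a consistent tree satisfying the constraints
  while preserving as many relations (respectively clades) as possible;
* bad-subgraph elimination — the approximation that repeatedly removes every
  edge incident to a bad induced subgraph (an induced P4, or a 3-vertex path
  whose species triplet the species tree does not display); it removes at
  most 4*Delta(R) times the optimal number of edges.

The exact graph solvers are branch and bound: each induced P4 admits six
single-pair editings (three deletions, three insertions) and each
contradictory 3-path admits three; a pair is never edited twice along a
branch, insertions between same-species genes are pruned, and the incumbent
is initialized from the approximation. Branching follows lexicographic gene
order, and ties between equal-cost optima are broken toward the
lexicographically smallest script, making every solver deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple, Optional

from .relations import (
    ConstraintSet,
    GraphError,
    RelationGraph,
    build_s_consistent_tree,
    is_s_consistent_graph,
    relation_graph_of,
)
from .trees import (
    DUP,
    SPEC,
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
    "BadSubgraph",
    "EditScript",
    "CorrectionResult",
    "find_bad_subgraph",
    "min_edge_removal_exact",
    "min_edit_exact",
    "max_node_consistency_exact",
    "approx_bad_subgraph_removal",
    "max_homology_correction_exact",
    "max_clade_correction_exact",
    "rooted_binary_topologies",
    "rooted_topologies",
]


class BadSubgraph(NamedTuple):
    """A witness making the graph inconsistent: kind is "p4" (vertices are an
    ordered induced path a-b-c-d) or "p3" (vertices are (x, z, y) with center
    z and ``triplet`` the induced species triplet not displayed by S)."""

    kind: str
    vertices: tuple
    triplet: Optional[Triplet] = None


@dataclass(frozen=True)
class EditScript:
    """Ordered single-pair edits; each pair appears at most once, and an
    insertion never joins two genes of the same species."""

    edits: tuple

    @property
    def cost(self) -> int:
        return len(self.edits)

    def __iter__(self):
        return iter(self.edits)


@dataclass
class CorrectionResult:
    problem: str
    objective: Optional[int]
    optimal: bool
    feasible: bool = True
    edits: Optional[EditScript] = None
    retained: Optional[tuple] = None
    tree: Optional[DSTree] = None
    witness: Optional[DSTree] = None
    max_degree: Optional[int] = None

    def to_json_dict(self) -> dict:
        out = {
            "problem": self.problem,
            "objective": self.objective,
            "optimal": self.optimal,
            "feasible": self.feasible,
        }
        if self.edits is not None:
            out["edits"] = [[list(p), op] for p, op in self.edits]
        if self.retained is not None:
            out["retained"] = list(self.retained)
        if self.tree is not None:
            out["newick"] = self.tree.newick()
        if self.witness is not None:
            out["witness_newick"] = self.witness.newick()
        if self.max_degree is not None:
            out["max_degree"] = self.max_degree
        return out


# ---------------------------------------------------------------------------
# Bitmask core shared by the graph solvers
# ---------------------------------------------------------------------------

class _Core:
    """Adjacency bitmasks over the sorted gene list, with a species-triplet
    display cache against the species tree."""

    def __init__(self, R: RelationGraph, S: SpeciesTree):
        self.genes = R.genes
        self.n = len(self.genes)
        self.idx = {g: i for i, g in enumerate(self.genes)}
        self.species = [R.species[g] for g in self.genes]
        for sp in set(self.species):
            if sp not in S.leaf_labels:
                raise TreeError(f"species {sp!r} not present in the species tree")
        self.S = S
        self.adj = [0] * self.n
        for u, v in R.edges():
            iu, iv = self.idx[u], self.idx[v]
            self.adj[iu] |= 1 << iv
            self.adj[iv] |= 1 << iu
        self._disp: dict[tuple, bool] = {}

    def displayed(self, x: int, y: int, z: int) -> bool:
        key = (self.species[x], self.species[y], self.species[z])
        hit = self._disp.get(key)
        if hit is None:
            hit = displays_triplet(self.S, Triplet(*key))
            self._disp[key] = hit
            self._disp[(key[1], key[0], key[2])] = hit
        return hit

    def graph(self, adj: list, active_mask: Optional[int] = None) -> RelationGraph:
        if active_mask is None:
            active_mask = (1 << self.n) - 1
        keep = [g for i, g in enumerate(self.genes) if active_mask >> i & 1]
        species = {g: self.species[self.idx[g]] for g in keep}
        g = RelationGraph(keep, species)
        for i in range(self.n):
            if not active_mask >> i & 1:
                continue
            m = adj[i] & active_mask
            while m:
                j = (m & -m).bit_length() - 1
                m &= m - 1
                if i < j:
                    g.add_edge(self.genes[i], self.genes[j])
        return g

    def find_bad(self, adj: list, active_mask: Optional[int] = None):
        """First bad induced subgraph in deterministic scan order: induced
        P4s (lexicographic 4-subsets) before contradictory 3-paths."""
        if active_mask is None:
            active_mask = (1 << self.n) - 1
        active = [i for i in range(self.n) if active_mask >> i & 1]
        # on larger graphs, settle P4-freeness by cotree decomposition first
        # so the quartic scan only runs when a P4 is guaranteed to exist
        if len(active) > 12 and _is_cograph_mask(adj, active_mask):
            return self._find_bad_p3(adj, active)
        for a, b, c, d in combinations(active, 4):
            quad = (a, b, c, d)
            bits = {}
            deg = dict.fromkeys(quad, 0)
            n_edges = 0
            for u, v in combinations(quad, 2):
                e = adj[u] >> v & 1
                bits[(u, v)] = e
                if e:
                    n_edges += 1
                    deg[u] += 1
                    deg[v] += 1
            if n_edges != 3 or sorted(deg.values()) != [1, 1, 2, 2]:
                continue
            ends = sorted(v for v in quad if deg[v] == 1)
            p = ends[0]
            path = [p]
            prev = None
            while len(path) < 4:
                nxt = next(
                    v for v in quad
                    if v != prev and v != p and bits.get((min(p, v), max(p, v)))
                )
                prev, p = p, nxt
                path.append(p)
            return ("p4", tuple(path))
        return self._find_bad_p3(adj, active)

    def _find_bad_p3(self, adj: list, active: list):
        active_mask = 0
        for i in active:
            active_mask |= 1 << i
        for z in active:
            nbm = adj[z] & active_mask
            nb = []
            m = nbm
            while m:
                nb.append((m & -m).bit_length() - 1)
                m &= m - 1
            for xi in range(len(nb)):
                x = nb[xi]
                for yi in range(xi + 1, len(nb)):
                    y = nb[yi]
                    if adj[x] >> y & 1:
                        continue
                    if self.species[x] == self.species[y]:
                        continue
                    if not self.displayed(x, y, z):
                        return ("p3", (x, z, y))
        return None


def _mask_split(adj: list, mask: int, complement: bool) -> list:
    """Connected components of the (complement of the) induced subgraph on
    ``mask``, as bitmasks."""
    comps = []
    rem = mask
    while rem:
        seed = rem & -rem
        comp = seed
        frontier = seed
        rem ^= seed
        while frontier:
            v = (frontier & -frontier).bit_length() - 1
            frontier &= frontier - 1
            new = (rem & ~adj[v]) if complement else (rem & adj[v])
            comp |= new
            rem &= ~new
            frontier |= new
        comps.append(comp)
    return comps


def _is_cograph_mask(adj: list, mask: int) -> bool:
    stack = [mask]
    while stack:
        m = stack.pop()
        if bin(m).count("1") <= 3:
            continue
        parts = _mask_split(adj, m, complement=False)
        if len(parts) == 1:
            parts = _mask_split(adj, m, complement=True)
            if len(parts) == 1:
                return False
        stack.extend(parts)
    return True


def find_bad_subgraph(R: RelationGraph, S: SpeciesTree) -> Optional[BadSubgraph]:
    """First bad induced subgraph of R w.r.t. S, or None iff R is
    S-consistent. P4 witnesses are reported before contradictory-triplet
    witnesses."""
    core = _Core(R, S)
    bad = core.find_bad(core.adj)
    if bad is None:
        return None
    kind, verts = bad
    names = tuple(core.genes[i] for i in verts)
    if kind == "p4":
        return BadSubgraph("p4", names)
    x, z, y = verts
    t = Triplet(core.species[x], core.species[y], core.species[z])
    return BadSubgraph("p3", names, t)


# ---------------------------------------------------------------------------
# Approximation: bad-subgraph elimination
# ---------------------------------------------------------------------------

def _approx_removals(core: _Core, adj: list) -> list:
    """Repeatedly find a bad subgraph and delete every edge incident to its
    vertices; mutates ``adj`` and returns the removed index pairs."""
    removed = []
    while True:
        bad = core.find_bad(adj)
        if bad is None:
            return removed
        for v in bad[1]:
            m = adj[v]
            while m:
                u = (m & -m).bit_length() - 1
                m &= m - 1
                removed.append((min(u, v), max(u, v)))
                adj[u] &= ~(1 << v)
            adj[v] = 0


def approx_bad_subgraph_removal(R: RelationGraph, S: SpeciesTree) -> CorrectionResult:
    """Bad-subgraph elimination: while a bad induced subgraph exists, remove
    all edges incident to its vertices. Removes at most 4*Delta(R) times the
    optimal number of edges."""
    core = _Core(R, S)
    adj = list(core.adj)
    removed = _approx_removals(core, adj)
    script = EditScript(
        tuple(
            ((core.genes[i], core.genes[j]), "delete")
            for i, j in sorted(removed)
        )
    )
    witness = build_s_consistent_tree(core.graph(adj), S) if core.n else None
    return CorrectionResult(
        problem="approx-bad-subgraph-removal",
        objective=len(removed),
        optimal=len(removed) == 0,
        edits=script,
        witness=witness,
        max_degree=R.max_degree(),
    )


# ---------------------------------------------------------------------------
# Exact solvers
# ---------------------------------------------------------------------------

def _toggle(adj: list, i: int, j: int) -> None:
    adj[i] ^= 1 << j
    adj[j] ^= 1 << i


def min_edge_removal_exact(R: RelationGraph, S: SpeciesTree) -> CorrectionResult:
    """Minimum number of orthology edges whose removal makes R S-consistent.

    Branch and bound on bad subgraphs: a P4 is destroyed by removing one of
    its three edges, a contradictory 3-path by removing one of its two edges.
    """
    core = _Core(R, S)
    adj = list(core.adj)
    incumbent_adj = list(adj)
    best_script = tuple(sorted(_approx_removals(core, incumbent_adj)))
    best = [len(best_script), best_script]

    def dfs(removed: list) -> None:
        bad = core.find_bad(adj)
        if bad is None:
            script = tuple(sorted(removed))
            if len(script) < best[0] or (len(script) == best[0] and script < best[1]):
                best[0], best[1] = len(script), script
            return
        if len(removed) + 1 > best[0]:
            return
        kind, verts = bad
        if kind == "p4":
            a, b, c, d = verts
            cand = [(a, b), (b, c), (c, d)]
        else:
            x, z, y = verts
            cand = [(z, x), (z, y)]
        cand = sorted((min(u, v), max(u, v)) for u, v in cand)
        for u, v in cand:
            _toggle(adj, u, v)
            removed.append((u, v))
            dfs(removed)
            removed.pop()
            _toggle(adj, u, v)

    dfs([])
    cost, script = best
    final = list(core.adj)
    for u, v in script:
        _toggle(final, u, v)
    return CorrectionResult(
        problem="min-edge-removal",
        objective=cost,
        optimal=True,
        edits=EditScript(
            tuple(((core.genes[i], core.genes[j]), "delete") for i, j in script)
        ),
        witness=build_s_consistent_tree(core.graph(final), S),
        max_degree=R.max_degree(),
    )


def min_edit_exact(R: RelationGraph, S: SpeciesTree) -> CorrectionResult:
    """Minimum number of single-pair editings (deletions and insertions)
    making R S-consistent.

    Branch and bound: six editings per P4, three per contradictory 3-path;
    insertions between same-species genes are pruned (such pairs are always
    paralogs), and no pair is edited twice along a branch.
    """
    core = _Core(R, S)
    adj = list(core.adj)
    incumbent_adj = list(adj)
    approx = sorted(_approx_removals(core, incumbent_adj))
    best_script = tuple(((i, j), "delete") for i, j in approx)
    best = [len(best_script), tuple(sorted(best_script))]

    def dfs(edits: list, frozen: set) -> None:
        bad = core.find_bad(adj)
        if bad is None:
            script = tuple(sorted(edits))
            if len(script) < best[0] or (len(script) == best[0] and script < best[1]):
                best[0], best[1] = len(script), script
            return
        if len(edits) + 1 > best[0]:
            return
        kind, verts = bad
        cand = []
        for u, v in combinations(sorted(verts), 2):
            present = adj[u] >> v & 1
            if present:
                cand.append(((u, v), "delete"))
            else:
                if core.species[u] != core.species[v]:
                    cand.append(((u, v), "insert"))
        if kind == "p3":
            # only the three pairs within {x, z, y} are editable
            allowed = {
                (min(a, b), max(a, b)) for a, b in combinations(verts, 2)
            }
            cand = [c for c in cand if c[0] in allowed]
        cand.sort()
        for (u, v), op in cand:
            if (u, v) in frozen:
                continue
            _toggle(adj, u, v)
            edits.append(((u, v), op))
            frozen.add((u, v))
            dfs(edits, frozen)
            frozen.discard((u, v))
            edits.pop()
            _toggle(adj, u, v)

    dfs([], set())
    cost, script = best
    final = list(core.adj)
    for (u, v), _op in script:
        _toggle(final, u, v)
    return CorrectionResult(
        problem="min-edit",
        objective=cost,
        optimal=True,
        edits=EditScript(
            tuple(((core.genes[i], core.genes[j]), op) for (i, j), op in script)
        ),
        witness=build_s_consistent_tree(core.graph(final), S),
        max_degree=R.max_degree(),
    )


def max_node_consistency_exact(R: RelationGraph, S: SpeciesTree) -> CorrectionResult:
    """Largest gene subset whose induced relation graph is S-consistent.

    Branch and bound on bad subgraphs: one of a P4's four vertices, or one of
    a contradictory 3-path's three vertices, must be deleted.
    """
    core = _Core(R, S)
    n = core.n
    full = (1 << n) - 1

    # greedy incumbent: drop every vertex of each bad subgraph found
    active = full
    while True:
        bad = core.find_bad(core.adj, active)
        if bad is None:
            break
        for v in bad[1]:
            active &= ~(1 << v)
    best = [bin(active).count("1"), tuple(sorted(i for i in range(n) if not active >> i & 1))]

    def dfs(deleted: list, active_mask: int) -> None:
        bad = core.find_bad(core.adj, active_mask)
        if bad is None:
            retained = n - len(deleted)
            dels = tuple(sorted(deleted))
            if retained > best[0] or (retained == best[0] and dels < best[1]):
                best[0], best[1] = retained, dels
            return
        if len(deleted) + 1 > n - best[0]:
            return
        for v in sorted(bad[1]):
            deleted.append(v)
            dfs(deleted, active_mask & ~(1 << v))
            deleted.pop()

    dfs([], full)
    retained_idx = [i for i in range(n) if i not in set(best[1])]
    retained = tuple(core.genes[i] for i in retained_idx)
    sub = R.induced(retained)
    return CorrectionResult(
        problem="max-node-consistency",
        objective=best[0],
        optimal=True,
        retained=retained,
        witness=build_s_consistent_tree(sub, S) if retained else None,
        max_degree=R.max_degree(),
    )


# ---------------------------------------------------------------------------
# Gene tree correction
# ---------------------------------------------------------------------------

def max_homology_correction_exact(
    G: DSTree,
    S: SpeciesTree,
    C: Optional[ConstraintSet] = None,
    cap: int = 6,
) -> CorrectionResult:
    """S-consistent gene tree satisfying the constraints while preserving the
    most orthology/paralogy relations of G.

    The objective depends only on the relation set of the corrected tree, so
    the search enumerates every full relation graph extending the constraints
    (exhaustive; gene families beyond ``cap`` genes are rejected).
    """
    C = C if C is not None else ConstraintSet()
    genes = sorted(G.genes)
    n = len(genes)
    if n > cap:
        raise GraphError(
            f"exhaustive homology correction capped at {cap} genes (got {n})"
        )
    if not is_s_consistent_tree(G, S):
        raise TreeError("input gene tree must be S-consistent")
    _check_constraint_genes(C, set(genes))
    C.validate_species(G.species)

    target = relations_of(G)
    all_pairs = [pair(u, v) for u, v in combinations(genes, 2)]
    same_species = {
        p for p in all_pairs if G.species[p[0]] == G.species[p[1]]
    }
    forced_edge = set(C.O)
    forced_nonedge = set(C.P) | same_species
    free = [p for p in all_pairs if p not in forced_edge and p not in forced_nonedge]

    core_template = RelationGraph(genes, G.species)
    core = _Core(core_template, S)
    pair_bits = {p: (core.idx[p[0]], core.idx[p[1]]) for p in all_pairs}

    best = None  # (objective, edge tuple)
    for k in range(len(free) + 1):
        for chosen in combinations(free, k):
            edges = forced_edge | set(chosen)
            adj = [0] * n
            for p in edges:
                i, j = pair_bits[p]
                adj[i] |= 1 << j
                adj[j] |= 1 << i
            if core.find_bad(adj) is not None:
                continue
            objective = sum(
                1 for p in all_pairs if (p in edges) == (p in target.orthologs)
            )
            key = (objective, tuple(sorted(edges)))
            if best is None or objective > best[0] or (
                objective == best[0] and key[1] < best[1]
            ):
                best = key
    if best is None:
        return CorrectionResult(
            problem="max-homology-correction",
            objective=None,
            optimal=True,
            feasible=False,
        )
    objective, edges = best
    graph = RelationGraph(genes, G.species, edges)
    tree = build_s_consistent_tree(graph, S)
    return CorrectionResult(
        problem="max-homology-correction",
        objective=objective,
        optimal=True,
        tree=tree,
        witness=tree,
    )


def max_clade_correction_exact(
    G: DSTree,
    S: SpeciesTree,
    C: Optional[ConstraintSet] = None,
    cap: int = 6,
) -> CorrectionResult:
    """S-consistent gene tree satisfying the constraints while sharing the
    most clades with G.

    When S is binary the search ranges over rooted binary topologies only
    (binary refinement preserves relations and consistency and never removes
    a shared clade, so a binary optimum exists); otherwise every rooted
    multifurcating topology is enumerated. On each topology the event labels
    are forced: the lca of an orthology-constrained pair must be Spec, of a
    paralogy-constrained or same-species pair Dup; remaining nodes are Dup,
    which never violates consistency.
    """
    C = C if C is not None else ConstraintSet()
    genes = sorted(G.genes)
    n = len(genes)
    if n > cap:
        raise GraphError(
            f"exhaustive clade correction capped at {cap} genes (got {n})"
        )
    if not is_s_consistent_tree(G, S):
        raise TreeError("input gene tree must be S-consistent")
    _check_constraint_genes(C, set(genes))
    C.validate_species(G.species)

    same_species = {
        pair(u, v)
        for u, v in combinations(genes, 2)
        if G.species[u] == G.species[v]
    }
    g_clades = G.clades()
    topologies = (
        rooted_binary_topologies(genes) if S.is_binary else rooted_topologies(genes)
    )
    best = None  # (objective, DSTree)
    for topo in topologies:
        root = _topology_to_nodes(topo)
        leaf_map: dict[str, Node] = {}
        depth: dict[int, int] = {id(root): 0}
        order = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            if node.is_leaf:
                leaf_map[node.label] = node
            for c in node.children:
                depth[id(c)] = depth[id(node)] + 1
                stack.append(c)

        def lca_local(u: Node, v: Node) -> Node:
            du, dv = depth[id(u)], depth[id(v)]
            while du > dv:
                u = u.parent
                du -= 1
            while dv > du:
                v = v.parent
                dv -= 1
            while u is not v:
                u, v = u.parent, v.parent
            return u

        forced: dict[int, str] = {}
        ok = True
        for (u, v), ev in [(p, SPEC) for p in C.O] + [
            (p, DUP) for p in set(C.P) | same_species
        ]:
            a = lca_local(leaf_map[u], leaf_map[v])
            if forced.get(id(a), ev) != ev:
                ok = False
                break
            forced[id(a)] = ev
        if not ok:
            continue
        for node in order:
            if not node.is_leaf:
                node.event = forced.get(id(node), DUP)
        try:
            T = DSTree(root, dict(G.species))
        except TreeError:
            continue
        if not is_s_consistent_tree(T, S):
            continue
        objective = len(g_clades & T.clades())
        if best is None or objective > best[0]:
            best = (objective, T)
    if best is None:
        return CorrectionResult(
            problem="max-clade-correction",
            objective=None,
            optimal=True,
            feasible=False,
        )
    objective, tree = best
    return CorrectionResult(
        problem="max-clade-correction",
        objective=objective,
        optimal=True,
        tree=tree,
        witness=tree,
    )


def _check_constraint_genes(C: ConstraintSet, genes: set) -> None:
    for u, v in C.O | C.P:
        if u not in genes or v not in genes:
            raise GraphError(f"constraint on unknown gene ({u!r}, {v!r})")


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

def rooted_binary_topologies(leaves: Iterable[str]) -> list:
    """All rooted binary tree topologies on a leaf set, as nested pair
    tuples; (2n-3)!! of them for n leaves."""
    items = sorted(leaves)
    trees: list = [items[0]]
    for leaf in items[1:]:
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return trees


def _insertions(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for a2 in _insertions(a, x):
            yield (a2, b)
        for b2 in _insertions(b, x):
            yield (a, b2)


def rooted_topologies(leaves: Iterable[str]) -> list:
    """All rooted (possibly multifurcating) topologies on a leaf set, as
    nested tuples; every internal node has at least two children."""
    items = tuple(sorted(leaves))

    def build(subset: tuple):
        if len(subset) == 1:
            return [subset[0]]
        out = []
        for blocks in _set_partitions(subset):
            if len(blocks) < 2:
                continue
            choices = [build(tuple(b)) for b in blocks]
            for combo in _product(choices):
                out.append(tuple(combo))
        return out

    return build(items)


def _set_partitions(items: tuple):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _product(choices: list):
    if not choices:
        yield []
        return
    for head in choices[0]:
        for tail in _product(choices[1:]):
            yield [head] + tail


def _topology_to_nodes(topo) -> Node:
    if isinstance(topo, str):
        return Node(topo)
    root = Node()
    for part in topo:
        root.add(_topology_to_nodes(part))
    return root
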