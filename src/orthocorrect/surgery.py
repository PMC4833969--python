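"""Relation-preserving tree surgery.

Two constructive operations used throughout the correction machinery:

* :func:`refine_to_binary` — resolve every multifurcation of a consistent
  gene tree into binary nodes without changing a single orthology/paralogy
  relation and without breaking species-tree consistency. Duplication nodes
  are resolved by chaining; a speciation node is resolved by splitting its
  children according to which child of its mapped species node they descend
  from.

* :func:`graft_leaf` — insert one new gene into a consistent gene tree so
  that it becomes orthologous to a prescribed partner gene, while every
  pre-existing relation and the tree's consistency are preserved. The
  insertion point is chosen by a deterministic case analysis: connect above
  the root when the root maps strictly below the two species' lca; otherwise
  attach to an existing node if any attachment satisfies all conditions;
  otherwise subdivide the edge above the lowest ancestor of the partner that
  maps at or above the species lca (a speciation is inserted below a
  duplication there, a duplication below a speciation).
"""

from __future__ import annotations

from .trees import (
    DUP,
    SPEC,
    DSTree,
    Node,
    SpeciesTree,
    TreeError,
    copy_subtree,
    is_s_consistent_tree,
    lca_mapping,
    pair,
    preorder,
    relations_of,
)

__all__ = ["refine_to_binary", "graft_leaf"]


def refine_to_binary(G: DSTree, S: SpeciesTree) -> DSTree:
    """Binary refinement preserving relations and S-consistency.

    Requires S binary (the speciation split follows the bipartition of the
    mapped species node's children) and G S-consistent.
    """
    if not S.is_binary:
        raise TreeError("binary refinement requires a binary species tree")
    if not is_s_consistent_tree(G, S):
        raise TreeError("binary refinement requires an S-consistent gene tree")
    current = G.copy()
    while True:
        target = None
        for node in preorder(current.root):
            if not node.is_leaf and len(node.children) > 2:
                target = node
                break
        if target is None:
            return current
        if target.event == DUP:
            first, rest = target.children[0], target.children[1:]
            w = Node(event=DUP)
            for c in rest:
                w.add(c)
            target.children = [first, w]
            w.parent = target
        else:
            smap = lca_mapping(current, S)
            s1, s2 = smap[target].children
            v1 = [c for c in target.children if S.is_ancestor(s1, smap[c])]
            v2 = [c for c in target.children if S.is_ancestor(s2, smap[c])]
            assert len(v1) + len(v2) == len(target.children) and v1 and v2, (
                "children of a consistent speciation map strictly below its "
                "species node, into both sides"
            )
            new_children = []
            for group in (v1, v2):
                if len(group) == 1:
                    new_children.append(group[0])
                else:
                    w = Node(event=SPEC)
                    for c in group:
                        w.add(c)
                    new_children.append(w)
            target.children = new_children
            for c in new_children:
                c.parent = target
        current = DSTree(current.root, current.species)


def _graft_conditions_hold(G: DSTree, candidate: DSTree, S: SpeciesTree,
                           x: str, y: str) -> bool:
    old = relations_of(G)
    new = relations_of(candidate)
    return (
        pair(x, y) in new.orthologs
        and old.orthologs <= new.orthologs
        and old.paralogs <= new.paralogs
        and bool(is_s_consistent_tree(candidate, S))
    )


def graft_leaf(G: DSTree, S: SpeciesTree, x: str, y: str, species_of_x: str,
               binarize: bool = False) -> DSTree:
    """Graft gene ``x`` (of species ``species_of_x``) into G so that x and y
    become orthologs, all prior relations persist, and the result remains
    S-consistent. With ``binarize=True`` the result is refined to binary
    afterwards (requires S binary)."""
    if x in G.genes:
        raise TreeError(f"gene {x!r} already present")
    if y not in G.genes:
        raise TreeError(f"gene {y!r} not in the tree")
    if species_of_x == G.species[y]:
        raise TreeError("x and y from the same species can never be orthologs")
    if species_of_x not in S.leaf_labels:
        raise TreeError(f"species {species_of_x!r} not in the species tree")
    if not is_s_consistent_tree(G, S):
        raise TreeError("grafting requires an S-consistent gene tree")

    new_species = dict(G.species)
    new_species[x] = species_of_x
    smap = lca_mapping(G, S)
    s_xy = S.lca2(S.leaf(species_of_x), S.leaf(G.species[y]))
    root_map = smap[G.root]

    # Case 1: the whole tree maps strictly below lca_S(s(x), s(y)):
    # connect x above the root under a new speciation.
    if root_map is not s_xy and S.is_ancestor(s_xy, root_map):
        new_root = Node(event=SPEC)
        new_root.add(copy_subtree(G.root))
        new_root.add(Node(x))
        result = DSTree(new_root, new_species)
        assert _graft_conditions_hold(G, result, S, x, y)
        return _maybe_binarize(result, S, binarize)

    # Case 2: adding x as a new child of an existing node, first node (in
    # preorder) for which all three conditions hold.
    order = list(preorder(G.root))
    for i, node in enumerate(order):
        if node.is_leaf:
            continue
        root_copy = copy_subtree(G.root)
        target = list(preorder(root_copy))[i]
        target.add(Node(x))
        try:
            candidate = DSTree(root_copy, new_species)
        except TreeError:
            continue
        if _graft_conditions_hold(G, candidate, S, x, y):
            return _maybe_binarize(candidate, S, binarize)

    # Case 3: subdivide the edge above g' where g is the lowest ancestor of y
    # mapping at or above lca_S(s(x), s(y)).
    g = G.leaf(y)
    while not (smap[g] is s_xy or S.is_ancestor(smap[g], s_xy)):
        g = g.parent
    if g.is_leaf:
        raise TreeError("no valid grafting point (degenerate single-leaf case)")
    order = list(preorder(G.root))
    g_index = order.index(g)
    root_copy = copy_subtree(G.root)
    g_copy = list(preorder(root_copy))[g_index]
    if g_copy.event == DUP:
        # child of g on the path to y; insert a speciation above it
        gp = G.leaf(y)
        while gp.parent is not g:
            gp = gp.parent
        gp_copy = list(preorder(root_copy))[order.index(gp)]
        p = Node(event=SPEC)
    else:
        # unique child of g whose mapping is an ancestor of s(x); insert a
        # duplication above it
        sx_leaf = S.leaf(species_of_x)
        cands = [c for c in g.children if S.is_ancestor(smap[c], sx_leaf)]
        if len(cands) != 1:
            raise TreeError("no valid grafting point found")
        gp = cands[0]
        gp_copy = list(preorder(root_copy))[order.index(gp)]
        p = Node(event=DUP)
    parent = gp_copy.parent
    parent.children[parent.children.index(gp_copy)] = p
    p.parent = parent
    p.add(gp_copy)
    p.add(Node(x))
    result = DSTree(root_copy, new_species)
    assert _graft_conditions_hold(G, result, S, x, y)
    return _maybe_binarize(result, S, binarize)


def _maybe_binarize(G: DSTree, S: SpeciesTree, binarize: bool) -> DSTree:
    return refine_to_binary(G, S) if binarize else G
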