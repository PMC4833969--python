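"""Synthetic ground truth: duplication histories along a species tree, and
noisy relation graphs derived from them.

``simulate_history`` draws a gene family top-down along the species tree: at
each step a lineage either duplicates (both copies stay in the same species
subtree, the node is labeled Dup) or follows the species bifurcation (one
copy per child species, labeled Spec). Losses are not modeled — the relation
formalism never represents them — but an optional leaf-dropout probability
can prune extant genes after the fact. Every simulated history is
S-consistent by construction, so derived relation graphs are consistent
ground truth and any correction solver must return cost zero on them.

``perturb_relations`` then flips each eligible gene pair (distinct species)
independently with a configured probability, producing realistic noisy
inputs for the correction problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .relations import RelationGraph
from .trees import DSTree, DUP, Node, SPEC, SpeciesTree, TreeError, pair

__all__ = ["SimConfig", "simulate_history", "perturb_relations", "random_species_tree"]

logger = logging.getLogger(__name__)

_MAX_GENES = 100_000


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    duplication_probability is the per-lineage, per-step chance of a
    duplication before the next speciation; relation_flip_probability the
    independent per-pair toggle rate when perturbing a relation graph;
    leaf_dropout_probability optionally prunes extant genes (losses are not
    modeled as events). The seed is mandatory: every draw flows from it.
    """

    seed: int
    species_count: int = 6
    duplication_probability: float = 0.2
    relation_flip_probability: float = 0.05
    leaf_dropout_probability: float = 0.0

    def __post_init__(self):
        for name in (
            "duplication_probability",
            "relation_flip_probability",
            "leaf_dropout_probability",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.species_count < 1:
            raise ValueError("species_count must be positive")


def random_species_tree(labels, rng: np.random.Generator) -> SpeciesTree:
    """Uniform-ish random rooted binary species tree built by inserting each
    species at a randomly chosen edge (including above the root)."""
    if isinstance(labels, int):
        labels = [f"s{i}" for i in range(1, labels + 1)]
    labels = list(labels)
    if not labels:
        raise TreeError("need at least one species")
    root = Node(labels[0])
    for lab in labels[1:]:
        nodes = _all_nodes(root)
        at = nodes[int(rng.integers(len(nodes)))]
        new = Node()
        parent = at.parent
        new.add(at)
        new.add(Node(lab))
        if parent is None:
            root = new
        else:
            parent.children[parent.children.index(at)] = new
            new.parent = parent
    return SpeciesTree(root)


def _all_nodes(root: Node) -> list:
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def simulate_history(S: SpeciesTree, cfg: SimConfig) -> DSTree:
    """Draw an S-consistent gene family history along S.

    Each gene lineage sitting at a species-tree node either duplicates (with
    ``duplication_probability``; both copies continue at the same species
    node under a Dup label) or, at an internal species node, speciates into
    one lineage per child (Spec label); at a species leaf it becomes an
    extant gene. The result always passes the speciation-separation check
    against S.
    """
    rng = np.random.default_rng(cfg.seed)
    counters: dict[str, int] = {}
    species_map: dict[str, str] = {}
    n_nodes = 0

    root = Node()
    # stack of (gene-tree node to fill, species node it sits at)
    stack = [(root, S.root)]
    while stack:
        node, snode = stack.pop()
        n_nodes += 1
        if n_nodes > _MAX_GENES:
            raise RuntimeError(
                "simulated family exceeded the size guard; lower "
                "duplication_probability"
            )
        if rng.random() < cfg.duplication_probability:
            node.event = DUP
            for _ in range(2):
                stack.append((node.add(Node()), snode))
        elif snode.is_leaf:
            sp = snode.label
            counters[sp] = counters.get(sp, 0) + 1
            node.label = f"{sp}_{counters[sp]}"
            species_map[node.label] = sp
        else:
            node.event = SPEC
            for schild in snode.children:
                stack.append((node.add(Node()), schild))
    tree = DSTree(root, species_map)
    if cfg.leaf_dropout_probability > 0.0:
        labels = sorted(tree.genes)
        survivors = [
            g for g in labels if rng.random() >= cfg.leaf_dropout_probability
        ]
        if not survivors:
            survivors = labels[:1]
        if len(survivors) < len(labels):
            tree = tree.restrict(survivors)
    return tree


def perturb_relations(R: RelationGraph, cfg: SimConfig):
    """Toggle each distinct-species gene pair independently with
    ``relation_flip_probability`` (same-species pairs are never made edges).
    Returns the perturbed graph and the list of toggled pairs."""
    rng = np.random.default_rng(cfg.seed)
    out = R.copy()
    toggles = []
    for u, v in combinations(out.genes, 2):
        if out.species[u] == out.species[v]:
            continue
        if rng.random() < cfg.relation_flip_probability:
            if out.has_edge(u, v):
                out.remove_edge(u, v)
            else:
                out.add_edge(u, v)
            toggles.append(pair(u, v))
    if toggles:
        logger.debug("perturbed %d gene pairs: %s", len(toggles), toggles)
    return out, toggles
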