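"""File formats: Newick trees, gene maps, relation edge lists, constraints.

All formats are plain text. Gene maps are TSV with a ``gene<TAB>species``
header; relation graphs are TSV edge lists (one orthology edge per line,
isolated genes appear in the gene map only); constraint files are TSV with a
trailing ``O``/``P`` column; solver results serialize to JSON.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Union

from .relations import ConstraintSet, GraphError, RelationGraph
from .trees import DSTree, SpeciesTree, TreeError, parse_newick

__all__ = [
    "read_species_tree",
    "write_species_tree",
    "read_gene_map",
    "write_gene_map",
    "read_ds_tree",
    "write_ds_tree",
    "read_relation_graph",
    "write_relation_graph",
    "read_constraints",
    "write_constraints",
    "write_result_json",
]

PathLike = Union[str, os.PathLike]


def read_species_tree(path: PathLike) -> SpeciesTree:
    with open(path) as fh:
        return parse_newick(fh.read(), kind="species")


def write_species_tree(S: SpeciesTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(S.newick() + "\n")


def read_gene_map(path: PathLike) -> dict:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["gene", "species"]:
            raise TreeError(
                f"gene map {path} must start with a 'gene<TAB>species' header"
            )
        out = {}
        for row in reader:
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise TreeError(f"malformed gene-map row: {row!r}")
            gene, species = row[0].strip(), row[1].strip()
            if gene in out:
                raise TreeError(f"duplicate gene {gene!r} in gene map")
            out[gene] = species
    return out


def write_gene_map(mapping: dict, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "species"])
        for gene in sorted(mapping):
            writer.writerow([gene, mapping[gene]])


def read_ds_tree(newick_path: PathLike, gene_map_path: PathLike) -> DSTree:
    species_map = read_gene_map(gene_map_path)
    with open(newick_path) as fh:
        return parse_newick(fh.read(), kind="ds", species_map=species_map)


def write_ds_tree(G: DSTree, newick_path: PathLike, gene_map_path: PathLike) -> None:
    with open(newick_path, "w") as fh:
        fh.write(G.newick() + "\n")
    write_gene_map(G.species, gene_map_path)


def read_relation_graph(edges_path: PathLike, gene_map_path: PathLike) -> RelationGraph:
    species = read_gene_map(gene_map_path)
    edges = []
    with open(edges_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise GraphError(f"malformed relation row: {row!r}")
            edges.append((row[0].strip(), row[1].strip()))
    return RelationGraph(species.keys(), species, edges)


def write_relation_graph(R: RelationGraph, edges_path: PathLike,
                         gene_map_path: PathLike) -> None:
    with open(edges_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for u, v in R.edges():
            writer.writerow([u, v])
    write_gene_map(R.species, gene_map_path)


def read_constraints(path: PathLike) -> ConstraintSet:
    O, P = [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            if len(row) < 3 or row[2].strip() not in ("O", "P"):
                raise GraphError(
                    f"constraint rows are 'gene1<TAB>gene2<TAB>O|P', got {row!r}"
                )
            (O if row[2].strip() == "O" else P).append(
                (row[0].strip(), row[1].strip())
            )
    return ConstraintSet(O=O, P=P)


def write_constraints(C: ConstraintSet, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for u, v in sorted(C.O):
            writer.writerow([u, v, "O"])
        for u, v in sorted(C.P):
            writer.writerow([u, v, "P"])


def write_result_json(result, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
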