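"""Trait origin nodes and the order of trait emergence.

Each trait is assumed to have arisen once, with any number of subsequent
irreversible losses (a Dollo-style reading appropriate for complex,
multi-gene traits). Under that assumption the origin of a trait is the most
recent common ancestor of all species bearing it: the shallowest node that
can explain every presence with a single gain.

Comparing two origin nodes on the rooted species tree yields one of four
relations: the same node (simultaneous at the resolution of the taxon
sample), one node ancestral to the other (that trait emerged earlier), or
two non-nested nodes (independent origins on disjoint lineages).
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from .traits import TraitMatrix
from .tree import RootedTree


class AbsentTraitError(ValueError):
    """Raised when a trait has no presence among the tree's leaves."""


class Relation(enum.Enum):
    """Order relation between two trait origin nodes."""

    FIRST_EARLIER = "first_earlier"
    SECOND_EARLIER = "second_earlier"
    SIMULTANEOUS = "simultaneous"
    NON_NESTED = "non_nested"

    def mirrored(self) -> "Relation":
        if self is Relation.FIRST_EARLIER:
            return Relation.SECOND_EARLIER
        if self is Relation.SECOND_EARLIER:
            return Relation.FIRST_EARLIER
        return self


def assign_origin(tree: RootedTree, matrix: TraitMatrix, trait: str) -> str:
    """Origin node of a trait: the MRCA of all its bearers on the tree.

    Bearers outside the tree's leaf set (e.g. when scoring a gene tree that
    spans only part of the taxon sample) are ignored. A trait present in
    every leaf maps to the root.
    """
    bearers = matrix.presence_set(trait) & tree.leaf_labels
    if not bearers:
        raise AbsentTraitError(
            f"trait {trait!r} is present in no leaf of the tree"
        )
    return tree.mrca(bearers)


def compare_pair(tree: RootedTree, origin_a: str, origin_b: str) -> Relation:
    """Relation between two origin nodes on the same rooted tree."""
    if origin_a == origin_b:
        return Relation.SIMULTANEOUS
    if tree.is_ancestor(origin_a, origin_b):
        return Relation.FIRST_EARLIER
    if tree.is_ancestor(origin_b, origin_a):
        return Relation.SECOND_EARLIER
    return Relation.NON_NESTED


@dataclass
class OrderReport:
    """Origin map, emergence blocks and all pairwise order relations.

    ``blocks`` lists (origin node id, traits sharing it) from the root
    toward the tips; traits inside a block are in input-column order, which
    is arbitrary. When ``non_nested`` is empty the blocks form a total
    order of emergence.
    """

    origins: dict[str, str]
    blocks: list[tuple[str, list[str]]]
    relations: dict[tuple[str, str], Relation]
    non_nested: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.relations)

    def relation(self, trait_a: str, trait_b: str) -> Relation:
        if (trait_a, trait_b) in self.relations:
            return self.relations[(trait_a, trait_b)]
        return self.relations[(trait_b, trait_a)].mirrored()

    def block_index(self, trait: str) -> int:
        for i, (_, traits) in enumerate(self.blocks):
            if trait in traits:
                return i
        raise KeyError(trait)

    def pair_matrix(self) -> pd.DataFrame:
        """Square trait-by-trait matrix of relation values (strings)."""
        traits = [t for _, ts in self.blocks for t in ts]
        mat = pd.DataFrame("", index=traits, columns=traits, dtype=object)
        for t in traits:
            mat.at[t, t] = Relation.SIMULTANEOUS.value
        for (a, b), rel in self.relations.items():
            mat.at[a, b] = rel.value
            mat.at[b, a] = rel.mirrored().value
        return mat

    def to_dict(self) -> dict:
        return {
            "origins": dict(self.origins),
            "blocks": [
                {"origin": node, "traits": list(traits)}
                for node, traits in self.blocks
            ],
            "relations": [
                {"first": a, "second": b, "relation": rel.value}
                for (a, b), rel in self.relations.items()
            ],
            "non_nested": [list(p) for p in self.non_nested],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")

    def write_csv(self, path: str | Path) -> None:
        self.pair_matrix().to_csv(path)


def build_order(
    tree: RootedTree,
    matrix: TraitMatrix,
    skip_absent: bool = False,
) -> OrderReport:
    """Assign origins to all traits and derive the order of emergence.

    Traits sharing an origin node form one block; blocks are sorted
    root-most first (by node depth, ties broken by node id for
    determinism). All C(k, 2) pair relations are recorded; non-nested
    pairs are additionally surfaced in their own list rather than
    aborting the report.

    Traits with no presence raise :class:`AbsentTraitError` unless
    ``skip_absent`` is set, in which case they are dropped from the report.
    """
    origins: dict[str, str] = {}
    for trait in matrix.traits:
        try:
            origins[trait] = assign_origin(tree, matrix, trait)
        except AbsentTraitError:
            if not skip_absent:
                raise
    by_node: dict[str, list[str]] = {}
    for trait in matrix.traits:
        if trait in origins:
            by_node.setdefault(origins[trait], []).append(trait)
    blocks = sorted(
        by_node.items(), key=lambda kv: (tree.depth(kv[0]), kv[0])
    )
    relations: dict[tuple[str, str], Relation] = {}
    non_nested: list[tuple[str, str]] = []
    kept = [t for t in matrix.traits if t in origins]
    for a, b in itertools.combinations(kept, 2):
        rel = compare_pair(tree, origins[a], origins[b])
        relations[(a, b)] = rel
        if rel is Relation.NON_NESTED:
            non_nested.append((a, b))
    return OrderReport(
        origins=origins,
        blocks=[(node, traits) for node, traits in blocks],
        relations=relations,
        non_nested=non_nested,
    )
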