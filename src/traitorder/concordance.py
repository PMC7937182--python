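"""Gene-tree concordance with the species-tree order of trait emergence.

A species tree built from a handful of core genes carries limited signal;
repeating the pairwise trait-order analysis across many rooted single-copy
gene trees provides a statistical check. A gene tree votes on a trait pair
only when it is evaluable for that pair — at least two of its leaves bear
each trait — and agrees when the MRCA-based origin relation computed inside
the gene tree equals the relation seen on the species tree.

In strict mode (default) agreement means exact relation equality, so a
non-nested gene-tree relation counts against a nested species-tree one. In
lenient mode non-nested gene-tree relations are dropped from the
denominator instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .order import OrderReport, Relation, compare_pair
from .traits import TraitMatrix
from .tree import RootedTree


class ConcordanceError(ValueError):
    pass


def pair_evaluable(
    gene_tree: RootedTree,
    matrix: TraitMatrix,
    trait_a: str,
    trait_b: str,
) -> bool:
    """At least two leaves of the gene tree bear each of the two traits."""
    leaves = gene_tree.leaf_labels
    return (
        len(matrix.presence_set(trait_a) & leaves) >= 2
        and len(matrix.presence_set(trait_b) & leaves) >= 2
    )


def gene_pair_relation(
    gene_tree: RootedTree,
    matrix: TraitMatrix,
    trait_a: str,
    trait_b: str,
) -> Relation:
    """Origin-order relation of a trait pair inside a rooted gene tree.

    Origins are assigned by the same single-origin MRCA rule, restricted to
    the gene tree's leaves. Raises :class:`ConcordanceError` when the pair
    is not evaluable on this tree.
    """
    if not pair_evaluable(gene_tree, matrix, trait_a, trait_b):
        raise ConcordanceError(
            f"pair ({trait_a!r}, {trait_b!r}) not evaluable on this gene tree"
        )
    oa = gene_tree.mrca(matrix.presence_set(trait_a) & gene_tree.leaf_labels)
    ob = gene_tree.mrca(matrix.presence_set(trait_b) & gene_tree.leaf_labels)
    return compare_pair(gene_tree, oa, ob)


@dataclass
class ConcordanceMatrix:
    """Per-pair agreement of gene trees with the species-tree order.

    ``table`` has one row per trait pair: the species-tree relation, the
    number of evaluable gene trees, the number agreeing, and the agreement
    proportion (NaN when no gene tree is evaluable).
    """

    table: pd.DataFrame
    mode: str
    n_gene_trees: int

    @property
    def mean_proportion(self) -> float:
        return float(self.table["proportion"].mean())

    def proportion(self, trait_a: str, trait_b: str) -> float:
        key = (trait_a, trait_b)
        idx = self.table.index
        if key not in idx:
            key = (trait_b, trait_a)
        return float(self.table.loc[key, "proportion"])

    def square_matrix(self) -> pd.DataFrame:
        """Trait x trait matrix: upper triangle = proportion, lower = n_evaluable."""
        traits: list[str] = []
        for a, b in self.table.index:
            for t in (a, b):
                if t not in traits:
                    traits.append(t)
        mat = pd.DataFrame(float("nan"), index=traits, columns=traits)
        for (a, b), row in self.table.iterrows():
            i, j = traits.index(a), traits.index(b)
            if i < j:
                mat.iat[i, j] = row["proportion"]
                mat.iat[j, i] = row["n_evaluable"]
            else:
                mat.iat[j, i] = row["proportion"]
                mat.iat[i, j] = row["n_evaluable"]
        return mat

    def to_dict(self) -> dict:
        rows = []
        for (a, b), row in self.table.iterrows():
            prop = row["proportion"]
            rows.append({
                "first": a,
                "second": b,
                "species_relation": row["species_relation"],
                "n_evaluable": int(row["n_evaluable"]),
                "n_agree": int(row["n_agree"]),
                "proportion": None if pd.isna(prop) else float(prop),
            })
        return {"mode": self.mode, "n_gene_trees": self.n_gene_trees,
                "pairs": rows}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")

    def write_csv(self, path: str | Path) -> None:
        """Long-format CSV, one row per trait pair."""
        out = self.table.copy()
        out.index = pd.MultiIndex.from_tuples(out.index,
                                              names=["first", "second"])
        out.to_csv(path)


def concordance(
    gene_trees: Mapping[str, RootedTree] | Sequence[RootedTree],
    matrix: TraitMatrix,
    species_order: OrderReport,
    exclude_taxa: Iterable[str] = (),
    mode: str = "strict",
    prune_unknown: bool = False,
) -> ConcordanceMatrix:
    """Score every species-tree trait pair against a set of rooted gene trees.

    ``exclude_taxa`` are pruned from every gene tree before evaluation (the
    taxon-exclusion sensitivity rerun); evaluability is re-checked after
    pruning. Gene trees whose leaves are not all in the matrix raise unless
    ``prune_unknown`` is set, in which case unknown leaves are pruned.

    A gene tree left with fewer than two leaves after pruning is skipped
    entirely (it can evaluate no pair).
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"unknown mode: {mode!r}")
    if isinstance(gene_trees, Mapping):
        tree_list = list(gene_trees.values())
    else:
        tree_list = list(gene_trees)
    excl = frozenset(exclude_taxa)
    known = frozenset(matrix.species)

    prepared: list[RootedTree] = []
    for gt in tree_list:
        unknown = gt.leaf_labels - known
        if unknown and not prune_unknown:
            raise ConcordanceError(
                "gene tree leaves absent from the trait matrix: "
                f"{sorted(unknown)[:5]}; pass prune_unknown=True to drop them"
            )
        keep = gt.leaf_labels - excl - unknown
        if len(keep) < 2:
            continue
        prepared.append(gt if keep == gt.leaf_labels else gt.prune_to(keep))

    traits = sorted({t for pair in species_order.relations for t in pair})
    # Cache per-tree, per-trait bearer sets and origins.
    bearers = {t: matrix.presence_set(t) for t in traits}
    rows = {}
    pair_items = list(species_order.relations.items())
    per_tree_origin: list[dict[str, str]] = []
    per_tree_bearing: list[dict[str, int]] = []
    for gt in prepared:
        counts = {t: len(bearers[t] & gt.leaf_labels) for t in traits}
        per_tree_bearing.append(counts)
        per_tree_origin.append({})
    for (a, b), species_rel in pair_items:
        n_eval = 0
        n_agree = 0
        for gi, gt in enumerate(prepared):
            counts = per_tree_bearing[gi]
            if counts.get(a, 0) < 2 or counts.get(b, 0) < 2:
                continue
            origins = per_tree_origin[gi]
            for t in (a, b):
                if t not in origins:
                    origins[t] = gt.mrca(bearers[t] & gt.leaf_labels)
            rel = compare_pair(gt, origins[a], origins[b])
            if mode == "lenient" and rel is Relation.NON_NESTED \
                    and species_rel is not Relation.NON_NESTED:
                continue
            n_eval += 1
            if rel is species_rel:
                n_agree += 1
        rows[(a, b)] = {
            "species_relation": species_rel.value,
            "n_evaluable": n_eval,
            "n_agree": n_agree,
            "proportion": (n_agree / n_eval) if n_eval else float("nan"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ConcordanceMatrix(table=table, mode=mode,
                             n_gene_trees=len(tree_list))
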