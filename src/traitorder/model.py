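"""Model/results facade over the trait-order pipeline.

:class:`TraitOrderModel` bundles a rooted species tree, a binary trait
matrix and (optionally) rooted gene trees and a group map; ``fit()`` runs
the single-origin mapping, the emergence-order derivation, the CI/RI
parsimony indices and — when gene trees are supplied — the per-pair
concordance and the root-support census. The returned
:class:`TraitOrderResults` carries the estimates and renders a text
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .concordance import ConcordanceMatrix, concordance as _run_concordance
from .order import OrderReport, build_order as _build_order
from .parsimony import ParsimonyIndices, indices as _run_indices
from .rootcensus import CensusResult, GroupMap, census as _run_census
from .traits import TraitMatrix, read_trait_matrix, reconcile
from .tree import (
    RootedTree,
    read_gene_trees,
    read_newick_file,
    root_and_strip_outgroup,
)


class TraitOrderModel:
    """Single-origin (Dollo-style) trait emergence on a rooted species tree.

    Parameters
    ----------
    tree
        Rooted species tree over the ingroup species.
    matrix
        Binary trait matrix; species must match the tree's leaves (pass
        ``prune=True`` to restrict both to their intersection).
    gene_trees
        Optional mapping of id -> gene tree. Trees still carrying outgroup
        leaves are rooted and stripped at fit time when ``group_map`` (with
        its outgroup list) is given; otherwise they must already be rooted
        ingroup trees.
    group_map
        Optional species -> group assignment plus outgroup labels; enables
        the root-support census and outgroup-based gene-tree rooting.
    """

    def __init__(
        self,
        tree: RootedTree,
        matrix: TraitMatrix,
        gene_trees: Optional[Mapping[str, RootedTree]] = None,
        group_map: Optional[GroupMap] = None,
        prune: bool = False,
    ):
        self.matrix, self.tree, self.reconcile_report = reconcile(
            matrix, tree, prune=prune
        )
        self.gene_trees = dict(gene_trees) if gene_trees else None
        self.group_map = group_map

    @classmethod
    def from_files(
        cls,
        species_tree: str | Path,
        trait_matrix: str | Path,
        gene_trees: Optional[str | Path] = None,
        group_map: Optional[str | Path] = None,
        outgroup: Optional[str | Path] = None,
        prune: bool = False,
        sep: str = "\t",
    ) -> "TraitOrderModel":
        tree = read_newick_file(species_tree)[0]
        matrix = read_trait_matrix(trait_matrix, sep=sep)
        gts = read_gene_trees(gene_trees) if gene_trees else None
        gm = None
        if group_map is not None:
            if outgroup is None:
                raise ValueError("group_map requires an outgroup file")
            gm = GroupMap.from_files(group_map, outgroup)
        return cls(tree, matrix, gene_trees=gts, group_map=gm, prune=prune)

    def fit(
        self,
        concordance_mode: str = "strict",
        exclude_taxa: Iterable[str] = (),
        min_per_group: int = 2,
        skip_absent: bool = False,
        metadata: Optional[Mapping[str, float]] = None,
    ) -> "TraitOrderResults":
        """Run the full inference; see :class:`TraitOrderResults`."""
        order = _build_order(self.tree, self.matrix,
                                   skip_absent=skip_absent)
        indices = _run_indices(self.tree, self.matrix)
        conc = None
        census_result = None
        n_unrootable = 0
        if self.gene_trees is not None:
            if self.group_map is not None:
                census_result = _run_census(
                    self.gene_trees, self.group_map,
                    min_per_group=min_per_group, metadata=metadata,
                )
                ingroup_trees, discarded = root_and_strip_outgroup(
                    self.gene_trees, self.group_map.outgroup
                )
                n_unrootable = len(discarded)
            else:
                ingroup_trees = self.gene_trees
            conc = _run_concordance(
                ingroup_trees, self.matrix, order,
                exclude_taxa=exclude_taxa, mode=concordance_mode,
                prune_unknown=True,
            )
        return TraitOrderResults(
            model=self,
            order=order,
            indices=indices,
            concordance=conc,
            census=census_result,
            n_unrootable_gene_trees=n_unrootable,
        )


@dataclass
class TraitOrderResults:
    """Fitted trait-order estimates and diagnostics.

    Attributes
    ----------
    order
        :class:`~traitorder.order.OrderReport`: origin node per trait,
        emergence blocks root-to-tip, all pairwise relations.
    indices
        :class:`~traitorder.parsimony.ParsimonyIndices`: per-trait
        (m, s, g, CI, RI) and medians.
    concordance
        :class:`~traitorder.concordance.ConcordanceMatrix` or None.
    census
        :class:`~traitorder.rootcensus.CensusResult` or None.
    """

    model: TraitOrderModel
    order: OrderReport
    indices: ParsimonyIndices
    concordance: Optional[ConcordanceMatrix] = None
    census: Optional[CensusResult] = None
    n_unrootable_gene_trees: int = 0

    @property
    def origins(self) -> pd.Series:
        return pd.Series(self.order.origins, name="origin_node")

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        lines = []
        lines.append("Trait emergence order (single-origin mapping)")
        lines.append("=" * 54)
        lines.append(f"Species:            {m.matrix.n_species}")
        lines.append(f"Traits:             {m.matrix.n_traits}")
        lines.append(f"Trait pairs:        {self.order.n_pairs}")
        lines.append(f"Non-nested pairs:   {len(self.order.non_nested)}")
        lines.append("")
        lines.append("Emergence blocks (root -> tips; intra-block order arbitrary):")
        for i, (node, traits) in enumerate(self.order.blocks, start=1):
            lines.append(f"  {i:2d}. @{node}: {', '.join(traits)}")
        lines.append("")
        lines.append(
            f"Homoplasy: median CI = {self.indices.median_ci:.3f}, "
            f"median RI = {self.indices.median_ri:.3f}"
        )
        if self.indices.ci_undefined or self.indices.ri_undefined:
            lines.append(
                f"  undefined: CI for {self.indices.ci_undefined or 'none'}, "
                f"RI for {self.indices.ri_undefined or 'none'}"
            )
        if self.concordance is not None:
            defined = self.concordance.table["proportion"].dropna()
            lines.append("")
            lines.append(
                f"Gene-tree concordance ({self.concordance.mode} mode, "
                f"{self.concordance.n_gene_trees} trees"
                + (f", {self.n_unrootable_gene_trees} unrootable dropped"
                   if self.n_unrootable_gene_trees else "")
                + "):"
            )
            if len(defined):
                lines.append(
                    f"  mean agreement {defined.mean():.3f}, "
                    f"min {defined.min():.3f}, max {defined.max():.3f} "
                    f"over {len(defined)} evaluable pairs"
                )
            else:
                lines.append("  no evaluable pairs")
        if self.census is not None:
            lines.append("")
            lines.append("Root-support census:")
            for label, n in sorted(self.census.tally.items()):
                lines.append(f"  {label}: {n}")
        return "\n".join(lines)
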