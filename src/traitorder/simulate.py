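"""Synthetic species trees, traits and gene trees with known ground truth.

The generator emulates the shape of a phylogenomic trait-order study: a
rooted species tree; binary traits that each arise once at a known origin
node along a root-to-tip backbone and are then lost independently on edges
below it (optionally with a single extra lateral gain to create controlled
homoplasy); and gene trees that are taxon-subsampled, NNI-perturbed copies
of the species tree with an outgroup clade attached so that rooting
machinery is exercised end to end.

Default parameters mirror the scale of a large cyanobacterial survey:
199 ingroup species in three named groups, 21 traits, 553 gene trees and a
six-taxon outgroup. One master seed drives per-component substreams, so
identical configurations reproduce byte-identical outputs and changing the
number of gene trees does not alter the trait matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .order import Relation, compare_pair
from .rootcensus import GroupMap
from .traits import TraitMatrix
from .tree import RootedTree

_TREE_STREAM, _TRAIT_STREAM, _GENE_STREAM = 0, 1, 2


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    loss_prob is the per-edge probability of an irreversible 1->0 loss below
    a trait's origin; retention_prob is the per-leaf probability that a gene
    tree samples a given ingroup species; n_nni counts random
    nearest-neighbor-interchange moves applied to each gene tree; lgt_prob
    is the per-trait probability of one extra gain on a clade disjoint from
    the origin (lateral transfer of the trait).
    """

    n_species: int = 199
    n_traits: int = 21
    n_gene_trees: int = 553
    n_outgroup: int = 6
    loss_prob: float = 0.05
    retention_prob: float = 0.9
    n_nni: int = 1
    lgt_prob: float = 0.0
    missing_prob: float = 0.0
    origin_nodes: Optional[tuple[str, ...]] = None
    distinct_origins: bool = False
    min_group_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise SimulationError("n_species must be >= 4")
        if self.n_traits < 1:
            raise SimulationError("n_traits must be >= 1")
        for name in ("loss_prob", "lgt_prob", "missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.retention_prob <= 1.0:
            raise SimulationError("retention_prob must be in (0, 1]")
        if self.n_nni < 0 or self.n_gene_trees < 0 or self.n_outgroup < 1:
            raise SimulationError("counts must be non-negative (outgroup >= 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["origin_nodes"] is not None:
            d["origin_nodes"] = list(d["origin_nodes"])
        return d


def _substream(seed: int, index: int) -> random.Random:
    ss = np.random.SeedSequence(seed, spawn_key=(index,))
    return random.Random(int(ss.generate_state(1)[0]) & 0x7FFFFFFF)


def simulate_species_tree(n_species: int, seed: int,
                          birth_rate: float = 1.0) -> RootedTree:
    """Yule (pure-birth) rooted binary tree with leaves S001..Sn."""
    if n_species < 2:
        raise SimulationError("n_species must be >= 2")
    from dendropy.simulate import treesim

    rng = _substream(seed, _TREE_STREAM)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=rng,
    )
    width = max(3, len(str(n_species)))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1:0{width}d}"
    return RootedTree(dtree)


@dataclass
class GroundTruth:
    """The generative truth behind a synthetic trait matrix."""

    origins: dict[str, str]
    loss_edges: dict[str, list[str]]  # trait -> child ends of loss edges
    lgt_nodes: dict[str, Optional[str]]
    resample_counts: dict[str, int]

    def blocks(self, tree: RootedTree) -> list[tuple[str, list[str]]]:
        """True emergence blocks, root-most first (ties by node id)."""
        by_node: dict[str, list[str]] = {}
        for trait, node in self.origins.items():
            by_node.setdefault(node, []).append(trait)
        return sorted(by_node.items(),
                      key=lambda kv: (tree.depth(kv[0]), kv[0]))

    def relations(self, tree: RootedTree) -> dict[tuple[str, str], Relation]:
        """True pairwise relations between origin nodes."""
        traits = list(self.origins)
        out: dict[tuple[str, str], Relation] = {}
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                out[(a, b)] = compare_pair(tree, self.origins[a],
                                           self.origins[b])
        return out

    def to_dict(self) -> dict:
        return {
            "origins": dict(self.origins),
            "loss_edges": {t: list(v) for t, v in self.loss_edges.items()},
            "lgt_nodes": dict(self.lgt_nodes),
            "resample_counts": dict(self.resample_counts),
        }


def _backbone(tree: RootedTree) -> list[str]:
    """Internal nodes on the path from the root to a deepest leaf."""
    deepest = max(
        (l for l in tree.node_ids() if tree.is_leaf(l)),
        key=lambda l: (tree.depth(l), l),
    )
    path = []
    cur: Optional[str] = tree.parent(deepest)
    while cur is not None:
        path.append(cur)
        cur = tree.parent(cur)
    return list(reversed(path))  # root first


def simulate_traits(
    tree: RootedTree, config: SimulationConfig,
    rng: Optional[random.Random] = None,
) -> tuple[TraitMatrix, GroundTruth]:
    """Single-origin/multiple-loss traits with a known nested origin order.

    Origins are spread evenly along the root-to-deepest-leaf backbone (so
    they are nested by construction and traits may share an origin node,
    forming blocks), or taken from ``config.origin_nodes`` when given.
    Each trait starts present on every leaf below its origin; every edge
    strictly below the origin then loses the trait independently with
    ``loss_prob`` (a loss silences the whole subtree). Loss draws leaving a
    trait with no bearer are resampled and counted. With ``lgt_prob`` a
    single extra gain is grafted onto one clade disjoint from the origin.
    """
    if rng is None:
        rng = _substream(config.seed, _TRAIT_STREAM)
    backbone = _backbone(tree)
    n = config.n_traits
    if config.origin_nodes is not None:
        if len(config.origin_nodes) != n:
            raise SimulationError("origin_nodes length must equal n_traits")
        origins = list(config.origin_nodes)
        for node in origins:
            if tree.is_leaf(node):
                raise SimulationError(f"origin must be internal: {node!r}")
    else:
        if config.distinct_origins and n > len(backbone):
            raise SimulationError(
                f"{n} distinct origins requested but the backbone has only "
                f"{len(backbone)} internal nodes"
            )
        if config.distinct_origins:
            idx = sorted(rng.sample(range(len(backbone)), n))
        elif n == 1:
            idx = [0]
        else:
            idx = [round(i * (len(backbone) - 1) / (n - 1)) for i in range(n)]
        origins = [backbone[i] for i in idx]

    width = len(str(n))
    trait_names = [f"T{i + 1:0{width}d}" for i in range(n)]
    species = sorted(tree.leaf_labels)
    data = pd.DataFrame(0, index=species, columns=trait_names, dtype="object")
    truth = GroundTruth(origins={}, loss_edges={}, lgt_nodes={},
                        resample_counts={})

    for trait, origin in zip(trait_names, origins):
        clade = tree.leaf_set(origin)
        for attempt in range(1000):
            losses: list[str] = []
            survivors = set(clade)
            stack = list(tree.children(origin))
            while stack:
                node = stack.pop()
                if rng.random() < config.loss_prob:
                    losses.append(node)
                    survivors -= tree.leaf_set(node)
                elif not tree.is_leaf(node):
                    stack.extend(tree.children(node))
            if survivors:
                truth.resample_counts[trait] = attempt
                break
        else:  # pragma: no cover
            raise SimulationError(
                f"could not draw surviving bearers for {trait} "
                f"(loss_prob={config.loss_prob})"
            )
        lgt_node: Optional[str] = None
        if rng.random() < config.lgt_prob:
            parent = tree.parent(origin)
            candidates = [
                nid for nid in tree.node_ids()
                if nid != tree.root_id
                and not tree.leaf_set(nid) & clade
                # a graft on the origin's sole sibling would fuse with the
                # origin clade into one clade and carry no homoplasy signal
                and not (parent is not None
                         and tree.parent(nid) == parent
                         and len(tree.children(parent)) == 2)
            ]
            if candidates:
                lgt_node = rng.choice(candidates)
                survivors |= tree.leaf_set(lgt_node)
        truth.origins[trait] = origin
        truth.loss_edges[trait] = losses
        truth.lgt_nodes[trait] = lgt_node
        for sp in survivors:
            data.at[sp, trait] = 1

    if config.missing_prob > 0:
        for trait in trait_names:
            present = [sp for sp in species if data.at[sp, trait] == 1]
            keep_one = rng.choice(present)
            for sp in species:
                if sp != keep_one and rng.random() < config.missing_prob:
                    data.at[sp, trait] = None
    return TraitMatrix(data), truth


def _nni_once(dtree: dendropy.Tree, rng: random.Random) -> Optional[tuple[str, str]]:
    """One random NNI move; returns (moved-subtree, sibling) leaf witnesses."""
    internal = [
        nd for nd in dtree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    if not internal:
        return None
    v = rng.choice(internal)
    u = v.parent_node
    sibs = [c for c in u.child_nodes() if c is not v]
    s = rng.choice(sibs)
    c = rng.choice(v.child_nodes())
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)
    witness = min(l.taxon.label for l in c.leaf_iter() if l.taxon)
    sib_witness = min(l.taxon.label for l in s.leaf_iter() if l.taxon)
    return witness, sib_witness


def _outgroup_clade_newick(labels: list[str]) -> str:
    s = labels[-1]
    for lab in reversed(labels[:-1]):
        s = f"({lab},{s})"
    return s


def simulate_gene_trees(
    tree: RootedTree, config: SimulationConfig,
    rng: Optional[random.Random] = None,
) -> tuple[dict[str, RootedTree], dict, list[str]]:
    """Subsampled, NNI-perturbed copies of the species tree plus an outgroup.

    Each gene tree keeps every ingroup leaf independently with
    ``retention_prob`` (redrawn until >= 4 leaves survive), undergoes
    ``n_nni`` random NNI moves, and receives a pectinate outgroup clade
    (O1..Om) as sister to the ingroup. Returns (trees, per-tree logs,
    outgroup labels). Branch lengths are not propagated; nothing downstream
    reads them.
    """
    if rng is None:
        rng = _substream(config.seed, _GENE_STREAM)
    outgroup = [f"O{i + 1}" for i in range(config.n_outgroup)]
    og_clade = _outgroup_clade_newick(outgroup)
    ingroup = sorted(tree.leaf_labels)
    trees: dict[str, RootedTree] = {}
    logs: dict[str, dict] = {}
    width = max(4, len(str(config.n_gene_trees)))
    for i in range(config.n_gene_trees):
        redraws = 0
        while True:
            kept = [sp for sp in ingroup
                    if rng.random() < config.retention_prob]
            if len(kept) >= 4:
                break
            redraws += 1
        sub = tree.prune_to(kept)
        dsub = sub._dtree.clone(depth=1)
        moves = []
        for _ in range(config.n_nni):
            mv = _nni_once(dsub, rng)
            if mv is not None:
                moves.append(mv)
        ingroup_newick = dsub.as_string(
            schema="newick", suppress_rooting=True,
            suppress_edge_lengths=True, unquoted_underscores=True,
        ).strip().rstrip(";")
        gid = f"g{i + 1:0{width}d}"
        trees[gid] = RootedTree.from_newick(
            f"({og_clade},{ingroup_newick});"
        )
        logs[gid] = {
            "n_leaves": len(kept),
            "redraws": redraws,
            "nni_moves": moves,
        }
    return trees, logs, outgroup


def derive_groups(tree: RootedTree) -> tuple[dict[str, str], str]:
    """Partition the ingroup into three named groups from the root split.

    The smaller root side becomes ``GroupA`` (the true basal group); the
    larger side is split at its first internal node into ``GroupB`` (its
    smaller side) and ``GroupC``. Returns (species -> group, basal group).
    """
    kids = tree.children(tree.root_id)
    if len(kids) != 2:
        raise SimulationError("species tree root must have two children")
    sides = sorted(kids, key=lambda k: (len(tree.leaf_set(k)), k))
    basal_side, big_side = sides[0], sides[1]
    groups = {sp: "GroupA" for sp in tree.leaf_set(basal_side)}
    big_kids = tree.children(big_side)
    if len(big_kids) < 2:  # big side is a leaf
        groups[big_side] = "GroupC"
        return groups, "GroupA"
    sub_sides = sorted(big_kids, key=lambda k: (len(tree.leaf_set(k)), k))
    for sp in tree.leaf_set(sub_sides[0]):
        groups[sp] = "GroupB"
    for k in sub_sides[1:]:
        for sp in tree.leaf_set(k):
            groups[sp] = "GroupC"
    return groups, "GroupA"


@dataclass
class SyntheticDataset:
    """Everything one simulated study comprises, in memory."""

    config: SimulationConfig
    species_tree: RootedTree
    matrix: TraitMatrix
    truth: GroundTruth
    gene_trees: dict[str, RootedTree]
    gene_tree_logs: dict[str, dict]
    group_map: GroupMap
    basal_group: str
    tree_attempts: int


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full dataset: species tree, traits, gene trees, groups.

    The Yule draw is repeated with bumped substream indices until every
    derived group has at least ``config.min_group_size`` species (the
    census needs informative groups); the number of attempts is recorded.
    """
    attempts = 0
    while True:
        attempts += 1
        if attempts > 100:
            raise SimulationError(
                "no species tree with large enough groups after 100 draws"
            )
        tree = simulate_species_tree(
            config.n_species, seed=config.seed + (attempts - 1),
        )
        groups, basal = derive_groups(tree)
        sizes = pd.Series(groups).value_counts()
        if int(sizes.min()) >= config.min_group_size:
            break
    matrix, truth = simulate_traits(tree, config)
    gene_trees, logs, outgroup = simulate_gene_trees(tree, config)
    group_map = GroupMap(groups=groups, outgroup=frozenset(outgroup))
    return SyntheticDataset(
        config=config, species_tree=tree, matrix=matrix, truth=truth,
        gene_trees=gene_trees, gene_tree_logs=logs, group_map=group_map,
        basal_group=basal, tree_attempts=attempts,
    )


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a dataset to disk and return its manifest.

    Files: species_tree.nwk, gene_trees.nwk (one per line), traits.tsv,
    groups.tsv, outgroup.txt, ground_truth.json, manifest.json. The
    manifest records the config, seed and SHA-256 checksums, so a re-run
    with the same config reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)

    files = {}
    (out / "species_tree.nwk").write_text(
        ds.species_tree.to_newick() + "\n", encoding="utf-8")
    (out / "gene_trees.nwk").write_text(
        "".join(t.to_newick() + "\n" for t in ds.gene_trees.values()),
        encoding="utf-8")
    ds.matrix.write_tsv(out / "traits.tsv")
    pd.DataFrame(
        {"species": list(ds.group_map.groups),
         "group": [ds.group_map.groups[s] for s in ds.group_map.groups]}
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    (out / "outgroup.txt").write_text(
        "\n".join(sorted(ds.group_map.outgroup)) + "\n", encoding="utf-8")
    (out / "ground_truth.json").write_text(
        json.dumps({
            **ds.truth.to_dict(),
            "blocks": [
                {"origin": node, "traits": traits}
                for node, traits in ds.truth.blocks(ds.species_tree)
            ],
            "basal_group": ds.basal_group,
        }, indent=2) + "\n", encoding="utf-8")
    for name in ("species_tree.nwk", "gene_trees.nwk", "traits.tsv",
                 "groups.tsv", "outgroup.txt", "ground_truth.json"):
        files[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "tree_attempts": ds.tree_attempts,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                       encoding="utf-8")
    return manifest
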