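"""Root-support census: which ingroup group is basal or ancestral per gene tree.

The placement of a species-tree root can be probed with many individually
rooted gene trees. Each gene tree is rooted on its outgroup, the outgroup is
stripped, and the two sides of the remaining ingroup root are characterized
by the named groups occurring on them:

* no group occurs on both sides and one side holds a single group — that
  group is **basal** (it forms a lineage of its own at the root);
* exactly one group occurs on both sides — that group is **ancestral** (the
  root falls within it);
* more than one group spans the root — **ambiguous**.

Two filters discard trees before classification: trees whose outgroup
leaves do not form a single partition of the unrooted topology (the rooting
is then undefined), and trees with fewer than ``min_per_group`` members of
any named group (the pattern is then uninformative).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Mapping, Optional, Sequence

import pandas as pd

from .tree import RootedTree


class GroupMapError(ValueError):
    pass


@dataclass(frozen=True)
class GroupMap:
    """Species -> group assignment plus the outgroup taxon list.

    Every ingroup species belongs to exactly one named group; the outgroup
    is disjoint from all groups.
    """

    groups: Mapping[str, str]
    outgroup: frozenset[str]

    def __post_init__(self):
        overlap = set(self.groups) & self.outgroup
        if overlap:
            raise GroupMapError(
                f"species both grouped and outgroup: {sorted(overlap)[:5]}"
            )
        if not self.outgroup:
            raise GroupMapError("empty outgroup list")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def group_of(self, species: str) -> str:
        try:
            return self.groups[species]
        except KeyError:
            raise GroupMapError(f"species not mapped to a group: {species!r}")

    @classmethod
    def from_files(cls, group_tsv: str | Path,
                   outgroup_file: str | Path) -> "GroupMap":
        df = pd.read_csv(group_tsv, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise GroupMapError("group map needs two columns: species, group")
        species_col, group_col = df.columns[0], df.columns[1]
        if df[species_col].duplicated().any():
            dups = df[species_col][df[species_col].duplicated()].tolist()
            raise GroupMapError(f"duplicate species in group map: {dups[:5]}")
        og = [
            line.strip()
            for line in Path(outgroup_file).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        return cls(groups=dict(zip(df[species_col], df[group_col])),
                   outgroup=frozenset(og))


@dataclass
class RootClassification:
    """Verdict for one rooted gene tree."""

    verdict: str  # "basal" | "ancestral" | "ambiguous" | "discarded"
    group: Optional[str] = None
    reason: Optional[str] = None  # discard reason or ambiguity note
    side_groups: Optional[tuple[frozenset[str], ...]] = None

    @property
    def is_discarded(self) -> bool:
        return self.verdict == "discarded"

    def label(self) -> str:
        if self.group:
            return f"{self.verdict}({self.group})"
        if self.reason and self.verdict == "discarded":
            return f"discarded({self.reason})"
        return self.verdict


def classify_root(tree: RootedTree, group_map: GroupMap) -> RootClassification:
    """Classify a rooted, outgroup-free gene tree by its root-side groups."""
    root_kids = tree.children(tree.root_id)
    if len(root_kids) != 2:
        return RootClassification(
            verdict="ambiguous",
            reason=f"root has {len(root_kids)} children; sides undefined",
        )
    sides = tuple(
        frozenset(group_map.group_of(sp) for sp in tree.leaf_set(k))
        for k in root_kids
    )
    spanning = sides[0] & sides[1]
    if len(spanning) > 1:
        return RootClassification(verdict="ambiguous", side_groups=sides,
                                  reason="multiple groups span the root")
    if len(spanning) == 1:
        return RootClassification(verdict="ancestral",
                                  group=next(iter(spanning)),
                                  side_groups=sides)
    single = [s for s in sides if len(s) == 1]
    if len(single) == 1:
        return RootClassification(verdict="basal",
                                  group=next(iter(single[0])),
                                  side_groups=sides)
    if len(single) == 2:
        # Both sides single-group with different groups (only two groups
        # survive): "basal" is not well defined.
        return RootClassification(
            verdict="ambiguous", side_groups=sides,
            reason="both root sides are single-group; basal side undefined",
        )
    return RootClassification(
        verdict="ambiguous", side_groups=sides,
        reason="no group spans the root and no side is single-group",
    )


@dataclass
class CensusResult:
    """Tally and per-tree verdicts for a gene-tree root census."""

    tally: dict[str, int]
    records: pd.DataFrame
    median_metadata: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"tally": dict(self.tally)}
        if self.median_metadata:
            out["median_metadata"] = dict(self.median_metadata)
        return out

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def census(
    gene_trees: Mapping[str, RootedTree] | Sequence[RootedTree],
    group_map: GroupMap,
    min_per_group: int = 2,
    metadata: Optional[Mapping[str, float]] = None,
) -> CensusResult:
    """Run the two-filter root census over a collection of gene trees.

    Per tree: (1) discard if the outgroup leaves do not form a single
    partition; (2) root on the outgroup and strip it; (3) discard if any
    named group has fewer than ``min_per_group`` leaves; (4) classify the
    root. ``metadata`` (tree id -> number, e.g. alignment length) yields
    per-verdict medians in the result.
    """
    if isinstance(gene_trees, Mapping):
        items = list(gene_trees.items())
    else:
        items = [(f"g{i + 1:04d}", t) for i, t in enumerate(gene_trees)]
    tally: Counter[str] = Counter()
    rows = []
    meta_by_label: dict[str, list[float]] = {}
    for tid, gt in items:
        og_here = group_map.outgroup & gt.leaf_labels
        if not og_here or og_here == gt.leaf_labels \
                or not gt.outgroup_partition_ok(og_here):
            cls = RootClassification(verdict="discarded",
                                     reason="outgroup_split")
        else:
            rooted = gt.root_on_outgroup(og_here)
            ingroup = rooted.prune_to(rooted.leaf_labels - og_here)
            counts = Counter(group_map.group_of(sp)
                             for sp in ingroup.leaf_labels)
            short = [g for g in group_map.group_names
                     if counts.get(g, 0) < min_per_group]
            if short:
                cls = RootClassification(verdict="discarded",
                                         reason="min_group_count")
            else:
                cls = classify_root(ingroup, group_map)
        label = cls.label()
        tally[label] += 1
        rows.append({
            "tree_id": tid,
            "verdict": cls.verdict,
            "group": cls.group,
            "reason": cls.reason,
            "side_groups": (
                " | ".join(",".join(sorted(s)) for s in cls.side_groups)
                if cls.side_groups else None
            ),
        })
        if metadata is not None and tid in metadata:
            meta_by_label.setdefault(label, []).append(float(metadata[tid]))
    medians = {lab: float(median(vals)) for lab, vals in meta_by_label.items()}
    return CensusResult(
        tally=dict(tally),
        records=pd.DataFrame(rows),
        median_metadata=medians,
    )
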