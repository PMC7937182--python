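"""Rooted phylogeny data model, Newick I/O, outgroup rooting and ancestry queries.

The :class:`RootedTree` wraps a :mod:`dendropy` tree and treats it as
immutable: every topology-changing operation (rerooting, pruning) returns a
new instance. Nodes are addressed by stable string ids assigned in preorder
at construction — leaves are addressed by their label, internal nodes by a
generated id — so downstream results (origin maps, order reports) serialize
naturally.

Polytomies are first-class: internal nodes may have any number >= 2 of
children, and no operation binarizes them. Internal Newick labels (typically
bootstrap values in gene trees) are retained as opaque annotations and never
interpreted as taxa.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import dendropy


class TreeError(ValueError):
    """Base class for tree construction and query errors."""


class NewickParseError(TreeError):
    """Raised when a Newick string cannot be parsed."""


class DuplicateLabelError(TreeError):
    """Raised when a tree carries the same leaf label more than once."""


class OutgroupError(TreeError):
    """Raised when a requested outgroup cannot root the tree.

    The main instance is "outgroup not a single partition": no edge of the
    unrooted topology separates exactly the outgroup leaves from the rest.
    Callers running a census record the tree as discarded instead of failing.
    """


class UnknownLabelError(TreeError):
    """Raised when a query names a leaf label absent from the tree."""


class UnknownNodeError(TreeError):
    """Raised when a query names a node id absent from the tree."""


_PARSE_KWARGS = dict(
    schema="newick",
    suppress_internal_node_taxa=True,
    preserve_underscores=True,
)


class RootedTree:
    """A rooted phylogeny with unique leaf labels and addressable nodes.

    Parameters
    ----------
    dtree
        A dendropy tree. Ownership is taken: the caller must not mutate it
        afterwards. Unifurcations (single-child internal nodes) are collapsed
        at construction.
    """

    def __init__(self, dtree: dendropy.Tree):
        if dtree.seed_node is None:
            raise TreeError("empty tree")
        dtree.suppress_unifurcations()
        self._dtree = dtree

        leaves = [nd for nd in dtree.leaf_node_iter()]
        labels = []
        for nd in leaves:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                raise TreeError("leaf with empty label")
            labels.append(label)
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise DuplicateLabelError(
                f"duplicate leaf labels: {', '.join(sorted(dup))}"
            )

        # Internal node ids must not collide with leaf labels.
        prefix = "N"
        label_set = set(labels)
        while any(lab.startswith(prefix) and lab[len(prefix):].isdigit()
                  for lab in label_set):
            prefix += "_"

        self._node_of: dict[str, dendropy.Node] = {}
        self._id_of: dict[int, str] = {}  # id(dendropy node) -> node id
        self._parent: dict[str, Optional[str]] = {}
        self._children: dict[str, tuple[str, ...]] = {}
        self._depth: dict[str, int] = {}
        self._preorder: list[str] = []
        counter = 0
        for nd in dtree.preorder_node_iter():
            if nd.is_leaf():
                nid = nd.taxon.label if nd.taxon is not None else nd.label
            else:
                nid = f"{prefix}{counter}"
                counter += 1
            self._node_of[nid] = nd
            self._id_of[id(nd)] = nid
            par = nd.parent_node
            self._parent[nid] = self._id_of[id(par)] if par is not None else None
            self._depth[nid] = 0 if par is None else self._depth[self._parent[nid]] + 1
            self._preorder.append(nid)
        for nid, nd in self._node_of.items():
            self._children[nid] = tuple(
                self._id_of[id(c)] for c in nd.child_nodes()
            )

        self._postorder: list[str] = list(reversed(self._preorder))
        self._leaf_labels: frozenset[str] = frozenset(labels)
        self._bit: dict[str, int] = {
            lab: i for i, lab in enumerate(sorted(labels))
        }
        # Leaf-set bitmasks per node, bottom-up.
        self._mask: dict[str, int] = {}
        for nid in self._postorder:
            kids = self._children[nid]
            if not kids:
                self._mask[nid] = 1 << self._bit[nid]
            else:
                m = 0
                for k in kids:
                    m |= self._mask[k]
                self._mask[nid] = m
        self._root_id = self._preorder[0]
        self._full_mask = self._mask[self._root_id]
        self._leafset_cache: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        """Parse a single Newick statement into a rooted tree."""
        try:
            dtree = dendropy.Tree.get(data=text, **_PARSE_KWARGS)
        except Exception as exc:  # dendropy raises several parse error types
            msg = str(exc)
            if "Multiple occurrences" in msg or "Duplicate tax" in msg:
                raise DuplicateLabelError(msg) from exc
            raise NewickParseError(msg) from exc
        return cls(dtree)

    def to_newick(self, include_lengths: bool = True) -> str:
        """Serialize to a Newick string (single line, trailing semicolon)."""
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=not include_lengths,
            real_value_format_specifier=".17g",
        )
        return s.strip()

    # ------------------------------------------------------------ structure

    @property
    def root_id(self) -> str:
        return self._root_id

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def node_ids(self) -> list[str]:
        """All node ids in preorder (root first)."""
        return list(self._preorder)

    def preorder(self) -> Iterator[str]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[str]:
        return iter(self._postorder)

    def is_leaf(self, node_id: str) -> bool:
        self._check_node(node_id)
        return not self._children[node_id]

    def parent(self, node_id: str) -> Optional[str]:
        self._check_node(node_id)
        return self._parent[node_id]

    def children(self, node_id: str) -> tuple[str, ...]:
        self._check_node(node_id)
        return self._children[node_id]

    def depth(self, node_id: str) -> int:
        """Number of edges from the root to the node."""
        self._check_node(node_id)
        return self._depth[node_id]

    def edge_length(self, node_id: str) -> Optional[float]:
        """Length of the edge above the node (None if absent or root)."""
        self._check_node(node_id)
        return self._node_of[node_id].edge.length

    def annotation(self, node_id: str) -> Optional[str]:
        """Internal-node label (e.g. bootstrap support) carried by the input."""
        self._check_node(node_id)
        nd = self._node_of[node_id]
        return None if nd.is_leaf() else nd.label

    def leaf_set(self, node_id: str) -> frozenset[str]:
        """Labels of the leaves descending from (or equal to) the node."""
        self._check_node(node_id)
        if node_id not in self._leafset_cache:
            mask = self._mask[node_id]
            self._leafset_cache[node_id] = frozenset(
                lab for lab, b in self._bit.items() if mask >> b & 1
            )
        return self._leafset_cache[node_id]

    def _check_node(self, node_id: str) -> None:
        if node_id not in self._node_of:
            raise UnknownNodeError(f"unknown node id: {node_id!r}")

    def _labels_mask(self, labels: Iterable[str]) -> int:
        m = 0
        n = 0
        for lab in labels:
            n += 1
            try:
                m |= 1 << self._bit[lab]
            except KeyError:
                raise UnknownLabelError(f"unknown leaf label: {lab!r}") from None
        if n == 0:
            raise TreeError("empty label set")
        return m

    # ------------------------------------------------------------- ancestry

    def mrca(self, labels: Iterable[str]) -> str:
        """Most recent common ancestor of a non-empty set of leaf labels.

        The unique deepest node whose descendant leaf set contains all of
        ``labels``; the MRCA of a single leaf is that leaf itself.
        """
        target = self._labels_mask(labels)
        best = self._root_id
        best_depth = -1
        for nid in self._preorder:
            m = self._mask[nid]
            if m & target == target and self._depth[nid] > best_depth:
                best, best_depth = nid, self._depth[nid]
        return best

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff node ``a`` lies strictly above node ``b``."""
        self._check_node(a)
        self._check_node(b)
        if a == b:
            return False
        da = self._depth[a]
        cur: Optional[str] = self._parent[b]
        while cur is not None and self._depth[cur] >= da:
            if cur == a:
                return True
            cur = self._parent[cur]
        return False

    # ------------------------------------------------------------- rerooting

    def outgroup_partition_ok(self, outgroup: Iterable[str]) -> bool:
        """Does some edge of the unrooted topology split off exactly the outgroup?

        A single-leaf outgroup is always a partition. Raises
        :class:`OutgroupError` if the outgroup is empty, not a subset of the
        leaves, or equals the full leaf set.
        """
        og = frozenset(outgroup)
        self._validate_outgroup(og)
        return self._find_split_node(og) is not None

    def root_on_outgroup(self, outgroup: Iterable[str]) -> "RootedTree":
        """Root on the branch separating the outgroup from the ingroup.

        The result's root has exactly two children, one subtending exactly
        the outgroup leaves and the other the ingroup leaves. A branch length
        on the split edge is divided equally between the two new root edges.
        Rooting is recomputed from the unrooted topology even for already
        rooted input.
        """
        og = frozenset(outgroup)
        self._validate_outgroup(og)
        split = self._find_split_node(og)
        if split is None:
            raise OutgroupError("outgroup not a single partition")
        # Already correctly rooted: the root separates outgroup from ingroup.
        kids = self._children[self._root_id]
        if len(kids) == 2 and any(self.leaf_set(k) == og for k in kids):
            return self
        clone = self._dtree.clone(depth=1)
        node = self._matching_clone_node(clone, self._mask[split])
        edge = node.edge
        if edge.length is not None:
            half = edge.length / 2.0
            clone.reroot_at_edge(edge, length1=half, length2=half,
                                 update_bipartitions=False)
        else:
            clone.reroot_at_edge(edge, update_bipartitions=False)
        return RootedTree(clone)

    def _validate_outgroup(self, og: frozenset[str]) -> None:
        if not og:
            raise OutgroupError("empty outgroup")
        missing = og - self._leaf_labels
        if missing:
            raise OutgroupError(
                f"outgroup labels not in tree: {', '.join(sorted(missing))}"
            )
        if og == self._leaf_labels:
            raise OutgroupError("outgroup equals the full leaf set")

    def _find_split_node(self, og: frozenset[str]) -> Optional[str]:
        """A non-root node whose leaf set is the outgroup or its complement."""
        target = self._labels_mask(og)
        comp = self._full_mask & ~target
        for nid in self._preorder:
            if nid == self._root_id:
                continue
            if self._mask[nid] == target or self._mask[nid] == comp:
                return nid
        return None

    def _matching_clone_node(self, clone: dendropy.Tree, mask: int) -> dendropy.Node:
        for nd in clone.preorder_node_iter():
            m = 0
            for leaf in nd.leaf_iter():
                m |= 1 << self._bit[leaf.taxon.label if leaf.taxon else leaf.label]
            if m == mask:
                return nd
        raise AssertionError("clone lost the split node")  # pragma: no cover

    # -------------------------------------------------------------- pruning

    def prune_to(self, labels: Iterable[str]) -> "RootedTree":
        """Restrict the tree to the given leaves (unifurcations collapsed)."""
        keep = set(labels)
        missing = keep - self._leaf_labels
        if missing:
            raise UnknownLabelError(
                f"labels not in tree: {', '.join(sorted(missing))}"
            )
        if not keep:
            raise TreeError("cannot prune to an empty leaf set")
        if keep == self._leaf_labels:
            return self
        sub = self._dtree.extract_tree_with_taxa_labels(keep)
        return RootedTree(sub)

    # ------------------------------------------------------------- equality

    def same_topology(self, other: "RootedTree") -> bool:
        """Rooted-topology identity: same leaf sets at every node."""
        if self._leaf_labels != other._leaf_labels:
            return False
        mine = {frozenset(self.leaf_set(n)) for n in self.node_ids()}
        theirs = {frozenset(other.leaf_set(n)) for n in other.node_ids()}
        return mine == theirs

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedTree with {self.n_leaves} leaves>"


def parse_newick(text: str) -> RootedTree:
    """Parse one Newick statement (see :meth:`RootedTree.from_newick`)."""
    return RootedTree.from_newick(text)


def write_newick(tree: RootedTree, include_lengths: bool = True) -> str:
    return tree.to_newick(include_lengths=include_lengths)


def read_newick_file(path: str | Path) -> list[RootedTree]:
    """Read one or more trees from a Newick file (one statement per line)."""
    trees: list[RootedTree] = []
    text = Path(path).read_text(encoding="utf-8")
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(RootedTree.from_newick(chunk + ";"))
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return trees


def root_and_strip_outgroup(
    gene_trees: Mapping[str, "RootedTree"],
    outgroup: Iterable[str],
) -> tuple[dict[str, "RootedTree"], list[str]]:
    """Root each gene tree on its outgroup leaves and drop the outgroup.

    Trees whose outgroup leaves (those present in the tree) do not form a
    single partition — or that contain no outgroup leaf at all — cannot be
    rooted and are returned in the discarded list instead.
    """
    og = frozenset(outgroup)
    rooted: dict[str, RootedTree] = {}
    discarded: list[str] = []
    for tid, gt in gene_trees.items():
        present = og & gt.leaf_labels
        if not present or present == gt.leaf_labels:
            discarded.append(tid)
            continue
        if not gt.outgroup_partition_ok(present):
            discarded.append(tid)
            continue
        r = gt.root_on_outgroup(present)
        rooted[tid] = r.prune_to(r.leaf_labels - present)
    return rooted, discarded


def read_gene_trees(path: str | Path) -> dict[str, RootedTree]:
    """Read gene trees from a multi-tree Newick file or a directory of files.

    Returns a mapping from tree id to tree: file stem for directory input,
    ``g0001``-style sequence numbers for multi-tree files.
    """
    p = Path(path)
    if p.is_dir():
        out: dict[str, RootedTree] = {}
        for f in sorted(p.iterdir()):
            if f.suffix.lower() in {".nwk", ".newick", ".tre", ".tree", ".txt"}:
                for i, t in enumerate(read_newick_file(f)):
                    key = f.stem if i == 0 else f"{f.stem}.{i}"
                    out[key] = t
        if not out:
            raise NewickParseError(f"no Newick files found in {path}")
        return out
    trees = read_newick_file(p)
    width = max(4, len(str(len(trees))))
    return {f"g{i + 1:0{width}d}": t for i, t in enumerate(trees)}
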