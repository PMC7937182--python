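"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use different algorithms than the package:
MRCA by intersecting root-to-leaf paths, and parsimony by exhaustive
enumeration of ancestral state assignments.
"""

from __future__ import annotations

import itertools
import random
from typing import Optional

import pytest

from traitorder.tree import RootedTree, parse_newick


def random_newick(rng: random.Random, n_leaves: int,
                  polytomy_prob: float = 0.0,
                  with_lengths: bool = False) -> str:
    """Random rooted tree over leaves L1..Ln by sequential joining."""
    subtrees = [f"L{i + 1}" for i in range(n_leaves)]
    rng.shuffle(subtrees)
    while len(subtrees) > 1:
        k = 2
        if len(subtrees) > 2 and rng.random() < polytomy_prob:
            k = rng.randint(3, min(4, len(subtrees)))
        picks = [subtrees.pop(rng.randrange(len(subtrees))) for _ in range(k)]
        if with_lengths:
            picks = [f"{p}:{rng.uniform(0.01, 2.0):.6g}" for p in picks]
        subtrees.append("(" + ",".join(picks) + ")")
    return subtrees[0] + ";"


def random_tree(rng: random.Random, n_leaves: int,
                polytomy_prob: float = 0.0) -> RootedTree:
    return parse_newick(random_newick(rng, n_leaves, polytomy_prob))


def oracle_mrca(tree: RootedTree, labels) -> str:
    """MRCA by intersecting root-to-leaf paths (deepest shared node)."""
    paths = []
    for lab in labels:
        path = [lab]
        cur = tree.parent(lab)
        while cur is not None:
            path.append(cur)
            cur = tree.parent(cur)
        paths.append(list(reversed(path)))  # root first
    shared = None
    for nodes in zip(*paths):
        if len(set(nodes)) == 1:
            shared = nodes[0]
        else:
            break
    assert shared is not None
    return shared


def oracle_parsimony(tree: RootedTree, states: dict[str, Optional[int]]) -> int:
    """Minimum changes by brute force over all ancestral assignments.

    Missing leaves are free: their states are enumerated too. Exponential;
    only for trees with few internal nodes.
    """
    free = [n for n in tree.node_ids()
            if not tree.is_leaf(n) or states[n] is None]
    fixed = {n: states[n] for n in tree.node_ids()
             if tree.is_leaf(n) and states[n] is not None}
    edges = [(tree.parent(n), n) for n in tree.node_ids()
             if tree.parent(n) is not None]
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        cost = sum(1 for p, c in edges if assign[p] != assign[c])
        if best is None or cost < best:
            best = cost
    return best


@pytest.fixture
def balanced4() -> RootedTree:
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def caterpillar6() -> RootedTree:
    return parse_newick("(A,(B,(C,(D,(E,F)))));")
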