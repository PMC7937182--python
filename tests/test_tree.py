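"""Rooted-tree model: parsing, round trips, MRCA/ancestry, outgroup rooting."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from traitorder.tree import (
    DuplicateLabelError,
    NewickParseError,
    OutgroupError,
    TreeError,
    UnknownLabelError,
    UnknownNodeError,
    parse_newick,
    read_gene_trees,
    root_and_strip_outgroup,
    write_newick,
)

from conftest import oracle_mrca, random_newick, random_tree


class TestParsing:
    def test_balanced_structure(self, balanced4):
        assert balanced4.leaf_labels == {"A", "B", "C", "D"}
        internals = [n for n in balanced4.node_ids()
                     if not balanced4.is_leaf(n)]
        assert len(internals) == 3  # root + two cherries

    def test_polytomy_preserved(self):
        t = parse_newick("(A,B,C);")
        assert t.children(t.root_id) == ("A", "B", "C")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DuplicateLabelError):
            parse_newick("((A,B),(A,C));")

    @pytest.mark.parametrize("bad", ["((A,B", "(A,(B,C);", "", "(A,B))C;"])
    def test_malformed_rejected(self, bad):
        with pytest.raises((NewickParseError, TreeError)):
            parse_newick(bad)

    def test_internal_labels_kept_as_annotations(self):
        t = parse_newick("((A:1,B:1)95:0.5,C:2);")
        ann = [t.annotation(n) for n in t.node_ids() if not t.is_leaf(n)]
        assert "95" in ann
        # never interpreted as taxa
        assert "95" not in t.leaf_labels

    def test_quoted_and_underscore_labels(self):
        t = parse_newick("('sp one',sp_two);")
        assert t.leaf_labels == {"sp one", "sp_two"}


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_parse_write_parse_isomorphic(self, seed):
        rng = random.Random(seed)
        t = random_tree(rng, rng.randint(4, 20), polytomy_prob=0.3)
        t2 = parse_newick(write_newick(t))
        assert t2.same_topology(t)

    def test_branch_lengths_preserved(self):
        rng = random.Random(99)
        text = random_newick(rng, 8, with_lengths=True)
        t = parse_newick(text)
        t2 = parse_newick(write_newick(t))
        lengths = sorted(t.edge_length(l) for l in t.leaf_labels)
        lengths2 = sorted(t2.edge_length(l) for l in t2.leaf_labels)
        assert lengths == pytest.approx(lengths2, rel=1e-10)

    def test_single_leaf_degenerate(self):
        assert write_newick(parse_newick("A;")) == "A;"


class TestMrca:
    def test_cherry(self, balanced4):
        assert balanced4.leaf_set(balanced4.mrca({"A", "B"})) == {"A", "B"}

    def test_spanning_pair_hits_root(self, balanced4):
        assert balanced4.mrca({"A", "C"}) == balanced4.root_id

    def test_singleton_is_leaf(self, balanced4):
        assert balanced4.mrca({"A"}) == "A"

    def test_unknown_label_named_in_error(self, balanced4):
        with pytest.raises(UnknownLabelError, match="Z"):
            balanced4.mrca({"A", "Z"})

    def test_empty_set_rejected(self, balanced4):
        with pytest.raises(TreeError):
            balanced4.mrca(set())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_path_intersection_oracle(self, seed):
        rng = random.Random(seed)
        t = random_tree(rng, rng.randint(4, 64), polytomy_prob=0.2)
        leaves = sorted(t.leaf_labels)
        labels = rng.sample(leaves, rng.randint(1, min(8, len(leaves))))
        assert t.mrca(labels) == oracle_mrca(t, labels)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_mrca_is_minimal_cover(self, seed):
        """Every label descends from the MRCA and no child covers them all."""
        rng = random.Random(seed)
        t = random_tree(rng, rng.randint(4, 32))
        labels = set(rng.sample(sorted(t.leaf_labels), rng.randint(2, 4)))
        m = t.mrca(labels)
        assert labels <= t.leaf_set(m)
        for c in t.children(m):
            assert not labels <= t.leaf_set(c)


class TestIsAncestor:
    def test_root_above_everything(self, balanced4):
        for n in balanced4.node_ids():
            if n != balanced4.root_id:
                assert balanced4.is_ancestor(balanced4.root_id, n)

    def test_irreflexive(self, balanced4):
        for n in balanced4.node_ids():
            assert not balanced4.is_ancestor(n, n)

    def test_disjoint_subtrees_unrelated(self, balanced4):
        assert not balanced4.is_ancestor("A", "C")
        assert not balanced4.is_ancestor("C", "A")

    def test_unknown_node_rejected(self, balanced4):
        with pytest.raises(UnknownNodeError):
            balanced4.is_ancestor("nope", "A")


class TestOutgroupRooting:
    def test_clade_outgroup_ok(self):
        t = parse_newick("((O1,O2),(A,(B,C)));")
        assert t.outgroup_partition_ok({"O1", "O2"})

    def test_interleaved_outgroup_not_ok(self):
        t = parse_newick("((O1,A),(O2,(B,C)));")
        assert not t.outgroup_partition_ok({"O1", "O2"})

    def test_single_leaf_outgroup_always_partitions(self):
        t = parse_newick("((O1,A),B);")
        assert t.outgroup_partition_ok({"O1"})

    def test_full_leafset_outgroup_rejected(self, balanced4):
        with pytest.raises(OutgroupError):
            balanced4.outgroup_partition_ok({"A", "B", "C", "D"})

    def test_unknown_outgroup_rejected(self, balanced4):
        with pytest.raises(OutgroupError):
            balanced4.outgroup_partition_ok({"A", "Z"})

    def test_rooting_forces_split(self):
        t = parse_newick("(O1,O2,(A,(B,C)));")
        r = t.root_on_outgroup({"O1", "O2"})
        sides = {r.leaf_set(c) for c in r.children(r.root_id)}
        assert sides == {frozenset({"O1", "O2"}), frozenset({"A", "B", "C"})}

    def test_rooting_idempotent_on_correct_split(self):
        t = parse_newick("((O1,O2),(A,(B,C)));")
        r = t.root_on_outgroup({"O1", "O2"})
        sides = {r.leaf_set(c) for c in r.children(r.root_id)}
        assert frozenset({"O1", "O2"}) in sides

    def test_interleaved_outgroup_raises(self):
        t = parse_newick("((O1,A),(O2,(B,C)));")
        with pytest.raises(OutgroupError, match="single partition"):
            t.root_on_outgroup({"O1", "O2"})

    def test_split_edge_length_halved(self):
        t = parse_newick("(O1:1,A:2,(B:1,C:1):3);")
        r = t.root_on_outgroup({"B", "C"})
        kids = r.children(r.root_id)
        lengths = sorted(r.edge_length(k) for k in kids)
        assert lengths == pytest.approx([1.5, 1.5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_rerooted_tree_partitions_outgroup(self, seed):
        """root_on_outgroup then outgroup_partition_ok is always true."""
        rng = random.Random(seed)
        t = random_tree(rng, rng.randint(5, 24))
        # any non-root clade is a legal outgroup
        clades = [t.leaf_set(n) for n in t.node_ids()
                  if n != t.root_id and t.leaf_set(n) != t.leaf_labels]
        og = rng.choice(clades)
        r = t.root_on_outgroup(og)
        assert r.outgroup_partition_ok(og)
        assert len(r.children(r.root_id)) == 2
        assert r.leaf_labels == t.leaf_labels


class TestRootAndStrip:
    def test_mixed_set(self):
        trees = {
            "ok": parse_newick("((O1,O2),(A,(B,C)));"),
            "bad": parse_newick("((O1,A),(O2,(B,C)));"),
            "no_og": parse_newick("((A,B),(C,D));"),
        }
        rooted, discarded = root_and_strip_outgroup(trees, {"O1", "O2"})
        assert sorted(discarded) == ["bad", "no_og"]
        assert rooted["ok"].leaf_labels == {"A", "B", "C"}


def test_read_gene_trees_from_file_and_dir(tmp_path):
    (tmp_path / "many.nwk").write_text("((A,B),C);\n((A,C),B);\n")
    trees = read_gene_trees(tmp_path / "many.nwk")
    assert len(trees) == 2
    d = tmp_path / "trees"
    d.mkdir()
    (d / "fam1.nwk").write_text("((A,B),C);\n")
    (d / "fam2.nwk").write_text("((A,C),B);\n")
    by_dir = read_gene_trees(d)
    assert set(by_dir) == {"fam1", "fam2"}
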