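"""Synthetic-data generator: determinism, ground-truth consistency, recovery."""

import json

import pytest

from traitorder.order import Relation, build_order
from traitorder.parsimony import parsimony_steps
from traitorder.simulate import (
    SimulationConfig,
    SimulationError,
    _backbone,
    generate_dataset,
    simulate_dataset,
    simulate_gene_trees,
    simulate_species_tree,
    simulate_traits,
)

FAST = dict(n_species=16, n_traits=4, n_gene_trees=6, n_outgroup=2)


class TestSpeciesTree:
    def test_cherry_for_two(self):
        t = simulate_species_tree(2, seed=1)
        assert t.n_leaves == 2 and len(t.children(t.root_id)) == 2

    @pytest.mark.parametrize("n", [4, 17, 64])
    def test_leaf_count(self, n):
        assert simulate_species_tree(n, seed=3).n_leaves == n

    def test_seed_determinism(self):
        a = simulate_species_tree(64, seed=9).to_newick()
        b = simulate_species_tree(64, seed=9).to_newick()
        assert a == b
        c = simulate_species_tree(64, seed=10).to_newick()
        assert a != c


class TestTraits:
    def test_noise_free_presence_is_origin_clade(self):
        cfg = SimulationConfig(**FAST, loss_prob=0.0, seed=4)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        matrix, truth = simulate_traits(tree, cfg)
        for trait, origin in truth.origins.items():
            assert matrix.presence_set(trait) == tree.leaf_set(origin)
        # and the pipeline recovers the exact block order
        rep = build_order(tree, matrix)
        assert rep.blocks == truth.blocks(tree)

    def test_origins_nested_along_backbone(self):
        cfg = SimulationConfig(**FAST, loss_prob=0.3, seed=5)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        _, truth = simulate_traits(tree, cfg)
        rels = truth.relations(tree)
        assert all(r is not Relation.NON_NESTED for r in rels.values())

    def test_every_trait_has_a_bearer(self):
        cfg = SimulationConfig(**FAST, loss_prob=0.45, seed=6)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        matrix, truth = simulate_traits(tree, cfg)
        for trait in matrix.traits:
            assert matrix.presence_set(trait)
            assert truth.resample_counts[trait] >= 0

    def test_loss_events_bound_parsimony_steps(self):
        """With no LGT: 1 <= s <= 1 + recorded losses; s == 1 when loss-free."""
        cfg = SimulationConfig(**FAST, loss_prob=0.1, lgt_prob=0.0, seed=7)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        matrix, truth = simulate_traits(tree, cfg)
        for trait in matrix.traits:
            s = parsimony_steps(tree, matrix.states(trait))
            n_loss = len(truth.loss_edges[trait])
            if truth.origins[trait] == tree.root_id and n_loss == 0:
                assert s <= 1
            else:
                assert 1 <= s <= 1 + n_loss
            if n_loss == 0:
                assert s <= 1

    def test_forced_lgt_creates_homoplasy(self):
        """A grafted extra gain forces at least two parsimony steps."""
        cfg = SimulationConfig(**FAST, loss_prob=0.0, lgt_prob=1.0, seed=8)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        matrix, truth = simulate_traits(tree, cfg)
        for trait in matrix.traits:
            if truth.lgt_nodes[trait] is not None:
                assert parsimony_steps(tree, matrix.states(trait)) >= 2

    def test_missing_states_leave_observations(self):
        cfg = SimulationConfig(**FAST, missing_prob=0.3, seed=9)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        matrix, _ = simulate_traits(tree, cfg)
        for trait in matrix.traits:
            assert matrix.presence_set(trait)

    def test_too_many_distinct_origins_rejected(self):
        cfg = SimulationConfig(n_species=4, n_traits=4,
                               distinct_origins=True, seed=1)
        tree = simulate_species_tree(4, 1)
        assert len(_backbone(tree)) < 4
        with pytest.raises(SimulationError):
            simulate_traits(tree, cfg)


class TestGeneTrees:
    def test_zero_noise_trees_match_species_topology(self):
        cfg = SimulationConfig(**FAST, retention_prob=1.0, n_nni=0, seed=10)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        trees, logs, og = simulate_gene_trees(tree, cfg)
        assert len(trees) == cfg.n_gene_trees
        for gt in trees.values():
            ingroup = gt.prune_to(gt.leaf_labels - set(og))
            assert ingroup.same_topology(tree)

    def test_subsampled_splits_stay_compatible(self):
        """With no NNI every gene-tree clade is a restriction of a species clade."""
        cfg = SimulationConfig(**FAST, retention_prob=0.7, n_nni=0, seed=11)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        trees, _, og = simulate_gene_trees(tree, cfg)
        species_clades = {tree.leaf_set(n) for n in tree.node_ids()}
        for gt in trees.values():
            ingroup = gt.prune_to(gt.leaf_labels - set(og))
            kept = ingroup.leaf_labels
            restricted = {c & kept for c in species_clades}
            for n in ingroup.node_ids():
                assert ingroup.leaf_set(n) in restricted

    def test_outgroup_always_monophyletic(self):
        cfg = SimulationConfig(**FAST, n_nni=3, seed=12)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        trees, _, og = simulate_gene_trees(tree, cfg)
        for gt in trees.values():
            assert gt.outgroup_partition_ok(set(og))

    def test_nni_changes_topology(self):
        cfg = SimulationConfig(**FAST, retention_prob=1.0, n_nni=4, seed=13)
        tree = simulate_species_tree(cfg.n_species, cfg.seed)
        trees, logs, og = simulate_gene_trees(tree, cfg)
        changed = sum(
            not gt.prune_to(gt.leaf_labels - set(og)).same_topology(tree)
            for gt in trees.values())
        assert changed > 0
        assert all(len(l["nni_moves"]) == 4 for l in logs.values())


class TestDataset:
    def test_files_written_and_parseable(self, tmp_path):
        cfg = SimulationConfig(**FAST, seed=20)
        manifest = generate_dataset(cfg, tmp_path)
        for name in manifest["files"]:
            assert (tmp_path / name).exists()
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert len(truth["origins"]) == cfg.n_traits

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(**FAST, seed=21)
        m1 = generate_dataset(cfg, tmp_path / "a")
        m2 = generate_dataset(cfg, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_gene_tree_count_does_not_perturb_traits(self, tmp_path):
        base = dict(FAST, seed=22)
        m1 = generate_dataset(SimulationConfig(**base), tmp_path / "a")
        m2 = generate_dataset(
            SimulationConfig(**{**base, "n_gene_trees": 3}), tmp_path / "b")
        assert m1["files"]["traits.tsv"] == m2["files"]["traits.tsv"]
        assert m1["files"]["species_tree.nwk"] == m2["files"]["species_tree.nwk"]

    def test_groups_cover_ingroup_disjoint_from_outgroup(self):
        ds = simulate_dataset(SimulationConfig(**FAST, seed=23))
        assert set(ds.group_map.groups) == set(ds.species_tree.leaf_labels)
        assert not ds.group_map.outgroup & set(ds.group_map.groups)
        sizes = [list(ds.group_map.groups.values()).count(g)
                 for g in ds.group_map.group_names]
        assert min(sizes) >= 2


class TestRecovery:
    def test_pairwise_recovery_under_mild_noise(self):
        """>= 90% of pair relations recovered at loss 0.05 over 20 seeds."""
        total = 0
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_species=32, n_traits=8, n_gene_trees=0,
                loss_prob=0.05, retention_prob=0.9, n_nni=1, seed=seed)
            tree = simulate_species_tree(cfg.n_species, cfg.seed)
            matrix, truth = simulate_traits(tree, cfg)
            rep = build_order(tree, matrix)
            for pair, true_rel in truth.relations(tree).items():
                total += 1
                if rep.relations[pair] is true_rel:
                    hits += 1
        assert hits / total >= 0.9
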