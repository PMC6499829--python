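import numpy as np
import pytest

from cellphylo.trees import (
    Chronogram,
    NewickParseError,
    TreeError,
    TreeSample,
    parse_newick,
    write_newick,
)

from conftest import random_tree_newick


class TestParseWrite:
    def test_basic_structure(self, tree3):
        assert sorted(tree3.tip_labels) == ["A", "B", "C"]
        assert tree3.tree_height() == pytest.approx(2.0)
        assert tree3.is_ultrametric(1e-6)

    def test_round_trip_topology_and_lengths(self, tree3):
        again = parse_newick(write_newick(tree3))
        assert again.tip_set == tree3.tip_set
        for pair in [("A", "B"), ("A", "C"), ("B", "C")]:
            d1 = _tip_distance(tree3, *pair)
            d2 = _tip_distance(again, *pair)
            assert d2 == pytest.approx(d1, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        t = parse_newick(random_tree_newick(rng, int(rng.integers(4, 10))))
        u = parse_newick(write_newick(t))
        labels = sorted(t.tip_labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert _tip_distance(u, a, b) == pytest.approx(
                    _tip_distance(t, a, b), abs=1e-9
                )

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_missing_lengths_rejected(self):
        with pytest.raises(NewickParseError, match="length"):
            parse_newick("((A:1,B):1,C:2);")

    def test_topology_parse_without_lengths(self):
        t = parse_newick("((A,B),C);", require_lengths=False)
        assert t.n_tips == 3


class TestMrca:
    def test_pair(self, tree3):
        node = tree3.mrca({"A", "B"})
        assert not tree3.is_tip(node)
        assert tree3.clade_tips(node) == {"A", "B"}

    def test_spanning_pair_is_root(self, tree3):
        assert tree3.mrca({"A", "C"}) == tree3.root

    def test_single_taxon_is_tip(self, tree3):
        assert tree3.mrca({"A"}) == tree3.tip_node("A")

    def test_unknown_taxon(self, tree3):
        with pytest.raises(TreeError, match="unknown taxon"):
            tree3.mrca({"A", "Z"})


class TestScaleBranches:
    def test_target_mean(self, tree3):
        s = tree3.scale_branches(0.1)
        mask = np.arange(s.n_nodes) != s.root
        assert s.edge_length[mask].mean() == pytest.approx(0.1, abs=1e-12)

    def test_two_branch_arithmetic(self):
        t = parse_newick("(A:0.2,B:0.4);")
        s = t.scale_branches(0.1)
        got = sorted(s.edge_length[i] for i in s.tips)
        assert got == pytest.approx([0.2 / 3, 0.4 / 3], abs=1e-12)

    def test_identity_when_already_at_target(self, tree3):
        s = tree3.scale_branches(0.1)
        again = s.scale_branches(0.1)
        np.testing.assert_allclose(again.edge_length, s.edge_length, atol=1e-15)

    def test_ratios_preserved(self, tree5):
        s = tree5.scale_branches(0.37)
        mask = np.arange(tree5.n_nodes) != tree5.root
        r = s.edge_length[mask] / tree5.edge_length[mask]
        assert np.ptp(r) < 1e-12

    def test_all_zero_degenerate(self):
        t = parse_newick("(A:0,B:0);")
        with pytest.raises(TreeError, match="zero"):
            t.scale_branches(0.1)


class TestPrune:
    def test_path_length_conservation(self, tree3):
        p = tree3.prune_to_taxa({"A", "C"})
        assert p.n_tips == 2
        assert _tip_distance(p, "A", "C") == pytest.approx(4.0, abs=1e-9)

    def test_keep_all_is_identity(self, tree5):
        p = tree5.prune_to_taxa(set(tree5.tip_labels))
        labels = sorted(tree5.tip_labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert _tip_distance(p, a, b) == pytest.approx(
                    _tip_distance(tree5, a, b), abs=1e-9
                )

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_distances_preserved(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = parse_newick(random_tree_newick(rng, 8))
        keep = sorted(rng.choice(sorted(t.tip_labels), 4, replace=False))
        p = t.prune_to_taxa(keep)
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                assert _tip_distance(p, a, b) == pytest.approx(
                    _tip_distance(t, a, b), abs=1e-9
                )

    def test_one_per_class_gives_four_tips(self, tree_sample_small):
        from cellphylo.simulate import ONE_PER_CLASS

        p = tree_sample_small[0].prune_to_taxa(ONE_PER_CLASS)
        assert p.n_tips == 4
        assert p.is_ultrametric(1e-6)

    def test_too_few_taxa(self, tree3):
        with pytest.raises(TreeError, match="at least 2"):
            tree3.prune_to_taxa({"A"})


class TestTreeSample:
    def test_file_round_trip(self, tmp_path, tree_sample_small):
        path = tmp_path / "trees.nwk"
        sub = TreeSample(tree_sample_small.trees[:5], provenance="sampled")
        sub.write_newick_file(path)
        back = TreeSample.read_newick_file(path)
        assert len(back) == 5
        assert back.provenance == "file"
        assert back.tip_set == sub.tip_set
        np.testing.assert_allclose(
            sorted(back[0].edge_length), sorted(sub[0].edge_length), rtol=1e-9
        )

    def test_mismatched_tip_sets_rejected(self, tree3, tree5):
        with pytest.raises(TreeError, match="tip set"):
            TreeSample([tree3, tree5])

    def test_nexus_trees_block_with_translate(self, tmp_path):
        text = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS A B C; END;
BEGIN TREES;
    TRANSLATE 1 A, 2 B, 3 C;
    TREE t1 = ((1:1,2:1):1,3:2);
    TREE t2 = ((1:2,2:2):1,3:3);
END;
"""
        path = tmp_path / "trees.nex"
        path.write_text(text)
        sample = TreeSample.read_nexus(path)
        assert len(sample) == 2
        assert sample.tip_set == {"A", "B", "C"}
        assert _tip_distance(sample[0], "A", "B") == pytest.approx(2.0)


def _tip_distance(tree: Chronogram, a: str, b: str) -> float:
    d = tree.node_depths()
    anc = tree.mrca({a, b})
    return float(d[tree.tip_node(a)] + d[tree.tip_node(b)] - 2 * d[anc])
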