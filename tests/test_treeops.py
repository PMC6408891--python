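"""Gene-tree parsing, expansion detection, subtree extraction, divergence."""

import numpy as np
import pytest

from expanscan.treeops import (
    DivergenceSummary,
    ExpansionGroup,
    LabelScheme,
    TreeError,
    extract_group_subtree,
    find_lineage_expansions,
    parse_newick,
    patristic_divergence_summary,
)
from conftest import brute_force_expansions, random_newick


class TestParseNewick:
    def test_reads_support_and_lengths(self):
        t = parse_newick("((A_g1:0.1,A_g2:0.1)0.9:0.2,B_g1:0.3);")
        assert sorted(t.leaf_labels()) == ["A_g1", "A_g2", "B_g1"]
        supports = [
            nd.label for nd in t.tree.postorder_node_iter() if not nd.is_leaf()
        ]
        assert "0.9" in supports

    def test_missing_lengths_stay_missing(self):
        t = parse_newick("((A_g1,A_g2),B_g1);")
        lengths = {nd.edge.length for nd in t.tree.postorder_node_iter()}
        assert lengths == {None}

    def test_round_trip_preserves_topology_and_lengths(self, rng):
        nwk, _ = random_newick(rng, 20)
        t1 = parse_newick(nwk)
        t2 = parse_newick(t1.to_newick())

        def clades(t):
            return {
                frozenset(lf.taxon.label for lf in nd.leaf_iter())
                for nd in t.tree.postorder_node_iter()
            }

        assert clades(t1) == clades(t2)
        l1 = sorted(nd.edge.length for nd in t1.tree.postorder_node_iter() if nd.edge.length)
        l2 = sorted(nd.edge.length for nd in t2.tree.postorder_node_iter() if nd.edge.length)
        assert np.allclose(l1, l2)

    def test_malformed_newick_raises(self):
        with pytest.raises(TreeError, match="malformed"):
            parse_newick("((A_g1:0.1,A_g2:0.1")

    def test_label_scheme_violations_listed(self):
        scheme = LabelScheme(pattern=r"(?P<species>[A-Z]+)-(?P<gene>\d+)$")
        with pytest.raises(TreeError, match="bad!label"):
            parse_newick("((AB-1:0.1,AB-2:0.1):0.1,(CD-3:0.1,bad!label:0.2):0.1);", scheme)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(TreeError, match="leaves"):
            parse_newick("(A_g1:0.1,B_g1:0.2);")

    def test_support_outside_unit_interval_rejected(self):
        with pytest.raises(TreeError, match="support"):
            parse_newick("((A_g1:0.1,A_g2:0.1)1.5:0.2,B_g1:0.3);")


class TestFindLineageExpansions:
    TREE = "(((c1_a:0.1,c1_b:0.1)0.9:0.1,(c2_a:0.1,c2_b:0.1)0.9:0.1)0.95:0.2,(x1_a:0.1,x2_a:0.1)0.8:0.2);"

    def test_detects_maximal_focal_clade(self):
        t = parse_newick(self.TREE)
        groups = find_lineage_expansions(t, {"c1", "c2"}, cutoff=3)
        assert len(groups) == 1
        assert groups[0].size == 4
        assert set(groups[0].member_genes) == {"c1_a", "c1_b", "c2_a", "c2_b"}
        assert groups[0].support == 0.95

    def test_cutoff_boundary_empties_result(self):
        t = parse_newick(self.TREE)
        assert find_lineage_expansions(t, {"c1", "c2"}, cutoff=5) == []

    def test_no_focal_leaves_gives_empty_list(self):
        t = parse_newick(self.TREE)
        assert find_lineage_expansions(t, {"zz"}, cutoff=2) == []

    def test_cutoff_below_two_rejected(self):
        t = parse_newick(self.TREE)
        with pytest.raises(ValueError, match="cutoff"):
            find_lineage_expansions(t, {"c1"}, cutoff=1)

    def test_all_focal_returns_degenerate_root(self):
        t = parse_newick(self.TREE)
        with pytest.warns(UserWarning, match="focal"):
            groups = find_lineage_expansions(t, {"c1", "c2", "x1", "x2"}, cutoff=2)
        assert len(groups) == 1
        assert groups[0].degenerate_root
        assert groups[0].size == 6

    def test_support_filter_drops_weak_nodes(self):
        t = parse_newick(self.TREE)
        assert find_lineage_expansions(t, {"c1", "c2"}, cutoff=3, min_support=0.99) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            nwk, focal = random_newick(rng, int(rng.integers(8, 64)))
            t = parse_newick(nwk)
            cutoff = int(rng.integers(2, 6))
            got = find_lineage_expansions(t, focal, cutoff=cutoff)
            want = brute_force_expansions(t, focal, cutoff)
            assert sorted(
                (frozenset(g.member_genes) for g in got),
                key=lambda s: (-len(s), sorted(s)),
            ) == want

    def test_no_returned_group_nested_in_another(self, rng):
        for _ in range(30):
            nwk, focal = random_newick(rng, 48)
            groups = find_lineage_expansions(parse_newick(nwk), focal, cutoff=2)
            sets = [set(g.member_genes) for g in groups]
            for i, a in enumerate(sets):
                for j, b in enumerate(sets):
                    assert i == j or not a < b

    def test_monotone_in_cutoff_and_support(self, rng):
        for _ in range(20):
            nwk, focal = random_newick(rng, 40)
            t = parse_newick(nwk)
            lo = {frozenset(g.member_genes) for g in find_lineage_expansions(t, focal, 2)}
            hi = {frozenset(g.member_genes) for g in find_lineage_expansions(t, focal, 4)}
            assert hi <= lo
            weak = find_lineage_expansions(t, focal, 2, min_support=0.2)
            strong = find_lineage_expansions(t, focal, 2, min_support=0.8)
            assert {frozenset(g.member_genes) for g in strong} <= {
                frozenset(g.member_genes) for g in weak
            }

    def test_recovers_planted_clades(self):
        from expanscan.synthetic_data import CEPHALOPODS, TreeSpec, simulate_gene_tree

        tp = fp = fn = 0
        for seed in range(12):
            gtree, truth = simulate_gene_tree(TreeSpec(), seed=seed)
            planted = {frozenset(t["members"]) for t in truth}
            found = {
                frozenset(g.member_genes)
                for g in find_lineage_expansions(gtree, set(CEPHALOPODS), cutoff=10)
            }
            tp += len(planted & found)
            fp += len(found - planted)
            fn += len(planted - found)
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95


class TestExtractGroupSubtree:
    def test_supported_sister_accepted(self):
        t = parse_newick("(((c1_a:0.1,c1_b:0.1)0.95:0.1,x1_a:0.2)0.9:0.1,x2_a:0.3);")
        [g] = find_lineage_expansions(t, {"c1"}, cutoff=2)
        sub = extract_group_subtree(t, g, min_support=0.7)
        assert sorted(sub.leaf_labels()) == ["c1_a", "c1_b", "x1_a"]
        assert sorted(g.sister_genes) == ["x1_a"]

    def test_weak_sister_walks_rootward(self):
        t = parse_newick("(((c1_a:0.1,c1_b:0.1)0.95:0.1,x1_a:0.2)0.5:0.1,x2_a:0.3);")
        [g] = find_lineage_expansions(t, {"c1"}, cutoff=2)
        with pytest.warns(UserWarning, match="root"):
            sub = extract_group_subtree(t, g, min_support=0.7)
        assert "x2_a" in sub.leaf_labels()

    def test_zero_threshold_accepts_immediate_sister(self):
        t = parse_newick("(((c1_a:0.1,c1_b:0.1)0.95:0.1,x1_a:0.2):0.1,x2_a:0.3);")
        [g] = find_lineage_expansions(t, {"c1"}, cutoff=2)
        sub = extract_group_subtree(t, g, min_support=0.0)
        assert sorted(sub.leaf_labels()) == ["c1_a", "c1_b", "x1_a"]

    def test_branch_lengths_preserved(self):
        t = parse_newick("(((c1_a:0.11,c1_b:0.12)0.95:0.13,x1_a:0.2)0.9:0.1,x2_a:0.3);")
        [g] = find_lineage_expansions(t, {"c1"}, cutoff=2)
        sub = extract_group_subtree(t, g, min_support=0.7)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in sub.tree.leaf_node_iter()
        }
        assert lengths["c1_a"] == pytest.approx(0.11)
        assert lengths["c1_b"] == pytest.approx(0.12)


class TestPatristicDivergence:
    def _group(self, t, focal, cutoff=2):
        [g] = find_lineage_expansions(t, focal, cutoff=cutoff)
        return g

    def test_chain_distance_is_path_sum(self):
        t = parse_newick("((A_g1:0.5,A_g2:0.5):0.5,X_g1:0.5);")
        g = self._group(t, {"A"})
        ds = patristic_divergence_summary(t, g, {"X"})
        # both members: 0.5 + 0.5 + 0.5 = 1.5 to the only reference leaf
        assert ds.median == ds.q1 == ds.q3 == pytest.approx(1.5)

    def test_single_member_collapses_quartiles(self):
        t = parse_newick("((A_g1:0.4,X_g2:0.3):0.2,X_g1:0.1);")
        g = ExpansionGroup(node_id=0, member_genes=["A_g1"], member_species={"A"},
                           size=1, support=None)
        ds = patristic_divergence_summary(t, g, {"X"})
        assert ds.q1 == ds.median == ds.q3 == pytest.approx(0.4 + 0.3)

    def test_zero_lengths_give_zero_distances(self):
        t = parse_newick("((A_g1:0.0,A_g2:0.0):0.0,X_g1:0.0);")
        g = self._group(t, {"A"})
        ds = patristic_divergence_summary(t, g, {"X"})
        assert ds.median == 0.0

    def test_missing_length_is_an_error(self):
        t = parse_newick("((A_g1:0.1,A_g2),X_g1:0.1);")
        g = self._group(t, {"A"})
        with pytest.raises(TreeError, match="branch length"):
            patristic_divergence_summary(t, g, {"X"})

    def test_distances_symmetric_and_triangle(self, rng):
        from expanscan.treeops import patristic_distance_matrix

        nwk, _ = random_newick(rng, 16)
        labels, d = patristic_distance_matrix(parse_newick(nwk))
        assert np.allclose(d, d.T)
        n = len(labels)
        for _ in range(60):
            i, j, k = rng.choice(n, size=3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_quartile_ordering_invariant(self):
        with pytest.raises(ValueError):
            DivergenceSummary(median=1.0, q1=2.0, q3=3.0, n=5)
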