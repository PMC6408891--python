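"""Scaffold occupancy and tandem-cluster detection."""

import numpy as np
import pandas as pd
import pytest

from expanscan.genloc import (
    GeneLocus,
    detect_tandem_clusters,
    read_loci,
    scaffold_summary,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["scaffold", "start", "stop", "strand", "gene", "group"])


def _brute_force_summary(loci, m):
    """Plain group-by counting, independent of the implementation."""
    df = pd.DataFrame(
        [(l.group, l.scaffold) for l in loci if l.group], columns=["group", "scaffold"]
    )
    out = {}
    for g, sub in df.groupby("group"):
        counts = sub["scaffold"].value_counts()
        out[g] = (len(counts), int((counts >= m).sum()))
    return out


class TestReadLoci:
    def test_reads_toy_table(self):
        loci = read_loci(_table([
            ("s1", 0, 100, "+", "g1", "A"),
            ("s1", 200, 250, "-", "g2", "A"),
            ("s2", 5, 60, "+", "g3", None),
        ]))
        assert len(loci) == 3
        assert loci[2].group is None

    def test_start_equal_stop_rejected(self):
        with pytest.raises(ValueError, match="start >= stop"):
            read_loci(_table([("s1", 100, 100, "+", "g1", "A")]))

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_loci(_table([
                ("s1", 0, 10, "+", "g1", "A"),
                ("s2", 0, 10, "+", "g1", "A"),
            ]))

    def test_one_based_conversion_preserves_length(self):
        [locus] = read_loci(_table([("s1", 11, 20, "+", "g1", "A")]), one_based=True)
        assert locus.start == 10
        assert locus.stop == 20
        assert locus.stop - locus.start == 10  # 1-based inclusive length 11..20

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneLocus("g", "s", 0, 10, "x")


class TestScaffoldSummary:
    def test_occupied_and_clustered_counts(self):
        loci = read_loci(_table([
            ("s1", 0, 10, "+", "a1", "A"),
            ("s1", 20, 30, "+", "a2", "A"),
            ("s1", 40, 50, "+", "a3", "A"),
            ("s2", 0, 10, "-", "a4", "A"),
        ]))
        s = scaffold_summary(loci, m=3)
        assert s.per_group["A"]["scaffolds_occupied"] == 2
        assert s.per_group["A"]["scaffolds_with_ge_m"] == 1

    def test_unknown_group_label_rejected(self):
        loci = read_loci(_table([("s1", 0, 10, "+", "a1", "A")]))
        with pytest.raises(ValueError, match="unknown"):
            scaffold_summary(loci, groups=["B"])

    def test_m_one_counts_every_occupied_scaffold(self):
        loci = read_loci(_table([
            ("s1", 0, 10, "+", "a1", "A"), ("s2", 0, 10, "+", "a2", "A"),
        ]))
        s = scaffold_summary(loci, m=1)
        assert s.per_group["A"]["scaffolds_with_ge_m"] == 2

    def test_matches_brute_force_on_random_layouts(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            rows = []
            for k in range(n):
                start = int(rng.integers(0, 10_000)) * 100
                rows.append((
                    f"s{rng.integers(1, 8)}", start, start + 50,
                    "+" if rng.random() < 0.5 else "-", f"g{k}",
                    f"G{rng.integers(3)}",
                ))
            loci = read_loci(_table(rows))
            m = int(rng.integers(1, 5))
            s = scaffold_summary(loci, m=m)
            for g, (occ, clus) in _brute_force_summary(loci, m).items():
                assert s.per_group[g]["scaffolds_occupied"] == occ
                assert s.per_group[g]["scaffolds_with_ge_m"] == clus


class TestTandemClusters:
    def _mk(self, positions, group_flags, scaffold="s1"):
        rows = []
        for k, (pos, is_member) in enumerate(zip(positions, group_flags)):
            rows.append((scaffold, pos, pos + 10, "+", f"g{k}",
                         "A" if is_member else None))
        return read_loci(_table(rows))

    def test_single_intervening_gene_bridged(self):
        # members at ranks 1, 2, 4 with one non-member between ranks 2 and 4
        loci = self._mk([100, 200, 300, 400], [True, True, False, True])
        [c] = detect_tandem_clusters(loci, "A", max_intervening=1)
        assert c.members == ["g0", "g1", "g3"]
        assert c.n_intervening == 1

    def test_members_on_different_scaffolds_never_cluster(self):
        rows = [("s1", 0, 10, "+", "a", "A"), ("s2", 0, 10, "+", "b", "A")]
        assert detect_tandem_clusters(read_loci(_table(rows)), "A") == []

    def test_zero_intervening_requires_adjacency(self):
        loci = self._mk([100, 200, 300, 400], [True, True, False, True])
        [c] = detect_tandem_clusters(loci, "A", max_intervening=0)
        assert c.members == ["g0", "g1"]

    def test_count_monotone_in_max_intervening(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            loci = self._mk(
                [100 * (k + 1) for k in range(n)],
                [bool(rng.random() < 0.4) for _ in range(n)],
            )
            sizes = [
                sum(c.size for c in detect_tandem_clusters(loci, "A", max_intervening=mi))
                for mi in (0, 2, 5)
            ]
            assert sizes == sorted(sizes)

    def test_clusters_disjoint_and_from_group(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            loci = self._mk(
                [100 * (k + 1) for k in range(n)],
                [bool(rng.random() < 0.5) for _ in range(n)],
            )
            clusters = detect_tandem_clusters(loci, "A", max_intervening=2)
            seen = set()
            members = {l.gene for l in loci if l.group == "A"}
            for c in clusters:
                assert set(c.members) <= members
                assert not (set(c.members) & seen)
                seen |= set(c.members)

    def test_distance_fallback_without_background(self):
        rows = [
            ("s1", 0, 1_000, "+", "a", "A"),
            ("s1", 5_000, 6_000, "+", "b", "A"),
            ("s1", 500_000, 501_000, "+", "c", "A"),
        ]
        [c] = detect_tandem_clusters(read_loci(_table(rows)), "A", max_gap_bp=100_000)
        assert c.members == ["a", "b"]

    def test_recovers_planted_arrays(self):
        from expanscan.synthetic_data import ScaffoldSpec, simulate_scaffolds

        recovered = total = 0
        for seed in range(30):
            genes = [f"g{i}" for i in range(40)]
            assign = {g: "group1" for g in genes[:12]}
            loci_df, truth = simulate_scaffolds(
                genes, assign, ScaffoldSpec(n_scaffolds=20, array_sizes=((4, 3),)),
                seed=seed,
            )
            clusters = detect_tandem_clusters(read_loci(loci_df), "group1",
                                              max_intervening=5)
            found = {frozenset(c.members) for c in clusters}
            for t in truth:
                total += 1
                recovered += frozenset(t["members"]) in found
        assert recovered / total >= 0.95
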