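from itertools import product

import networkx as nx
import numpy as np
import pytest

from palindromekit import synth
from palindromekit.clusters import (
    ArmFilterRules,
    PalindromeCluster,
    arm_alignments_all_pairs,
    build_links,
    filter_arm_alignment,
    sharing_summary,
    transitive_closure,
)
from palindromekit.align import reverse_complement
from palindromekit.palindromes import Palindrome
from palindromekit.seqio import AlignmentRecord, GenomicInterval, SequenceRecord

from oracles import subset_sharing_counts


def _aln(identity, gaps, matched, cov_q, cov_t, qchrom="q", tchrom="t"):
    return AlignmentRecord(
        query=GenomicInterval(qchrom, 0, max(matched, 10_000)),
        target=GenomicInterval(tchrom, 0, max(matched, 10_000)),
        orientation="direct",
        identity_pct=identity, gap_pct=gaps, matched_bases=matched,
        query_coverage_pct=cov_q, target_coverage_pct=cov_t,
    )


class TestArmFilter:
    @pytest.mark.parametrize("identity,gaps,matched,cov,expect", [
        (84.9, 1.0, 9_000, 90.0, False),   # identity < 85
        (95.0, 6.0, 9_000, 90.0, False),   # gaps > 5
        (95.0, 1.0, 499, 90.0, False),     # matched < 500
        (95.0, 1.0, 9_000, 39.9, False),   # coverage < 40
        (85.0, 5.0, 500, 40.0, True),      # all boundaries kept
        (99.0, 1.0, 9_000, 95.0, True),
    ])
    def test_rules(self, identity, gaps, matched, cov, expect):
        assert filter_arm_alignment(_aln(identity, gaps, matched, cov, cov)) is expect

    def test_all_16_boundary_combinations(self):
        """Each rule independently strict: on-boundary passes, off fails."""
        vals = {
            "identity": (85.0, 84.999),
            "gaps": (5.0, 5.001),
            "matched": (500, 499),
            "cov": (40.0, 39.999),
        }
        for bits in product((0, 1), repeat=4):
            identity = vals["identity"][bits[0]]
            gaps = vals["gaps"][bits[1]]
            matched = vals["matched"][bits[2]]
            cov = vals["cov"][bits[3]]
            expect = bits == (0, 0, 0, 0)
            assert filter_arm_alignment(_aln(identity, gaps, matched, cov, cov)) is expect

    def test_either_arm_coverage_counts(self):
        assert filter_arm_alignment(_aln(95, 1, 9_000, 90.0, 39.0)) is False
        assert filter_arm_alignment(_aln(95, 1, 9_000, 39.0, 90.0)) is False


def _pal(chrom, pid, a1s=0, arm=10_000, spacer=1_000):
    a1e = a1s + arm
    a2s, a2e = a1e + spacer, a1e + spacer + arm
    return Palindrome(pid, chrom, GenomicInterval(chrom, a1s, a1e),
                      GenomicInterval(chrom, a2s, a2e),
                      GenomicInterval(chrom, a1e, a2s), 99.0, 0.0)


class TestBuildLinks:
    def test_surviving_alignment_makes_one_edge(self):
        pals = {"hs": [_pal("hs.chrY", "P1")], "pt": [_pal("pt.chrY", "P1")]}
        aln = AlignmentRecord(
            query=GenomicInterval("hs.chrY", 0, 10_000),
            target=GenomicInterval("pt.chrY", 0, 10_000),
            orientation="direct", identity_pct=99.0, gap_pct=1.0,
            matched_bases=9_500, query_coverage_pct=95.0, target_coverage_pct=95.0)
        edges = build_links(pals, [aln])
        assert edges == {frozenset({("hs", "P1"), ("pt", "P1")})}

    def test_self_alignment_makes_no_edge(self):
        pals = {"hs": [_pal("hs.chrY", "P1")]}
        aln = AlignmentRecord(
            query=GenomicInterval("hs.chrY", 0, 10_000),
            target=GenomicInterval("hs.chrY", 11_000, 21_000),
            orientation="inverted", identity_pct=99.0, gap_pct=1.0,
            matched_bases=9_500, query_coverage_pct=95.0, target_coverage_pct=95.0)
        assert build_links(pals, [aln]) == set()

    def test_unknown_arm_is_error(self):
        pals = {"hs": [_pal("hs.chrY", "P1")]}
        aln = AlignmentRecord(
            query=GenomicInterval("hs.chrY", 500_000, 510_000),
            target=GenomicInterval("hs.chrY", 0, 10_000),
            orientation="direct", identity_pct=99.0, gap_pct=1.0,
            matched_bases=9_500, query_coverage_pct=95.0, target_coverage_pct=95.0)
        with pytest.raises(ValueError, match="does not match any known arm"):
            build_links(pals, [aln])

    def test_filtered_alignment_makes_no_edge(self):
        pals = {"hs": [_pal("hs.chrY", "P1")], "pt": [_pal("pt.chrY", "P1")]}
        aln = AlignmentRecord(
            query=GenomicInterval("hs.chrY", 0, 10_000),
            target=GenomicInterval("pt.chrY", 0, 10_000),
            orientation="direct", identity_pct=80.0, gap_pct=1.0,
            matched_bases=8_000, query_coverage_pct=80.0, target_coverage_pct=80.0)
        assert build_links(pals, [aln]) == set()

    def test_planted_homology_groups_match_bruteforce_arm_alignment(self, rng):
        """Palindromes seeded from shared vs distinct ancestors link exactly
        within their planted groups under all-pairs arm alignment."""
        n_groups, per_group = 4, 3
        pals_by_species = {}
        seqs = {}
        ancestors = [synth.random_sequence(3_000, rng) for _ in range(n_groups)]
        for g in range(n_groups):
            for i in range(per_group):
                species = f"sp{g}_{i}"
                chrom = f"{species}.chr"
                arm = synth.mutate(ancestors[g], 0.05, rng=rng)
                seq = arm + synth.random_sequence(500, rng) + reverse_complement(arm)
                seqs[chrom] = SequenceRecord(chrom, seq)
                pals_by_species[species] = [Palindrome(
                    "P1", chrom,
                    GenomicInterval(chrom, 0, len(arm)),
                    GenomicInterval(chrom, len(arm) + 500, len(seq)),
                    GenomicInterval(chrom, len(arm), len(arm) + 500),
                    99.0, 0.0)]
        alns = arm_alignments_all_pairs(pals_by_species, seqs)
        edges = build_links(pals_by_species, alns)
        for e in edges:
            (sa, _), (sb, _) = tuple(e)
            assert sa.split("_")[0] == sb.split("_")[0], "cross-group edge"
        # every within-group pair linked
        expected_edges = n_groups * (per_group * (per_group - 1) // 2)
        assert len(edges) == expected_edges


class TestTransitiveClosure:
    def test_chain_rule(self):
        nodes = [("s", "A"), ("s", "B"), ("s", "C")]
        edges = [(("s", "A"), ("s", "B")), (("s", "B"), ("s", "C"))]
        clusters = transitive_closure(nodes, edges)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(nodes)

    def test_no_edges_gives_singletons(self):
        nodes = [("s", "A"), ("s", "B")]
        clusters = transitive_closure(nodes, [])
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def test_partition_property(self, rng):
        nodes = [("s", f"P{i}") for i in range(50)]
        edges = [tuple(rng.choice(50, 2, replace=False)) for _ in range(40)]
        edges = [(nodes[a], nodes[b]) for a, b in edges]
        clusters = transitive_closure(nodes, edges)
        union = set()
        for c in clusters:
            assert not (union & c.members)
            union |= c.members
        assert union == set(nodes)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bfs_components_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        nodes = [("s", f"P{i}") for i in range(n)]
        g = nx.gnp_random_graph(n, 0.02, seed=seed)
        edges = [(nodes[a], nodes[b]) for a, b in g.edges]
        clusters = transitive_closure(nodes, edges)
        got = {frozenset(c.members) for c in clusters}
        expect = {frozenset(nodes[i] for i in comp)
                  for comp in nx.connected_components(g)}
        assert got == expect

    def test_edge_addition_never_increases_cluster_count(self, rng):
        nodes = [("s", f"P{i}") for i in range(30)]
        edges = []
        last = len(transitive_closure(nodes, edges))
        for _ in range(25):
            a, b = rng.choice(30, 2, replace=False)
            edges.append((nodes[a], nodes[b]))
            now = len(transitive_closure(nodes, edges))
            assert now <= last
            last = now


class TestSharingSummary:
    def _cluster(self, species):
        members = frozenset((sp, f"P_{sp}") for sp in species)
        return PalindromeCluster(id=min(f"{sp}:P_{sp}" for sp in species),
                                 members=members)

    def test_exact_group(self):
        c = self._cluster({"human", "chimpanzee", "bonobo"})
        counts, exact = sharing_summary(
            [c], {"african": {"human", "chimpanzee", "bonobo"}})
        assert counts == {"african": 1}
        assert exact[frozenset({"human", "chimpanzee", "bonobo"})] == 1

    def test_empty_clusters_all_zero(self):
        counts, exact = sharing_summary([], {"g": {"a", "b"}})
        assert counts == {"g": 0} and not exact

    def test_unknown_species_rejected(self):
        c = self._cluster({"human"})
        with pytest.raises(ValueError, match="unknown species"):
            sharing_summary([c], {"g": {"martian"}})

    def test_matches_bruteforce_on_random_clusters(self, rng):
        species = [f"sp{i}" for i in range(6)]
        clusters = []
        for i in range(100):
            k = int(rng.integers(1, 7))
            chosen = list(rng.choice(species, size=k, replace=False))
            members = frozenset((sp, f"P{i}") for sp in chosen)
            clusters.append(PalindromeCluster(id=f"c{i}", members=members))
        groups = {f"g{j}": set(rng.choice(species, size=int(rng.integers(1, 5)),
                                          replace=False))
                  for j in range(10)}
        got, _ = sharing_summary(clusters, groups)
        assert got == subset_sharing_counts(clusters, groups)

    def test_monotone_in_group_growth(self, rng):
        clusters = [self._cluster(set(np.random.default_rng(i).choice(
            ["a", "b", "c", "d"], size=1 + i % 4, replace=False))) for i in range(30)]
        prev = None
        group: set = set()
        for sp in ["a", "b", "c", "d"]:
            group = group | {sp}
            counts, _ = sharing_summary(clusters, {"g": group})
            if prev is not None:
                assert counts["g"] <= prev
            prev = counts["g"]
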