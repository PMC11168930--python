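"""Grouping palindromes within and across species.

Arm-to-arm alignments are filtered (identity < 85%, gaps > 5%, fewer than
500 matched bases, or < 40% coverage of either arm are discarded; exact
boundary values survive), surviving alignments become edges between the
palindromes owning the arms, and clusters are the transitive closure of
those edges.  Sharing summaries count clusters spanning named species
groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .align import align_pair, reverse_complement
from .palindromes import Palindrome
from .seqio import INVERTED, AlignmentRecord, GenomicInterval, SequenceRecord

Node = tuple[str, str]  # (species, palindrome id)


@dataclass
class ArmFilterRules:
    min_identity_pct: float = 85.0
    max_gap_pct: float = 5.0
    min_matched_bases: int = 500
    min_arm_coverage_pct: float = 40.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity_pct <= 100 and 0 <= self.max_gap_pct <= 100
                and 0 <= self.min_arm_coverage_pct <= 100 and self.min_matched_bases >= 0):
            raise ValueError("filter rule out of range")


@dataclass
class PalindromeCluster:
    id: str
    members: frozenset[Node]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster cannot be empty")

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.members)


def filter_arm_alignment(alignment: AlignmentRecord, rules: ArmFilterRules | None = None) -> bool:
    """True when the alignment survives all four discard rules.

    Discard conditions are strict (<85%, >5%, <500, <40%), so boundary
    values are kept.
    """
    rules = rules or ArmFilterRules()
    if alignment.identity_pct < rules.min_identity_pct:
        return False
    if alignment.gap_pct > rules.max_gap_pct:
        return False
    if alignment.matched_bases < rules.min_matched_bases:
        return False
    if min(alignment.query_coverage_pct, alignment.target_coverage_pct) < rules.min_arm_coverage_pct:
        return False
    return True


def _arm_index(
    palindromes_by_species: Mapping[str, Sequence[Palindrome]],
) -> tuple[dict[str, str], dict[str, list[tuple[GenomicInterval, Node]]]]:
    """chrom -> species map plus chrom -> [(arm interval, owning node)]."""
    chrom_species: dict[str, str] = {}
    arms: dict[str, list[tuple[GenomicInterval, Node]]] = {}
    for species, pals in palindromes_by_species.items():
        for p in pals:
            prev = chrom_species.get(p.chrom)
            if prev is not None and prev != species:
                raise ValueError(
                    f"chromosome {p.chrom!r} appears in species {prev!r} and {species!r}; "
                    "chromosome ids must be unique across species"
                )
            chrom_species[p.chrom] = species
            node: Node = (species, p.id)
            arms.setdefault(p.chrom, []).extend([(p.arm1, node), (p.arm2, node)])
    return chrom_species, arms


def _owner_of(
    interval: GenomicInterval,
    arms: Mapping[str, list[tuple[GenomicInterval, Node]]],
) -> Node:
    best: Node | None = None
    best_ov = 0
    for arm, node in arms.get(interval.chrom, []):
        ov = interval.overlap_len(arm)
        if ov > best_ov:
            best_ov, best = ov, node
    if best is None or best_ov < len(interval) // 2:
        raise ValueError(f"alignment interval {interval} does not match any known arm")
    return best


def build_links(
    palindromes_by_species: Mapping[str, Sequence[Palindrome]],
    alignments: Sequence[AlignmentRecord],
    rules: ArmFilterRules | None = None,
) -> set[frozenset[Node]]:
    """Edges between palindromes connected by a surviving arm alignment.

    One surviving alignment in either orientation suffices; self-edges are
    dropped.  Alignment intervals must land on known arms (>= half the
    aligned interval), otherwise an error is raised.
    """
    rules = rules or ArmFilterRules()
    _, arms = _arm_index(palindromes_by_species)
    edges: set[frozenset[Node]] = set()
    for aln in alignments:
        p = _owner_of(aln.query, arms)
        q = _owner_of(aln.target, arms)
        if p == q:
            continue
        if filter_arm_alignment(aln, rules):
            edges.add(frozenset((p, q)))
    return edges


def arm_alignments_all_pairs(
    palindromes_by_species: Mapping[str, Sequence[Palindrome]],
    sequences: Mapping[str, SequenceRecord],
) -> list[AlignmentRecord]:
    """Brute-force all-vs-all arm alignments (both orientations' best).

    Convenience generator of the edge evidence for small palindrome sets;
    for real data, import lastz-style tables via seqio instead.
    """
    items: list[tuple[Node, GenomicInterval, str]] = []
    for species, pals in palindromes_by_species.items():
        for p in pals:
            seq = sequences[p.chrom].residues
            for arm in (p.arm1, p.arm2):
                items.append(((species, p.id), arm, seq[arm.start:arm.end]))
    out: list[AlignmentRecord] = []
    for (na, iva, sa), (nb, ivb, sb) in combinations(items, 2):
        if na == nb:
            continue
        direct = align_pair(sa, sb)
        inv = align_pair(sa, reverse_complement(sb))
        best = direct if direct.identity_pct >= inv.identity_pct else inv
        out.append(AlignmentRecord(
            query=iva, target=ivb,
            orientation="direct" if best is direct else INVERTED,
            identity_pct=best.identity_pct,
            gap_pct=best.gap_pct,
            matched_bases=best.matched_bases,
            query_coverage_pct=100.0,
            target_coverage_pct=100.0,
        ))
    return out


def transitive_closure(
    nodes: Sequence[Node], edges: Sequence[frozenset[Node] | tuple[Node, Node]]
) -> list[PalindromeCluster]:
    """Connected components of the palindrome link graph (union-find).

    If pairs A–B and B–C are linked, A, B and C form one cluster;
    singletons are kept as their own clusters.  Cluster ids are the
    lexicographically smallest member, formatted "species:palindrome".
    """
    parent: dict[Node, Node] = {n: n for n in nodes}

    def find(a: Node) -> Node:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in edges:
        pair = tuple(e)
        if len(pair) == 1:
            continue
        a, b = pair[0], pair[1]
        if a not in parent or b not in parent:
            raise ValueError(f"edge {e} references unknown node")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[Node, set[Node]] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    clusters = []
    for members in groups.values():
        smallest = min(members)
        clusters.append(PalindromeCluster(
            id=f"{smallest[0]}:{smallest[1]}", members=frozenset(members)
        ))
    clusters.sort(key=lambda c: c.id)
    return clusters


def sharing_summary(
    clusters: Sequence[PalindromeCluster],
    species_groups: Mapping[str, set[str]] | None = None,
) -> tuple[dict[str, int], Counter]:
    """Cluster sharing across species.

    Returns (per-group counts of clusters whose species set contains the
    whole group, per-exact-combination counts keyed by frozenset of
    species).
    """
    known = set()
    for c in clusters:
        known |= c.species_set
    group_counts: dict[str, int] = {}
    if species_groups:
        for name, group in species_groups.items():
            unknown = set(group) - known
            if unknown and clusters:
                raise ValueError(f"group {name!r} names unknown species: {sorted(unknown)}")
            group_counts[name] = sum(1 for c in clusters if set(group) <= c.species_set)
    exact = Counter(c.species_set for c in clusters)
    return group_counts, exact


def write_cluster_table(clusters: Sequence[PalindromeCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tspecies\tpalindrome_id\n")
        for c in clusters:
            for species, pid in sorted(c.members):
                fh.write(f"{c.id}\t{species}\t{pid}\n")
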