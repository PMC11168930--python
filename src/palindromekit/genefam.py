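"""Multi-copy and ampliconic gene-family calling, plus gene density.

Homology between proteins is a best local alignment with >= 50% identity
covering >= 35% of both protein lengths; families are single-linkage
components of the homology graph, kept only when some within-species
pair is itself homologous; a family is ampliconic when at least two
copies within one species reach 97% protein identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.stats import chisquare

from .seqio import GenomicInterval, RepeatTrack
from .stats import bonferroni

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene: str
    species: str
    chrom: str
    locus: GenomicInterval | None
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.protein_id!r} has empty residues")
        bad = set(self.residues.upper()) - _AA
        if bad:
            raise ValueError(f"protein {self.protein_id!r}: non-amino-acid {sorted(bad)}")


@dataclass(frozen=True)
class HomologyEdge:
    protein_a: str
    protein_b: str
    identity_pct: float
    aligned_fraction_a: float
    aligned_fraction_b: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError("self-edge")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


@dataclass
class GeneFamily:
    id: str
    members: list[ProteinRecord]
    max_within_species_identity_pct: float
    ampliconic: bool = False

    @property
    def copy_numbers(self) -> Counter:
        return Counter(m.species for m in self.members)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def local_alignment_metrics(a: str, b: str, aligner: PairwiseAligner | None = None
                            ) -> tuple[float, float, float]:
    """(identity_pct, aligned_fraction_a, aligned_fraction_b) of the best
    local alignment.  Identity counts matches over all alignment columns;
    the aligned region of each protein is the span from the first to the
    last aligned residue."""
    aligner = aligner or _make_aligner()
    alns = aligner.align(a.upper(), b.upper())
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alns[0]
    blocks_a, blocks_b = aln.aligned
    matches = sum(
        1
        for (as_, ae), (bs, _) in zip(blocks_a, blocks_b)
        for off in range(ae - as_)
        if a[as_ + off].upper() == b[bs + off].upper()
    )
    sa, ea = int(blocks_a[0][0]), int(blocks_a[-1][1])
    sb, eb = int(blocks_b[0][0]), int(blocks_b[-1][1])
    # columns = aligned residue columns + internal gap columns on each side
    consumed = sum(int(e) - int(s) for s, e in blocks_a)  # == consumed on b
    columns = consumed + ((ea - sa) - consumed) + ((eb - sb) - consumed)
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, (ea - sa) / len(a), (eb - sb) / len(b)


def protein_homology_edges(
    proteins: Sequence[ProteinRecord],
    min_identity_pct: float = 50.0,
    min_aligned_fraction: float = 0.35,
) -> list[HomologyEdge]:
    """All-vs-all homology edges under the 50%-identity / 35%-of-both-
    lengths criterion."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    aligner = _make_aligner()
    edges: list[HomologyEdge] = []
    for pa, pb in combinations(proteins, 2):
        ident, fa, fb = local_alignment_metrics(pa.residues, pb.residues, aligner)
        if ident >= min_identity_pct and min(fa, fb) >= min_aligned_fraction:
            edges.append(HomologyEdge(pa.protein_id, pb.protein_id, ident, fa, fb))
    return edges


def cluster_families(
    proteins: Sequence[ProteinRecord], edges: Sequence[HomologyEdge]
) -> list[GeneFamily]:
    """Single-linkage families, refined.

    Connected components of the homology graph with >= 2 members;
    components whose edges are all cross-species (no within-species pair
    passes the homology criterion) are removed; singletons never
    reported.  Family id is the lexicographically smallest member id.
    """
    by_id = {p.protein_id: p for p in proteins}
    parent = {pid: pid for pid in by_id}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e in edges:
        if e.protein_a not in by_id or e.protein_b not in by_id:
            raise ValueError(f"edge references unknown protein: {e.protein_a}/{e.protein_b}")
        ra, rb = find(e.protein_a), find(e.protein_b)
        if ra != rb:
            parent[rb] = ra

    comps: dict[str, list[str]] = {}
    for pid in by_id:
        comps.setdefault(find(pid), []).append(pid)

    within_identity: dict[str, float] = {}
    has_within: dict[str, bool] = {}
    for e in edges:
        root = find(e.protein_a)
        if by_id[e.protein_a].species == by_id[e.protein_b].species:
            has_within[root] = True
            within_identity[root] = max(within_identity.get(root, 0.0), e.identity_pct)

    families: list[GeneFamily] = []
    for root, pids in comps.items():
        if len(pids) < 2 or not has_within.get(root, False):
            continue
        members = sorted((by_id[p] for p in pids), key=lambda m: m.protein_id)
        families.append(GeneFamily(
            id=min(pids),
            members=members,
            max_within_species_identity_pct=within_identity.get(root, 0.0),
        ))
    families.sort(key=lambda f: f.id)
    return families


def call_ampliconic(families: Sequence[GeneFamily], min_identity_pct: float = 97.0
                    ) -> list[GeneFamily]:
    """Flag families with >= min_identity_pct protein identity between at
    least two copies within one species."""
    for f in families:
        f.ampliconic = f.max_within_species_identity_pct >= min_identity_pct
    return list(families)


def copy_number_table(families: Sequence[GeneFamily]) -> pd.DataFrame:
    """Per-family x per-species copy counts (absent species = 0)."""
    species = sorted({m.species for f in families for m in f.members})
    data = {
        f.id: [f.copy_numbers.get(sp, 0) for sp in species] for f in families
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=species).sort_index()


def gene_density(
    annotation, gene_track: RepeatTrack, classes: Sequence[str] = ("PAR", "SAT", "AMP", "ANC")
) -> dict[str, float]:
    """Genes per Mb per sequence class; a gene belongs to the class of its
    midpoint."""
    lengths = annotation.class_lengths()
    counts = {c: 0 for c in classes}
    for iv in gene_track.intervals:
        if iv.chrom != annotation.chrom:
            continue
        mid = (iv.start + iv.end) // 2
        cls = annotation.class_of_position(mid)
        if cls in counts:
            counts[cls] += 1
    out: dict[str, float] = {}
    for c in classes:
        length = lengths.get(c, 0)
        if length == 0:
            if counts[c]:
                raise ValueError(f"genes assigned to zero-length class {c!r}")
            continue
        out[c] = counts[c] / (length / 1e6)
    return out


def density_gof_test(
    gene_counts_per_class: Mapping[str, int],
    class_lengths: Mapping[str, int],
    m_tests: int = 1,
) -> tuple[float, int, float, float]:
    """Pearson goodness-of-fit test of gene counts against length share.

    Returns (chi-squared statistic, df, p, Bonferroni-adjusted p).
    Expected counts are total genes apportioned by class length.
    """
    classes = [c for c in gene_counts_per_class]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = np.array([gene_counts_per_class[c] for c in classes], dtype=float)
    lengths = np.array([class_lengths[c] for c in classes], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("all class lengths must be positive")
    expected = counts.sum() * lengths / lengths.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count")
    stat, p = chisquare(counts, expected)
    return float(stat), len(classes) - 1, float(p), bonferroni(float(p), m_tests)


# ---------------------------------------------------------------------------
# Protein FASTA with pipe-delimited metadata headers

def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Headers: id|gene|species|chrom|start|end ('.' for unknown locus)."""
    records: list[ProteinRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split("|")
        if len(parts) != 6:
            raise ValueError(f"protein header needs 6 |-fields: {header!r}")
        pid, gene, species, chrom, start, end = parts
        locus = None
        if start != "." and end != ".":
            locus = GenomicInterval(chrom, int(start), int(end))
        records.append(ProteinRecord(pid, gene, species, chrom, locus, "".join(chunks)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    return records


def write_protein_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            locus = (str(r.locus.start), str(r.locus.end)) if r.locus else (".", ".")
            fh.write(f">{r.protein_id}|{r.gene}|{r.species}|{r.chrom}|{locus[0]}|{locus[1]}\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i:i + 60] + "\n")


def write_family_table(families: Sequence[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tprotein_id\tgene\tspecies\tampliconic\t"
                 "max_within_species_identity_pct\n")
        for f in families:
            for m in f.members:
                fh.write("\t".join([
                    f.id, m.protein_id, m.gene, m.species,
                    str(int(f.ampliconic)),
                    f"{f.max_within_species_identity_pct:.3f}",
                ]) + "\n")
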