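"""Input/output for the standard formats the pipeline touches.

All coordinates are 0-based half-open ([start, end), BED convention) at
every module boundary.  Soft-masking is carried as residue case: lowercase
means masked, and downstream modules decide whether masked bases may seed
alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# IUPAC nucleotide codes (ambiguity codes included); case-insensitive.
_IUPAC_NT = set("ACGTRYSWKMBDHVN")

DIRECT = "direct"
INVERTED = "inverted"

ALIGNMENT_TABLE_COLUMNS = [
    "query_chrom", "query_start", "query_end",
    "target_chrom", "target_start", "target_end",
    "orientation", "identity_pct", "gap_pct", "matched_bases",
    "qcov_pct", "tcov_pct",
]


class SeqIOError(ValueError):
    """Malformed sequence or track input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with case-preserved (soft-mask) residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        for off, ch in enumerate(self.residues):
            if ch.upper() not in _IUPAC_NT:
                raise SeqIOError(
                    f"non-IUPAC character {ch!r} at offset {off} in {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def soft_masked(self) -> list[bool]:
        """Per-residue flag: True where the base is lowercase (masked)."""
        return [c.islower() for c in self.residues]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise SeqIOError(f"negative coordinate: {self.start}")
        if self.start >= self.end:
            raise SeqIOError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in (None, "+", "-"):
            raise SeqIOError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RepeatTrack:
    """Ordered repeat annotation (e.g. RepeatMasker output reduced to BED)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) not in (0, len(self.intervals)):
            raise SeqIOError("labels must be empty or parallel to intervals")
        if not self.labels:
            self.labels = ["" for _ in self.intervals]

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "RepeatTrack":
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        return RepeatTrack(
            [self.intervals[i] for i in order], [self.labels[i] for i in order]
        )

    def on_chrom(self, chrom: str) -> "RepeatTrack":
        keep = [i for i, iv in enumerate(self.intervals) if iv.chrom == chrom]
        return RepeatTrack(
            [self.intervals[i] for i in keep], [self.labels[i] for i in keep]
        )


@dataclass
class AlignmentRecord:
    """A pairwise alignment summary: the currency of every filtering rule.

    identity_pct counts matches over all alignment columns (gap columns
    included); gap_pct counts gap columns over all columns — the common
    lastz identity/continuity convention.
    """

    query: GenomicInterval
    target: GenomicInterval
    orientation: str
    identity_pct: float
    gap_pct: float
    matched_bases: int
    query_coverage_pct: float
    target_coverage_pct: float

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, INVERTED):
            raise SeqIOError(f"orientation must be direct/inverted, got {self.orientation!r}")
        for name in ("identity_pct", "gap_pct", "query_coverage_pct", "target_coverage_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise SeqIOError(f"{name}={v} outside [0, 100]")
        if self.matched_bases < 0:
            raise SeqIOError("matched_bases must be >= 0")
        if self.matched_bases > min(len(self.query), len(self.target)):
            raise SeqIOError(
                f"matched_bases {self.matched_bases} exceeds shorter interval "
                f"({min(len(self.query), len(self.target))} bp)"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-line, soft-masked) FASTA file.

    Case is preserved; duplicate ids, empty sequences and non-IUPAC
    characters are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> RepeatTrack:
    """Read BED3/BED4/BED6 into a RepeatTrack (0-based half-open)."""
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SeqIOError(f"line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise SeqIOError(f"line {lineno}: non-numeric coordinate") from exc
            if start < 0:
                raise SeqIOError(f"line {lineno}: negative coordinate {start}")
            if start >= end:
                raise SeqIOError(
                    f"line {lineno}: start {start} >= end {end} (zero-length not allowed)"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            intervals.append(GenomicInterval(chrom, start, end, strand))
            labels.append(fields[3] if len(fields) >= 4 else "")
    return RepeatTrack(intervals, labels)


def write_bed(track: RepeatTrack | Sequence[GenomicInterval], path: str | Path,
              labels: Sequence[str] | None = None) -> None:
    if isinstance(track, RepeatTrack):
        intervals, labels = track.intervals, track.labels
    else:
        intervals = list(track)
        labels = list(labels) if labels is not None else ["" for _ in intervals]
    with open(path, "w") as fh:
        for iv, lab in zip(intervals, labels):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if lab or iv.strand:
                cols.append(lab or ".")
            if iv.strand:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Alignment tables

def _record_from_generic(fields: dict[str, str], lineno: int) -> AlignmentRecord:
    try:
        identity = float(fields["identity_pct"])
        gap = float(fields["gap_pct"])
    except KeyError as exc:
        raise SeqIOError(f"line {lineno}: missing required column {exc}") from exc
    if not 0 <= identity <= 100:
        raise SeqIOError(f"line {lineno}: identity {identity} outside [0, 100]")
    return AlignmentRecord(
        query=GenomicInterval(fields["query_chrom"], int(fields["query_start"]),
                              int(fields["query_end"])),
        target=GenomicInterval(fields["target_chrom"], int(fields["target_start"]),
                               int(fields["target_end"])),
        orientation=fields["orientation"],
        identity_pct=identity,
        gap_pct=gap,
        matched_bases=int(fields["matched_bases"]),
        query_coverage_pct=float(fields["qcov_pct"]),
        target_coverage_pct=float(fields["tcov_pct"]),
    )


def _record_from_paf(cols: list[str], lineno: int) -> AlignmentRecord:
    if len(cols) < 12:
        raise SeqIOError(f"line {lineno}: PAF-like rows need >= 12 columns")
    qname, qlen, qstart, qend = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
    strand = cols[4]
    tname, tlen, tstart, tend = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
    matches, block = int(cols[9]), int(cols[10])
    qspan, tspan = qend - qstart, tend - tstart
    gapcols = max(0, block - qspan) + max(0, block - tspan)
    identity = 100.0 * matches / block if block else 0.0
    if not 0 <= identity <= 100:
        raise SeqIOError(f"line {lineno}: identity {identity} outside [0, 100]")
    return AlignmentRecord(
        query=GenomicInterval(qname, qstart, qend),
        target=GenomicInterval(tname, tstart, tend),
        orientation=INVERTED if strand == "-" else DIRECT,
        identity_pct=identity,
        gap_pct=100.0 * gapcols / block if block else 0.0,
        matched_bases=matches,
        query_coverage_pct=100.0 * qspan / qlen if qlen else 0.0,
        target_coverage_pct=100.0 * tspan / tlen if tlen else 0.0,
    )


def read_alignment_table(path: str | Path, dialect: str = "generic-tsv") -> list[AlignmentRecord]:
    """Read externally computed pairwise alignments.

    dialect "generic-tsv": headered TSV with the canonical columns
    (ALIGNMENT_TABLE_COLUMNS).  dialect "paf-like": headerless 12+ column
    PAF rows; orientation is inferred from the strand column.
    """
    if dialect not in ("generic-tsv", "paf-like"):
        raise SeqIOError(f"unknown dialect {dialect!r}")
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        if dialect == "generic-tsv":
            header = fh.readline().rstrip("\n").split("\t")
            missing = [c for c in ALIGNMENT_TABLE_COLUMNS if c not in header]
            if missing:
                raise SeqIOError(f"missing required column(s): {', '.join(missing)}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = dict(zip(header, line.split("\t")))
                records.append(_record_from_generic(fields, lineno))
        else:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                records.append(_record_from_paf(line.split("\t"), lineno))
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(map(str, [
                r.query.chrom, r.query.start, r.query.end,
                r.target.chrom, r.target.start, r.target.end,
                r.orientation,
                repr(r.identity_pct), repr(r.gap_pct), r.matched_bases,
                repr(r.query_coverage_pct), repr(r.target_coverage_pct),
            ])) + "\n")


# ---------------------------------------------------------------------------
# Interval arithmetic helpers shared across modules

def merge_intervals(intervals: Sequence[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Union of intervals per chromosome, joining neighbours separated by <= gap."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def total_overlap(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Bases in the intersection of union(a) and union(b)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    return sum(x.overlap_len(y) for x in ma for y in mb)
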