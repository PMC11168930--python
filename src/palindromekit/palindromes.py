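"""Palindrome calling and palindrome-level statistics.

A (genomic) palindrome is a pair of long inverted-repeat arms of
near-identical sequence on one chromosome, optionally separated by a
spacer.  Candidates proposed by the inverted self-aligner are kept when
the arms reach 98% identity, each arm spans at least 8 kb, the spacer is
at most 500 kb, and less than 80% of the candidate footprint is
repetitive — the thresholds used for the great-ape sex chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import stats as _stats
from .align import AlignParams, CandidateInvertedHit, self_inverted_hits
from .seqio import (
    GenomicInterval,
    RepeatTrack,
    SequenceRecord,
    merge_intervals,
    total_overlap,
)

PALINDROME_TABLE_COLUMNS = [
    "chrom", "arm1_start", "arm1_end", "arm2_start", "arm2_end",
    "identity_pct", "repeat_fraction", "id",
]


@dataclass
class PalindromeThresholds:
    min_arm_identity_pct: float = 98.0
    min_arm_len_bp: int = 8_000
    max_spacer_bp: int = 500_000
    max_repeat_fraction: float = 0.80
    #: whether the spacer counts toward the repetitive-content footprint
    include_spacer_in_repeat_fraction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_arm_identity_pct <= 100:
            raise ValueError("min_arm_identity_pct must be in (0, 100]")
        if min(self.min_arm_len_bp, self.max_spacer_bp) < 0:
            raise ValueError("length thresholds must be non-negative")
        if not 0 < self.max_repeat_fraction <= 1:
            raise ValueError("max_repeat_fraction must be in (0, 1]")


@dataclass
class Palindrome:
    id: str
    chrom: str
    arm1: GenomicInterval
    arm2: GenomicInterval
    spacer: GenomicInterval | None
    arm_identity_pct: float
    repeat_fraction: float

    def __post_init__(self) -> None:
        if self.arm1.end > self.arm2.start:
            raise ValueError("arm1 must end at or before arm2 starts")
        expect_spacer = self.arm2.start > self.arm1.end
        if expect_spacer:
            if (self.spacer is None or self.spacer.start != self.arm1.end
                    or self.spacer.end != self.arm2.start):
                raise ValueError("spacer must be exactly [arm1.end, arm2.start)")
        elif self.spacer is not None:
            raise ValueError("abutting arms cannot carry a spacer")

    @property
    def total_span_bp(self) -> int:
        return self.arm2.end - self.arm1.start

    @property
    def spacer_bp(self) -> int:
        return self.arm2.start - self.arm1.end

    def footprint(self, include_spacer: bool = True) -> list[GenomicInterval]:
        if include_spacer:
            return [GenomicInterval(self.chrom, self.arm1.start, self.arm2.end)]
        return [self.arm1, self.arm2]


def repeat_fraction(
    intervals: Sequence[GenomicInterval],
    repeat_track: RepeatTrack,
    chrom_length: int | None = None,
) -> float:
    """Fraction of union(intervals) bases covered by union(repeats)."""
    if not intervals:
        raise ValueError("repeat_fraction needs at least one interval")
    if chrom_length is not None:
        for iv in intervals:
            if iv.end > chrom_length:
                raise ValueError(f"interval {iv} extends past chromosome end {chrom_length}")
    merged = merge_intervals(intervals)
    denom = sum(len(iv) for iv in merged)
    if not len(repeat_track):
        return 0.0
    return total_overlap(merged, repeat_track.intervals) / denom


def detect_palindromes(
    record: SequenceRecord,
    repeat_track: RepeatTrack,
    thresholds: PalindromeThresholds | None = None,
    align_params: AlignParams | None = None,
    non_redundant: bool = False,
) -> list[Palindrome]:
    """Screen one chromosome for palindromes passing all four thresholds.

    Output is sorted by arm1 start and deterministic for fixed inputs.
    With non_redundant=True only the longest call per overlap group is
    kept (calls are otherwise allowed to overlap).
    """
    thresholds = thresholds or PalindromeThresholds()
    track = repeat_track.on_chrom(record.id)
    hits = self_inverted_hits(record, align_params)
    calls: list[Palindrome] = []
    for hit in hits:
        if hit.alignment.identity_pct < thresholds.min_arm_identity_pct:
            continue
        if min(len(hit.arm1), len(hit.arm2)) < thresholds.min_arm_len_bp:
            continue
        spacer_bp = hit.arm2.start - hit.arm1.end
        if spacer_bp > thresholds.max_spacer_bp:
            continue
        foot = (
            [GenomicInterval(record.id, hit.arm1.start, hit.arm2.end)]
            if thresholds.include_spacer_in_repeat_fraction
            else [hit.arm1, hit.arm2]
        )
        rf = repeat_fraction(foot, track, chrom_length=len(record))
        if rf >= thresholds.max_repeat_fraction:
            continue
        spacer = (
            GenomicInterval(record.id, hit.arm1.end, hit.arm2.start)
            if spacer_bp > 0 else None
        )
        calls.append(Palindrome(
            id="",
            chrom=record.id,
            arm1=hit.arm1,
            arm2=hit.arm2,
            spacer=spacer,
            arm_identity_pct=hit.alignment.identity_pct,
            repeat_fraction=rf,
        ))
    calls.sort(key=lambda p: (p.arm1.start, p.arm2.start))
    if non_redundant:
        kept: list[Palindrome] = []
        for p in sorted(calls, key=lambda q: (-q.total_span_bp, q.arm1.start)):
            span = GenomicInterval(p.chrom, p.arm1.start, p.arm2.end)
            if not any(span.overlaps(GenomicInterval(k.chrom, k.arm1.start, k.arm2.end))
                       for k in kept):
                kept.append(p)
        calls = sorted(kept, key=lambda p: (p.arm1.start, p.arm2.start))
    for rank, p in enumerate(calls, start=1):
        p.id = f"{record.id}_P{rank}"
    return calls


def gc_content(residues: str) -> float:
    """Percent G+C among unambiguous bases; N excluded from the denominator."""
    up = residues.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * gc / (gc + at)


def arm_vs_spacer_gc_test(
    palindromes: Sequence[Palindrome],
    sequences: dict[str, SequenceRecord],
) -> tuple[_stats.TestResult, int]:
    """One-sided two-sample t-test: are palindrome arms GC-richer than spacers?

    Arms contribute one pooled GC value per palindrome (both arms), spacers
    one value each; palindromes with empty spacers are excluded and their
    count returned alongside the test result.
    """
    arm_gc: list[float] = []
    spacer_gc: list[float] = []
    n_empty = 0
    for p in palindromes:
        seq = sequences[p.chrom].residues
        if p.spacer is None:
            n_empty += 1
            continue
        arm_gc.append(gc_content(seq[p.arm1.start:p.arm1.end] + seq[p.arm2.start:p.arm2.end]))
        spacer_gc.append(gc_content(seq[p.spacer.start:p.spacer.end]))
    if len(arm_gc) < 2:
        raise ValueError("need at least 2 palindromes with non-empty spacers")
    return _stats.t_test_two_sample(arm_gc, spacer_gc, alternative="greater"), n_empty


def palindrome_coverage(
    palindromes: Sequence[Palindrome],
    chrom_length: int,
    include_spacer: bool = True,
) -> float:
    """Fraction of the chromosome inside the union of palindrome footprints."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if not palindromes:
        return 0.0
    ivs: list[GenomicInterval] = []
    for p in palindromes:
        ivs.extend(p.footprint(include_spacer))
        if p.arm2.end > chrom_length:
            raise ValueError(f"palindrome {p.id} extends past chromosome end")
    return sum(len(iv) for iv in merge_intervals(ivs)) / chrom_length


def compare_spans(
    a: Sequence[Palindrome], b: Sequence[Palindrome], alternative: str = "greater"
) -> _stats.TestResult:
    """Rank-sum comparison of palindrome total spans between two sets."""
    return _stats.wilcoxon_rank_sum(
        [p.total_span_bp for p in a], [p.total_span_bp for p in b],
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Table IO

def write_palindrome_table(palindromes: Iterable[Palindrome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PALINDROME_TABLE_COLUMNS) + "\n")
        for p in palindromes:
            fh.write("\t".join(map(str, [
                p.chrom, p.arm1.start, p.arm1.end, p.arm2.start, p.arm2.end,
                repr(p.arm_identity_pct), repr(p.repeat_fraction), p.id,
            ])) + "\n")


def read_palindrome_table(path: str | Path) -> list[Palindrome]:
    out: list[Palindrome] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PALINDROME_TABLE_COLUMNS:
            raise ValueError(f"unexpected palindrome table header in {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, a1s, a1e, a2s, a2e, ident, rf, pid = line.split("\t")
            a1s, a1e, a2s, a2e = int(a1s), int(a1e), int(a2s), int(a2e)
            spacer = GenomicInterval(chrom, a1e, a2s) if a2s > a1e else None
            out.append(Palindrome(
                id=pid, chrom=chrom,
                arm1=GenomicInterval(chrom, a1s, a1e),
                arm2=GenomicInterval(chrom, a2s, a2e),
                spacer=spacer,
                arm_identity_pct=float(ident),
                repeat_fraction=float(rf),
            ))
    return out
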