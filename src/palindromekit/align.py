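"""Internal alignment engine.

Two jobs: (1) pairwise gapped alignment of nucleotide sequences with the
metrics every downstream filter consumes (identity, gap fraction, matched
bases, coverage); (2) inverted self-alignment of a chromosome — exact
k-mer seeds between the sequence and its reverse complement, anti-diagonal
chaining, and exact-match end polishing — proposing candidate palindrome
arms for the palindromes module to threshold.

Gapped alignment runs on edlib (unit-cost edit distance with an extended
CIGAR); the match/mismatch/gap fields of AlignParams parameterize seed
chaining only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .seqio import (
    INVERTED,
    AlignmentRecord,
    GenomicInterval,
    SequenceRecord,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# 2-bit base encoding; anything not ACGT (upper) is invalid for seeding
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


@dataclass
class AlignParams:
    """Knobs for inverted self-alignment discovery.

    k: exact seed length (bp).  max_seed_gap: largest hole tolerated
    between consecutive chained seeds along the chromosome.  band_width:
    tolerated anti-diagonal drift within one chain (absorbs indels between
    the arms).  min_arm_candidate: shortest arm candidate reported —
    deliberately below the palindrome arm-length threshold so that
    length-failing candidates are visible to (and rejected by) the caller.
    match/mismatch/gap: chain scoring weights.
    """

    k: int = 21
    max_seed_gap: int = 5_000
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    band_width: int = 2_000
    min_arm_candidate: int = 4_000

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.band_width <= 0 or self.min_arm_candidate <= 0:
            raise ValueError("band_width and min_arm_candidate must be positive")


@dataclass
class CandidateInvertedHit:
    """Two disjoint same-chromosome intervals aligning in inverted orientation."""

    arm1: GenomicInterval
    arm2: GenomicInterval
    alignment: AlignmentRecord

    def __post_init__(self) -> None:
        if self.arm1.chrom != self.arm2.chrom:
            raise ValueError("arms must share a chromosome")
        if self.arm1.end > self.arm2.start:
            raise ValueError("arm1 must lie 5' of arm2 without overlap")
        if self.alignment.orientation != INVERTED:
            raise ValueError("candidate hit alignment must be inverted")


def reverse_complement(residues: str) -> str:
    """Reverse complement, case-preserving, N<->N."""
    if not set(residues) <= set("ACGTNacgtn"):
        bad = sorted(set(residues) - set("ACGTNacgtn"))
        raise ValueError(f"cannot reverse-complement characters: {bad}")
    return residues.translate(_COMPLEMENT)[::-1]


def _cigar_metrics(cigar: str) -> tuple[int, int, int]:
    """(matches, gap columns, total columns) from an extended CIGAR."""
    matches = gaps = columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
        elif op in "ID":
            gaps += n
    return matches, gaps, columns


def align_pair(
    seq_a: str | SequenceRecord,
    seq_b: str | SequenceRecord,
    params: AlignParams | None = None,
    name_a: str = "seqA",
    name_b: str = "seqB",
    orientation: str = "direct",
) -> AlignmentRecord:
    """Global gapped alignment of two sequences with metric reporting.

    Deterministic; soft-masked bases are aligned through (uppercased
    first).  Raises on empty or all-N input.
    """
    a = seq_a.residues if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.residues if isinstance(seq_b, SequenceRecord) else seq_b
    if isinstance(seq_a, SequenceRecord):
        name_a = seq_a.id
    if isinstance(seq_b, SequenceRecord):
        name_b = seq_b.id
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    a_up, b_up = a.upper(), b.upper()
    if set(a_up) <= {"N"} or set(b_up) <= {"N"}:
        raise ValueError("cannot align a sequence of only N")
    res = edlib.align(a_up, b_up, mode="NW", task="path")
    matches, gapcols, columns = _cigar_metrics(res["cigar"])
    return AlignmentRecord(
        query=GenomicInterval(name_a, 0, len(a)),
        target=GenomicInterval(name_b, 0, len(b)),
        orientation=orientation,
        identity_pct=100.0 * matches / columns,
        gap_pct=100.0 * gapcols / columns,
        matched_bases=matches,
        query_coverage_pct=100.0,
        target_coverage_pct=100.0,
    )


def encode_sequence(residues: str) -> np.ndarray:
    """2-bit encode; soft-masked and non-ACGT positions become -1 (unseedable)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all valid k-mers and their start positions.

    Code convention: big-endian base-4 (first base most significant).
    Windows containing any unseedable base are dropped.
    """
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k).astype(np.int64)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


def _rc_kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of reverse-complemented k-mers, indexed by forward start position."""
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    comp = np.where(enc >= 0, 3 - enc, np.int8(-1))
    win = np.lib.stride_tricks.sliding_window_view(comp, k).astype(np.int64)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k, dtype=np.int64)  # reversed order = revcomp
    codes = win @ powers
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


def _inverted_seed_matches(enc: np.ndarray, k: int) -> np.ndarray:
    """All (i, j) with i + k <= j and seq[i:i+k] == revcomp(seq[j:j+k]).

    Returned as an (m, 2) array.  Join is done by sorting forward k-mer
    codes and range-searching reverse-complement codes against them.
    """
    fwd_codes, fwd_pos = kmer_codes(enc, k)
    rc_codes, rc_pos = _rc_kmer_codes(enc, k)
    if fwd_codes.size == 0 or rc_codes.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(fwd_codes, kind="stable")
    fc, fp = fwd_codes[order], fwd_pos[order]
    lo = np.searchsorted(fc, rc_codes, side="left")
    hi = np.searchsorted(fc, rc_codes, side="right")
    counts = hi - lo
    hit = counts > 0
    if not hit.any():
        return np.empty((0, 2), dtype=np.int64)
    j_rep = np.repeat(rc_pos[hit], counts[hit])
    idx = np.concatenate([np.arange(l, h) for l, h in zip(lo[hit], hi[hit])])
    i_all = fp[idx]
    keep = i_all + k <= j_rep
    return np.column_stack([i_all[keep], j_rep[keep]])


def _chain_matches(matches: np.ndarray, params: AlignParams) -> list[np.ndarray]:
    """Group seed matches into anti-diagonal chains.

    A chain holds matches whose anti-diagonal d = i + j drifts by at most
    band_width and whose consecutive i-gaps stay within max_seed_gap.
    """
    if matches.shape[0] == 0:
        return []
    d = matches[:, 0] + matches[:, 1]
    order = np.argsort(d, kind="stable")
    m, d = matches[order], d[order]
    chains: list[np.ndarray] = []
    start = 0
    for idx in range(1, len(d) + 1):
        if idx == len(d) or d[idx] - d[idx - 1] > params.band_width:
            group = m[start:idx]
            start = idx
            # split the diagonal group along the chromosome
            gorder = np.argsort(group[:, 0], kind="stable")
            g = group[gorder]
            brk = np.nonzero(np.diff(g[:, 0]) > params.max_seed_gap)[0] + 1
            for piece in np.split(g, brk):
                if piece.shape[0] > 0:
                    chains.append(piece)
    return chains


def _polish_ends(seq: str, a1s: int, a1e: int, a2s: int, a2e: int) -> tuple[int, int, int, int]:
    """Exact-match extension of arm boundaries in both directions."""
    up = seq.upper()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # outer: left of arm1 pairs with right of arm2
    while a1s > 0 and a2e < len(up):
        x, y = up[a1s - 1], up[a2e]
        if x in comp and comp[x] == y:
            a1s -= 1
            a2e += 1
        else:
            break
    # inner: right of arm1 pairs with left of arm2
    while a1e < a2s and a2s > a1e:
        x, y = up[a1e], up[a2s - 1]
        if x in comp and comp[x] == y and a1e + 1 <= a2s - 1:
            a1e += 1
            a2s -= 1
        else:
            break
    return a1s, a1e, a2s, a2e


def self_inverted_hits(
    record: SequenceRecord, params: AlignParams | None = None
) -> list[CandidateInvertedHit]:
    """Candidate palindrome arms: inverted-orientation self-alignments.

    Soft-masked bases never seed but are aligned through during the
    arm-vs-arm identity computation.  Overlapping candidates are resolved
    greedily by matched bases (leftmost wins ties).
    """
    params = params or AlignParams()
    if len(record) < 2 * params.min_arm_candidate:
        raise ValueError(
            f"sequence {record.id!r} shorter than two minimum arm candidates"
        )
    enc = encode_sequence(record.residues)
    matches = _inverted_seed_matches(enc, params.k)
    hits: list[CandidateInvertedHit] = []
    for chain in _chain_matches(matches, params):
        i_min, i_max = int(chain[:, 0].min()), int(chain[:, 0].max())
        j_min, j_max = int(chain[:, 1].min()), int(chain[:, 1].max())
        a1s, a1e = i_min, i_max + params.k
        a2s, a2e = j_min, j_max + params.k
        if a1e > a2s:  # arms collided across a tiny spacer; split at midpoint
            mid = (a1e + a2s) // 2
            a1e, a2s = mid, mid
            if a1e <= a1s or a2e <= a2s:
                continue
        a1s, a1e, a2s, a2e = _polish_ends(record.residues, a1s, a1e, a2s, a2e)
        if min(a1e - a1s, a2e - a2s) < params.min_arm_candidate:
            continue
        arm1 = GenomicInterval(record.id, a1s, a1e)
        arm2 = GenomicInterval(record.id, a2s, a2e)
        aln = align_pair(
            record.residues[a1s:a1e],
            reverse_complement(record.residues[a2s:a2e]),
            orientation="direct",
        )
        hits.append(
            CandidateInvertedHit(
                arm1=arm1,
                arm2=arm2,
                alignment=AlignmentRecord(
                    query=arm1,
                    target=arm2,
                    orientation=INVERTED,
                    identity_pct=aln.identity_pct,
                    gap_pct=aln.gap_pct,
                    matched_bases=aln.matched_bases,
                    query_coverage_pct=100.0,
                    target_coverage_pct=100.0,
                ),
            )
        )
    # greedy non-redundancy: best matched_bases first, leftmost tie-break
    hits.sort(key=lambda h: (-h.alignment.matched_bases, h.arm1.start, h.arm2.start))
    kept: list[CandidateInvertedHit] = []
    for h in hits:
        clash = any(
            h.arm1.overlaps(k.arm1) or h.arm2.overlaps(k.arm2)
            or h.arm1.overlaps(k.arm2) or h.arm2.overlaps(k.arm1)
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: h.arm1.start)
    return kept
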