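"""Sequence-class annotation of sex chromosomes.

The workflow mirrors the standard sex-chromosome partition: find
pseudoautosomal regions by aligning the X and Y termini; build a
satellite track by merging dense repeat annotation (gap <= 1 kb, span
> 0.25 Mb); call ampliconic candidates as runs of 5-kb windows with a
non-self intrachromosomal match (>= 50% identity) spanning > 90 kb; union
those with palindrome footprints; and tile the chromosome with precedence
PAR > SAT > AMP > ANC.  On the Y, leftover ancestral-by-default segments
overlapping ampliconic-family genes are reassigned AMP.  The segmental-
duplication post-filter (identity > 90%, length > 1 kb, satellite content
< 70%, all strict) is applied to externally discovered records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .align import _cigar_metrics, encode_sequence, kmer_codes, reverse_complement
from .palindromes import Palindrome
from .seqio import GenomicInterval, RepeatTrack, SequenceRecord, merge_intervals

logger = logging.getLogger(__name__)

CLASS_ORDER = ["ANC", "AMP", "SAT", "PAR"]  # ascending precedence
_CLASS_CODE = {name: i for i, name in enumerate(CLASS_ORDER)}


@dataclass
class ParParams:
    min_identity_pct: float = 99.0
    min_len_bp: int = 50_000
    chunk_bp: int = 10_000
    max_interruption_bp: int = 10_000
    refine_step_bp: int = 500


@dataclass
class WindowParams:
    window_bp: int = 5_000
    min_identity_pct: float = 50.0
    min_span_bp: int = 90_000
    k: int = 11
    min_seed_hits: int = 25
    diag_bin_bp: int = 250


@dataclass
class SegDupRecord:
    locus_a: GenomicInterval
    locus_b: GenomicInterval
    identity_pct: float
    satellite_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct outside [0, 100]")
        if not 0 <= self.satellite_fraction <= 1:
            raise ValueError("satellite_fraction outside [0, 1]")

    @property
    def length_bp(self) -> int:
        return len(self.locus_a)


@dataclass
class SeqClassAnnotation:
    """A labelled perfect tiling of [0, chrom length) into sequence classes."""

    chrom: str
    chrom_length: int
    segments: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def validate(self) -> None:
        pos = 0
        for iv, cls in self.segments:
            if iv.chrom != self.chrom:
                raise ValueError("segment on wrong chromosome")
            if iv.start != pos:
                raise ValueError(f"tiling broken at {pos}: next segment starts {iv.start}")
            if cls not in _CLASS_CODE and cls not in ("PAR1", "PAR2"):
                raise ValueError(f"unknown class {cls!r}")
            pos = iv.end
        if pos != self.chrom_length:
            raise ValueError(f"tiling ends at {pos}, chromosome length {self.chrom_length}")

    def class_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iv, cls in self.segments:
            base = "PAR" if cls.startswith("PAR") else cls
            out[base] = out.get(base, 0) + len(iv)
        return out

    def class_of_position(self, pos: int) -> str:
        for iv, cls in self.segments:
            if iv.start <= pos < iv.end:
                return "PAR" if cls.startswith("PAR") else cls
        raise ValueError(f"position {pos} outside chromosome")


# ---------------------------------------------------------------------------
# PAR detection

def _chunk_identity(a: str, b: str) -> float:
    if set(a.upper()) <= {"N"} or set(b.upper()) <= {"N"}:
        return 0.0
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches, _, columns = _cigar_metrics(res["cigar"])
    return 100.0 * matches / columns


def _terminal_homology(x: str, y: str, params: ParParams, from_end: bool) -> int:
    """Length of the maximal terminal block where X and Y stay homologous."""
    limit = min(len(x), len(y))
    c = params.chunk_bp
    extent = 0          # verified homologous extent (bp from the terminus)
    bad_run = 0
    off = 0
    while off + c <= limit:
        if from_end:
            xa, ya = x[len(x) - off - c:len(x) - off], y[len(y) - off - c:len(y) - off]
        else:
            xa, ya = x[off:off + c], y[off:off + c]
        if _chunk_identity(xa, ya) >= params.min_identity_pct:
            extent = off + c
            bad_run = 0
        else:
            bad_run += c
            if bad_run > params.max_interruption_bp:
                break
        off += c
    # refine the boundary inside the first failing chunk
    step = params.refine_step_bp
    off = extent
    while off + step <= limit:
        if from_end:
            xa, ya = x[len(x) - off - step:len(x) - off], y[len(y) - off - step:len(y) - off]
        else:
            xa, ya = x[off:off + step], y[off:off + step]
        if _chunk_identity(xa, ya) >= params.min_identity_pct:
            extent = off + step
            off += step
        else:
            break
    return extent


def detect_par(
    x_record: SequenceRecord,
    y_record: SequenceRecord,
    params: ParParams | None = None,
) -> dict[str, list[tuple[GenomicInterval, str]]]:
    """Pseudoautosomal regions: terminal X/Y homology blocks.

    PAR1 is the block at the left terminus, PAR2 (if any) at the right.
    Returns {"X": [(interval, "PAR1"/"PAR2"), ...], "Y": [...]}; empty
    with a warning when no terminal homology is found.
    """
    params = params or ParParams()
    x, y = x_record.residues, y_record.residues
    out: dict[str, list[tuple[GenomicInterval, str]]] = {"X": [], "Y": []}
    left = _terminal_homology(x, y, params, from_end=False)
    if left >= params.min_len_bp:
        out["X"].append((GenomicInterval(x_record.id, 0, left), "PAR1"))
        out["Y"].append((GenomicInterval(y_record.id, 0, left), "PAR1"))
    right = _terminal_homology(x, y, params, from_end=True)
    # don't let PAR2 re-report a chromosome that is PAR end to end
    if right >= params.min_len_bp and left + right < min(len(x), len(y)):
        out["X"].append((GenomicInterval(x_record.id, len(x) - right, len(x)), "PAR2"))
        out["Y"].append((GenomicInterval(y_record.id, len(y) - right, len(y)), "PAR2"))
    if not out["X"]:
        warnings.warn("no terminal X/Y homology found; no PAR reported")
    return out


# ---------------------------------------------------------------------------
# Satellite track

def satellite_track(
    repeat_track: RepeatTrack,
    merge_gap_bp: int = 1_000,
    min_span_bp: int = 250_000,
    label_filter: set[str] | None = None,
) -> list[GenomicInterval]:
    """Merge adjacent repeat annotation (gap <= merge_gap_bp) and keep
    merged spans strictly greater than min_span_bp."""
    ivs = repeat_track.intervals
    if label_filter is not None:
        ivs = [iv for iv, lab in zip(ivs, repeat_track.labels) if lab in label_filter]
    if not ivs:
        return []
    merged = merge_intervals(ivs, gap=merge_gap_bp)
    return [iv for iv in merged if len(iv) > min_span_bp]


# ---------------------------------------------------------------------------
# Ampliconic windows

def _mask_sequence(residues: str, repeat_track: RepeatTrack, chrom: str) -> str:
    arr = np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8).copy()
    for iv in repeat_track.intervals:
        if iv.chrom == chrom:
            arr[iv.start:iv.end] = ord("N")
    return arr.tobytes().decode("ascii")


def ampliconic_windows(
    record: SequenceRecord,
    repeat_track: RepeatTrack,
    params: WindowParams | None = None,
    exclude: Sequence[GenomicInterval] | None = None,
) -> tuple[list[GenomicInterval], list[dict]]:
    """Regions of high intrachromosomal similarity.

    The chromosome is repeat-masked, cut into consecutive windows, and a
    window qualifies when a non-self locus (either orientation, centred
    at least a window away) shows enough exact k-mer seed support on one
    diagonal band and the verifying alignment reaches the identity
    threshold.  Maximal runs of qualifying windows longer than
    min_span_bp are returned, together with per-window diagnostics.

    Windows overlapping `exclude` (typically the PARs) never qualify.
    Terminal partial windows are evaluated but flagged and excluded from
    run spans.
    """
    params = params or WindowParams()
    if params.window_bp <= 0:
        raise ValueError("window size must be positive")
    w = params.window_bp
    masked = _mask_sequence(record.residues, repeat_track, record.id)
    L = len(masked)
    enc = encode_sequence(masked)
    codes, pos = kmer_codes(enc, params.k)
    order = np.argsort(codes, kind="stable")
    codes_s, pos_s = codes[order], pos[order]

    rc_masked = reverse_complement(masked)
    enc_rc = encode_sequence(rc_masked)
    codes_rc, pos_rc = kmer_codes(enc_rc, params.k)
    # map rc positions back to forward coordinates of the k-mer start
    pos_rc_fwd = L - params.k - pos_rc
    order_rc = np.argsort(codes_rc, kind="stable")
    codes_rc_s, pos_rc_s = codes_rc[order_rc], pos_rc_fwd[order_rc]

    excl = merge_intervals(exclude) if exclude else []

    def window_excluded(ws: int, we: int) -> bool:
        return any(iv.start < we and ws < iv.end for iv in excl)

    def best_band_hits(ws: int, we: int) -> tuple[int, int, bool] | None:
        """(target_offset, hits, inverted?) of the strongest non-self band."""
        best: tuple[int, int, bool] | None = None
        a = np.searchsorted(pos, ws, side="left")
        b = np.searchsorted(pos, we - params.k + 1, side="left")
        wcodes, wpos = codes[a:b], pos[a:b]
        if wcodes.size == 0:
            return None
        for inverted, (c_sorted, p_sorted) in (
            (False, (codes_s, pos_s)),
            (True, (codes_rc_s, pos_rc_s)),
        ):
            lo = np.searchsorted(c_sorted, wcodes, side="left")
            hi = np.searchsorted(c_sorted, wcodes, side="right")
            counts = hi - lo
            if counts.sum() == 0:
                continue
            tpos = p_sorted[np.concatenate(
                [np.arange(l, h) for l, h in zip(lo, hi)])]
            qpos = np.repeat(wpos, counts)
            # non-self: target k-mer must start at least a window away
            keep = np.abs(tpos - qpos) >= w
            if not keep.any():
                continue
            diag = (tpos[keep] - qpos[keep]) // params.diag_bin_bp
            vals, cnts = np.unique(diag, return_counts=True)
            bi = int(np.argmax(cnts))
            if best is None or int(cnts[bi]) > best[1]:
                best = (int(vals[bi]) * params.diag_bin_bp, int(cnts[bi]), inverted)
        return best

    def verify(ws: int, we: int, offset: int, inverted: bool) -> float:
        query = masked[ws:we]
        slack = params.diag_bin_bp + 500
        if inverted:
            # offset refers to forward start of the matching rc locus
            ts = max(0, ws + offset - slack)
            te = min(L, ws + offset + (we - ws) + slack)
            target = reverse_complement(masked[ts:te])
        else:
            ts = max(0, ws + offset - slack)
            te = min(L, ws + offset + (we - ws) + slack)
            target = masked[ts:te]
        if set(query) <= {"N"} or set(target) <= {"N"}:
            return 0.0
        res = edlib.align(query, target, mode="HW", task="path")
        matches, _, columns = _cigar_metrics(res["cigar"])
        return 100.0 * matches / columns if columns else 0.0

    window_hits: list[dict] = []
    qualifying: list[bool] = []
    starts = list(range(0, L, w))
    for ws in starts:
        we = min(L, ws + w)
        partial = (we - ws) < w
        q = False
        ident = 0.0
        if not window_excluded(ws, we):
            band = best_band_hits(ws, we)
            if band is not None and band[1] >= params.min_seed_hits:
                ident = verify(ws, we, band[0], band[2])
                q = ident >= params.min_identity_pct
        window_hits.append({
            "window": GenomicInterval(record.id, ws, we),
            "best_nonself_identity_pct": ident,
            "qualifies": q,
            "partial": partial,
        })
        qualifying.append(q and not partial)

    # merge maximal runs of consecutive qualifying windows
    out: list[GenomicInterval] = []
    i = 0
    while i < len(starts):
        if qualifying[i]:
            j = i
            while j + 1 < len(starts) and qualifying[j + 1]:
                j += 1
            run_start, run_end = starts[i], min(L, starts[j] + w)
            if run_end - run_start > params.min_span_bp:
                out.append(GenomicInterval(record.id, run_start, run_end))
            i = j + 1
        else:
            i += 1
    return out, window_hits


# ---------------------------------------------------------------------------
# Class assignment

def assign_classes(
    chrom_length: int,
    chrom: str,
    par: Sequence[tuple[GenomicInterval, str]] | Sequence[GenomicInterval] = (),
    sat: Sequence[GenomicInterval] = (),
    amp_candidates: Sequence[GenomicInterval] = (),
    palindromes: Sequence[Palindrome] = (),
    gene_track: RepeatTrack | None = None,
    is_y: bool = False,
    palindrome_spacer_in_amp: bool = True,
) -> SeqClassAnnotation:
    """Tile [0, chrom_length) into PAR/SAT/AMP/ANC.

    AMP is the union of palindrome footprints and high-similarity
    candidates; overlaps resolve by precedence PAR > SAT > AMP > ANC.  On
    the Y (is_y=True, gene_track carrying "ancestral"/"ampliconic"
    labels), ancestral-by-default leftover segments that overlap an
    ampliconic-family gene are reassigned AMP.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    arr = np.zeros(chrom_length, dtype=np.uint8)  # ANC

    def paint(ivs, code):
        for iv in ivs:
            if iv.end > chrom_length:
                raise ValueError(f"interval {iv} extends past chromosome end")
            if iv.chrom != chrom:
                raise ValueError(f"interval {iv} on wrong chromosome")
            arr[iv.start:iv.end] = code

    amp_ivs: list[GenomicInterval] = list(amp_candidates)
    for p in palindromes:
        amp_ivs.extend(p.footprint(include_spacer=palindrome_spacer_in_amp))
    paint(amp_ivs, _CLASS_CODE["AMP"])
    paint(sat, _CLASS_CODE["SAT"])

    par_ivs: list[GenomicInterval] = []
    par_names: dict[tuple[int, int], str] = {}
    for item in par:
        if isinstance(item, tuple):
            iv, name = item
        else:
            iv, name = item, "PAR"
        par_ivs.append(iv)
        par_names[(iv.start, iv.end)] = name
    paint(par_ivs, _CLASS_CODE["PAR"])

    # log precedence-resolved overlaps (the ambiguity of nested classes)
    for low, high in ((amp_ivs, sat), (amp_ivs, par_ivs), (list(sat), par_ivs)):
        for a in low:
            for b in high:
                if a.overlaps(b):
                    logger.info("segment overlap resolved by precedence: %s vs %s", a, b)

    # Y refinement: leftover ANC runs overlapping ampliconic genes -> AMP
    if is_y and gene_track is not None:
        amp_genes = [iv for iv, lab in zip(gene_track.intervals, gene_track.labels)
                     if lab == "ampliconic" and iv.chrom == chrom]
        boundaries = np.flatnonzero(np.diff(arr)) + 1
        run_edges = np.concatenate([[0], boundaries, [chrom_length]])
        for s, e in zip(run_edges[:-1], run_edges[1:]):
            if arr[s] != _CLASS_CODE["ANC"]:
                continue
            run = GenomicInterval(chrom, int(s), int(e))
            if any(run.overlaps(g) for g in amp_genes):
                arr[s:e] = _CLASS_CODE["AMP"]

    # run-length encode into segments
    segments: list[tuple[GenomicInterval, str]] = []
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    run_edges = np.concatenate([[0], boundaries, [chrom_length]])
    for s, e in zip(run_edges[:-1], run_edges[1:]):
        cls = CLASS_ORDER[arr[s]]
        if cls == "PAR":
            name = "PAR"
            for (ps, pe), nm in par_names.items():
                if ps <= s and e <= pe:
                    name = nm
                    break
            cls = name
        segments.append((GenomicInterval(chrom, int(s), int(e)), cls))
    ann = SeqClassAnnotation(chrom, chrom_length, segments)
    ann.validate()
    return ann


def filter_segdups(records: Sequence[SegDupRecord]) -> list[SegDupRecord]:
    """Keep records with identity > 90, length > 1 kb and satellite
    content < 70% (all strict)."""
    return [
        r for r in records
        if r.identity_pct > 90.0 and r.length_bp > 1_000 and r.satellite_fraction < 0.70
    ]


def write_class_bed(annotation: SeqClassAnnotation, path) -> None:
    with open(path, "w") as fh:
        for iv, cls in annotation.segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\n")
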