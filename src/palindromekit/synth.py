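"""Synthetic chromosomes and protein sets with planted, machine-readable truth.

The generator emulates the feature structure of great-ape sex
chromosomes at desk scale: palindromes (inverted arm pairs at a chosen
divergence around a spacer), satellite arrays (tandem unit repeats, also
written to the repeat track), dispersed duplications, terminal PAR
blocks shared between an X and a Y sequence, and protein families with a
chosen identity structure.  Every planted feature is echoed in a truth
table with realized 0-based half-open coordinates, and identical spec +
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import reverse_complement
from .seqio import GenomicInterval, RepeatTrack, SequenceRecord
from .genefam import ProteinRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Feature specs

@dataclass
class PlantedPalindrome:
    position: int           # arm1 start
    arm_len: int
    spacer_len: int
    divergence: float = 0.01
    gc: float | None = None  # arm/spacer base composition override

    @property
    def span(self) -> int:
        return 2 * self.arm_len + self.spacer_len


@dataclass
class PlantedSatellite:
    position: int
    unit_len: int
    copies: int
    label: str = "satellite"
    divergence: float = 0.0  # per-copy divergence from the unit

    @property
    def span(self) -> int:
        return self.unit_len * self.copies


@dataclass
class PlantedDuplication:
    position: int            # source locus start
    length: int
    copy_position: int       # second locus start
    divergence: float = 0.05


@dataclass
class PlantedRepeat:
    """Repeat-track annotation over existing sequence (no sequence change)."""
    start: int
    end: int
    label: str = "repeat"
    soft_mask: bool = False


@dataclass
class PlantedGene:
    start: int
    end: int
    label: str = "ancestral"   # "ancestral" or "ampliconic"
    name: str = ""


@dataclass
class SynthSpec:
    chrom_name: str = "chrS"
    chrom_length: int = 1_000_000
    gc: float = 0.41
    seed: int = 0
    indel_rate: float = 0.0
    palindromes: list[PlantedPalindrome] = field(default_factory=list)
    satellites: list[PlantedSatellite] = field(default_factory=list)
    duplications: list[PlantedDuplication] = field(default_factory=list)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)

    def occupied(self) -> list[tuple[int, int, str]]:
        spans = []
        for p in self.palindromes:
            spans.append((p.position, p.position + p.span, "palindrome"))
        for s in self.satellites:
            spans.append((s.position, s.position + s.span, "satellite"))
        for d in self.duplications:
            spans.append((d.position, d.position + d.length, "duplication"))
            spans.append((d.copy_position, d.copy_position + d.length, "duplication"))
        return spans

    def validate(self) -> None:
        spans = sorted(self.occupied())
        for (s, e, kind) in spans:
            if s < 0 or e > self.chrom_length:
                raise ValueError(f"{kind} [{s}, {e}) outside chromosome")
        conflicts = [
            (a, b) for a, b in zip(spans, spans[1:]) if b[0] < a[1]
        ]
        if conflicts:
            raise ValueError(f"overlapping planted features: {conflicts}")
        for p in self.palindromes:
            if not 0 <= p.divergence <= 0.5:
                raise ValueError("divergence must be in [0, 0.5]")


# ---------------------------------------------------------------------------
# Sequence primitives

def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.41) -> str:
    """Uniform-composition random DNA at the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate(
    residues: str,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Independent per-base substitutions (to a uniformly chosen different
    base) at the requested expected fraction, plus optional small indels
    (geometric lengths, mean 2 bp).  Deterministic given seed."""
    if not 0 <= divergence <= 1 or not 0 <= indel_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if divergence == 0 and indel_rate == 0:
        return residues
    arr = np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    enc = code[arr]
    subst = (rng.random(len(arr)) < divergence) & (enc >= 0)
    shift = rng.integers(1, 4, size=len(arr))
    enc_new = np.where(subst, (enc + shift) % 4, enc)
    out = np.where(enc >= 0, _BASES[np.clip(enc_new, 0, 3)], arr).astype(np.uint8)
    seq = out.tobytes().decode("ascii")
    # restore case of unmutated input positions
    if residues != residues.upper():
        seq = "".join(
            c.lower() if orig.islower() else c for c, orig in zip(seq, residues)
        )
    if indel_rate > 0:
        pieces: list[str] = []
        pos = 0
        events = np.flatnonzero(rng.random(len(seq)) < indel_rate)
        for ev in events:
            if ev < pos:
                continue
            length = int(rng.geometric(0.5))
            pieces.append(seq[pos:ev])
            if rng.random() < 0.5:  # insertion
                pieces.append(random_sequence(length, rng))
                pos = ev
            else:                   # deletion
                pos = min(len(seq), ev + length)
        pieces.append(seq[pos:])
        seq = "".join(pieces)
    return seq


# ---------------------------------------------------------------------------
# Chromosome generation

def generate_chromosome(
    spec: SynthSpec,
) -> tuple[SequenceRecord, RepeatTrack, pd.DataFrame]:
    """Realize a spec: background random sequence with features spliced in
    at their recorded coordinates; repeat/gene annotation and a truth
    table alongside."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq = np.frombuffer(
        random_sequence(spec.chrom_length, rng, spec.gc).encode("ascii"),
        dtype=np.uint8,
    ).copy()
    chrom = spec.chrom_name
    truth_rows: list[dict] = []
    repeat_ivs: list[GenomicInterval] = []
    repeat_labels: list[str] = []
    soft_mask_spans: list[tuple[int, int]] = []

    def splice(start: int, piece: str) -> None:
        arr = np.frombuffer(piece.encode("ascii"), dtype=np.uint8)
        seq[start:start + len(arr)] = arr

    for n, p in enumerate(spec.palindromes):
        arm_gc = p.gc if p.gc is not None else spec.gc
        arm1 = random_sequence(p.arm_len, rng, arm_gc)
        spacer = random_sequence(p.spacer_len, rng, arm_gc)
        arm2 = mutate(reverse_complement(arm1), p.divergence, spec.indel_rate, rng=rng)
        splice(p.position, arm1 + spacer + arm2)
        a1s, a1e = p.position, p.position + p.arm_len
        a2s = a1e + p.spacer_len
        a2e = a2s + len(arm2)
        truth_rows.append({
            "kind": "palindrome", "name": f"pal{n}", "chrom": chrom,
            "start": a1s, "end": a2e,
            "arm1_start": a1s, "arm1_end": a1e,
            "arm2_start": a2s, "arm2_end": a2e,
            "divergence": p.divergence,
        })

    for n, s in enumerate(spec.satellites):
        unit = random_sequence(s.unit_len, rng)
        copies = [
            unit if s.divergence == 0 else mutate(unit, s.divergence, rng=rng)
            for _ in range(s.copies)
        ]
        arr_str = "".join(copies)
        splice(s.position, arr_str)
        iv = GenomicInterval(chrom, s.position, s.position + len(arr_str))
        repeat_ivs.append(iv)
        repeat_labels.append(s.label)
        truth_rows.append({
            "kind": "satellite", "name": f"sat{n}", "chrom": chrom,
            "start": iv.start, "end": iv.end, "label": s.label,
        })

    for n, d in enumerate(spec.duplications):
        src = random_sequence(d.length, rng)
        copy = mutate(src, d.divergence, spec.indel_rate, rng=rng)
        splice(d.position, src)
        splice(d.copy_position, copy[:d.length].ljust(d.length, "A")
               if len(copy) != d.length else copy)
        truth_rows.append({
            "kind": "duplication", "name": f"dup{n}", "chrom": chrom,
            "start": d.position, "end": d.position + d.length,
            "copy_start": d.copy_position, "copy_end": d.copy_position + d.length,
            "divergence": d.divergence,
        })

    for n, r in enumerate(spec.repeats):
        repeat_ivs.append(GenomicInterval(chrom, r.start, r.end))
        repeat_labels.append(r.label)
        if r.soft_mask:
            soft_mask_spans.append((r.start, r.end))
        truth_rows.append({
            "kind": "repeat", "name": f"rep{n}", "chrom": chrom,
            "start": r.start, "end": r.end, "label": r.label,
        })

    gene_ivs: list[GenomicInterval] = []
    gene_labels: list[str] = []
    for n, g in enumerate(spec.genes):
        gene_ivs.append(GenomicInterval(chrom, g.start, g.end))
        gene_labels.append(g.label)
        truth_rows.append({
            "kind": "gene", "name": g.name or f"gene{n}", "chrom": chrom,
            "start": g.start, "end": g.end, "label": g.label,
        })

    residues = seq.tobytes().decode("ascii")
    if soft_mask_spans:
        chars = list(residues)
        for s, e in soft_mask_spans:
            chars[s:e] = [c.lower() for c in chars[s:e]]
        residues = "".join(chars)
    record = SequenceRecord(chrom, residues)
    track = RepeatTrack(repeat_ivs, repeat_labels).sorted()
    truth = pd.DataFrame(truth_rows)
    gene_track = RepeatTrack(gene_ivs, gene_labels).sorted() if gene_ivs else RepeatTrack()
    # gene track rides along in the truth table; callers re-derive it via genes_track()
    return record, track, truth


def genes_track(spec: SynthSpec) -> RepeatTrack:
    ivs = [GenomicInterval(spec.chrom_name, g.start, g.end) for g in spec.genes]
    labels = [g.label for g in spec.genes]
    return RepeatTrack(ivs, labels).sorted()


def generate_xy_pair(
    x_length: int,
    y_length: int,
    par1_len: int,
    par2_len: int = 0,
    haplotype_divergence: float = 0.0,
    seed: int = 0,
    gc: float = 0.41,
) -> tuple[SequenceRecord, SequenceRecord, pd.DataFrame]:
    """An X/Y pair sharing terminal PAR blocks.

    PAR blocks are identical between the chromosomes (or mutated on the Y
    at the requested haplotype divergence); the remainders are
    independent random sequence."""
    if par1_len + par2_len >= min(x_length, y_length):
        raise ValueError("PAR blocks exceed chromosome length")
    rng = np.random.default_rng(seed)
    par1 = random_sequence(par1_len, rng, gc) if par1_len else ""
    par2 = random_sequence(par2_len, rng, gc) if par2_len else ""
    x_mid = random_sequence(x_length - par1_len - par2_len, rng, gc)
    y_mid = random_sequence(y_length - par1_len - par2_len, rng, gc)
    par1_y = mutate(par1, haplotype_divergence, rng=rng) if par1 else ""
    par2_y = mutate(par2, haplotype_divergence, rng=rng) if par2 else ""
    x_rec = SequenceRecord("chrX", par1 + x_mid + par2)
    y_rec = SequenceRecord("chrY", par1_y + y_mid + par2_y)
    rows = []
    if par1_len:
        rows += [
            {"kind": "PAR1", "chrom": "chrX", "start": 0, "end": par1_len},
            {"kind": "PAR1", "chrom": "chrY", "start": 0, "end": len(par1_y)},
        ]
    if par2_len:
        rows += [
            {"kind": "PAR2", "chrom": "chrX", "start": x_length - par2_len, "end": x_length},
            {"kind": "PAR2", "chrom": "chrY", "start": len(y_rec) - len(par2_y), "end": len(y_rec)},
        ]
    return x_rec, y_rec, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein families

@dataclass
class FamilySpec:
    name: str
    #: (species, identity of this member to the family reference, %)
    members: list[tuple[str, float]]
    length_aa: int = 200


def _random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_AA20), size=length)
    return "".join(_AA20[i] for i in idx)


def _mutate_protein(residues: str, divergence: float, rng: np.random.Generator,
                    end_margin: int = 10) -> str:
    """Exactly round(divergence * length) substitutions at distinct interior
    positions (terminal margins spared so local alignment cannot trim
    mismatches away and inflate realized identity)."""
    n = len(residues)
    n_sub = int(round(divergence * n))
    if n_sub == 0:
        return residues
    interior = np.arange(end_margin, n - end_margin)
    if n_sub > interior.size:
        raise ValueError("divergence too high for exact interior placement")
    sites = rng.choice(interior, size=n_sub, replace=False)
    out = list(residues)
    for i in sites:
        choices = _AA20.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def generate_protein_families(
    family_specs: Sequence[FamilySpec],
    seed: int = 0,
    n_singletons: int = 0,
    singleton_species: Sequence[str] = ("sp1",),
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteins with a star-shaped identity structure per family.

    Each family member is mutated from a hidden family reference at
    (100 - identity)%, so member-vs-reference identities realize the
    request; between-family identity is that of unrelated random
    proteins (~5%).  Optional unrelated singletons are appended."""
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    rows: list[dict] = []
    for fam in family_specs:
        for sp, ident in fam.members:
            if not 0 <= ident <= 100:
                raise ValueError(f"identity {ident} outside [0, 100]")
        ref = _random_protein(fam.length_aa, rng)
        per_species_rank: dict[str, int] = {}
        for sp, ident in fam.members:
            per_species_rank[sp] = per_species_rank.get(sp, 0) + 1
            pid = f"{fam.name}_{sp}_c{per_species_rank[sp]}"
            res = _mutate_protein(ref, 1.0 - ident / 100.0, rng)
            proteins.append(ProteinRecord(pid, fam.name, sp, "chrS", None, res))
            rows.append({
                "family": fam.name, "protein_id": pid, "species": sp,
                "requested_identity_pct": ident,
            })
    for i in range(n_singletons):
        sp = singleton_species[i % len(singleton_species)]
        pid = f"orph{i}_{sp}"
        proteins.append(ProteinRecord(
            pid, f"orph{i}", sp, "chrS", None, _random_protein(200, rng)
        ))
        rows.append({
            "family": "", "protein_id": pid, "species": sp,
            "requested_identity_pct": float("nan"),
        })
    return proteins, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ready-made fixture specs (the study conditions of the acceptance checks)

def palindrome_fixture_spec(seed: int, chrom_length: int = 2_000_000) -> SynthSpec:
    """Three qualifying palindromes plus three decoys, each decoy breaking
    exactly one of the four calling thresholds.

    Qualifying: 10-kb arms at 1% divergence, spacers 20-100 kb.  Decoys:
    96%-identity arms (identity), 6-kb arms (arm length), 550-kb spacer
    (spacer), and an annotated-repeat blanket over 85% of the footprint
    (repetitive content).
    """
    spec = SynthSpec(chrom_name=f"chrFix{seed}", chrom_length=chrom_length, seed=seed)
    spec.palindromes = [
        PlantedPalindrome(position=100_000, arm_len=10_000, spacer_len=20_000, divergence=0.01),
        PlantedPalindrome(position=300_000, arm_len=12_000, spacer_len=50_000, divergence=0.005),
        PlantedPalindrome(position=500_000, arm_len=10_000, spacer_len=100_000, divergence=0.01),
        # decoys
        PlantedPalindrome(position=800_000, arm_len=10_000, spacer_len=20_000, divergence=0.04),
        PlantedPalindrome(position=900_000, arm_len=6_000, spacer_len=20_000, divergence=0.01),
        PlantedPalindrome(position=1_000_000, arm_len=10_000, spacer_len=550_000, divergence=0.01),
        PlantedPalindrome(position=1_700_000, arm_len=10_000, spacer_len=20_000, divergence=0.01),
    ]
    last = spec.palindromes[-1]
    foot_len = last.span
    cover = int(0.85 * foot_len)
    spec.repeats = [PlantedRepeat(last.position, last.position + cover, label="decoy_repeat")]
    return spec


def protein_fixture_specs() -> tuple[list[FamilySpec], dict[str, dict]]:
    """Family specs covering the calling rules, with expected outcomes.

    famAmp: a within-species pair at 98% -> called, ampliconic.
    famMulti: a within-species pair at 96% -> called, not ampliconic.
    famCross: best within-species pairs ~80%, a cross-species pair at
      99% -> called, not ampliconic (the 97% rule is within-species).
    famOrphan: one copy per species (cross-species homology only) ->
      removed by the within-species refinement.
    """
    specs = [
        FamilySpec("famAmp", [("sp1", 100.0), ("sp1", 98.0), ("sp2", 95.0)]),
        FamilySpec("famMulti", [("sp1", 100.0), ("sp1", 96.0), ("sp3", 90.0)]),
        FamilySpec("famCross", [("sp1", 100.0), ("sp2", 99.0),
                                ("sp1", 80.0), ("sp2", 80.0)]),
        FamilySpec("famOrphan", [("sp1", 100.0), ("sp2", 60.0), ("sp3", 60.0)]),
    ]
    expected = {
        "famAmp": {"called": True, "ampliconic": True, "n_members": 3},
        "famMulti": {"called": True, "ampliconic": False, "n_members": 3},
        "famCross": {"called": True, "ampliconic": False, "n_members": 4},
        "famOrphan": {"called": False, "ampliconic": False, "n_members": 0},
    }
    return specs, expected


def qualifying_truth(spec: SynthSpec) -> list[PlantedPalindrome]:
    """The planted palindromes that satisfy all four calling thresholds."""
    out = []
    covered = [(r.start, r.end) for r in spec.repeats]
    for p in spec.palindromes:
        if p.arm_len < 8_000 or p.spacer_len > 500_000:
            continue
        if (1 - p.divergence) * 100 < 98.0:
            continue
        foot = (p.position, p.position + p.span)
        rep = sum(max(0, min(foot[1], e) - max(foot[0], s)) for s, e in covered)
        if rep / (foot[1] - foot[0]) >= 0.80:
            continue
        out.append(p)
    return out
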