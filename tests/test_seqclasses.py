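import numpy as np
import pytest

from palindromekit import synth
from palindromekit.palindromes import Palindrome
from palindromekit.seqclasses import (
    ParParams,
    SegDupRecord,
    SeqClassAnnotation,
    WindowParams,
    ampliconic_windows,
    assign_classes,
    detect_par,
    filter_segdups,
    satellite_track,
)
from palindromekit.seqio import GenomicInterval, RepeatTrack, SequenceRecord


class TestDetectPar:
    def test_shared_terminal_block_recovered(self):
        x, y, truth = synth.generate_xy_pair(
            1_500_000, 1_000_000, par1_len=400_000, seed=41)
        par = detect_par(x, y)
        (ivx, namex), = par["X"]
        (ivy, namey), = par["Y"]
        assert namex == namey == "PAR1"
        assert abs(ivx.start) == 0 and abs(ivx.end - 400_000) <= 1_000
        assert abs(ivy.end - 400_000) <= 1_000

    def test_both_termini(self):
        x, y, _ = synth.generate_xy_pair(
            1_200_000, 900_000, par1_len=300_000, par2_len=150_000, seed=42)
        par = detect_par(x, y)
        names = [n for _, n in par["Y"]]
        assert names == ["PAR1", "PAR2"]
        (p1, _), (p2, _) = par["Y"]
        assert abs(p1.end - 300_000) <= 1_000
        assert abs((len(y) - p2.start) - 150_000) <= 1_000

    def test_non_homologous_chromosomes_warn_and_report_nothing(self, rng):
        x = SequenceRecord("chrX", synth.random_sequence(300_000, rng))
        y = SequenceRecord("chrY", synth.random_sequence(300_000, rng))
        with pytest.warns(UserWarning, match="no terminal"):
            par = detect_par(x, y)
        assert par == {"X": [], "Y": []}

    def test_diverged_par_still_found_at_tolerant_identity(self):
        x, y, _ = synth.generate_xy_pair(
            800_000, 600_000, par1_len=200_000, haplotype_divergence=0.005,
            seed=43)
        par = detect_par(x, y, ParParams(min_identity_pct=98.0))
        (ivy, _), = par["Y"]
        assert abs(ivy.end - 200_000) <= 2_000


class TestSatelliteTrack:
    def test_merge_within_gap(self):
        track = RepeatTrack([GenomicInterval("c", 0, 200_000),
                             GenomicInterval("c", 200_900, 260_000)])
        assert satellite_track(track) == [GenomicInterval("c", 0, 260_000)]

    def test_exact_threshold_span_excluded(self):
        track = RepeatTrack([GenomicInterval("c", 0, 250_000)])
        assert satellite_track(track) == []

    def test_gap_just_over_limit_not_merged(self):
        track = RepeatTrack([GenomicInterval("c", 0, 200_000),
                             GenomicInterval("c", 201_001, 401_001)])
        assert satellite_track(track) == []

    def test_gap_exactly_limit_merged(self):
        track = RepeatTrack([GenomicInterval("c", 0, 200_000),
                             GenomicInterval("c", 201_000, 300_000)])
        assert satellite_track(track) == [GenomicInterval("c", 0, 300_000)]

    def test_invariant_to_order_and_fragmentation(self, rng):
        base = [GenomicInterval("c", 0, 100_000),
                GenomicInterval("c", 100_500, 300_000)]
        fragmented = ([GenomicInterval("c", s, s + 10_000) for s in range(0, 100_000, 10_000)]
                      + [GenomicInterval("c", s, min(s + 10_000, 300_000))
                         for s in range(100_500, 300_000, 10_000)])
        shuffled = list(fragmented)
        rng.shuffle(shuffled)
        assert (satellite_track(RepeatTrack(base))
                == satellite_track(RepeatTrack(fragmented))
                == satellite_track(RepeatTrack(shuffled)))

    def test_label_filter(self):
        track = RepeatTrack(
            [GenomicInterval("c", 0, 300_000), GenomicInterval("c", 400_000, 700_000)],
            ["alpha", "LINE"])
        assert satellite_track(track, label_filter={"alpha"}) == \
            [GenomicInterval("c", 0, 300_000)]


@pytest.fixture(scope="module")
def dup_fixture():
    spec = synth.SynthSpec(chrom_name="chrA", chrom_length=1_000_000, seed=51)
    spec.duplications = [
        synth.PlantedDuplication(100_000, 120_000, 500_000, divergence=0.05),
        synth.PlantedDuplication(300_000, 60_000, 700_000, divergence=0.05),
    ]
    record, track, truth = synth.generate_chromosome(spec)
    amp, hits = ampliconic_windows(record, track)
    return spec, amp, hits


class TestAmpliconicWindows:
    def test_120kb_duplication_recovered_at_both_loci(self, dup_fixture):
        spec, amp, _ = dup_fixture
        for locus in (100_000, 500_000):
            assert any(iv.start <= locus and iv.end >= locus + 110_000 for iv in amp), \
                f"locus {locus} not recovered: {amp}"

    def test_60kb_duplication_excluded(self, dup_fixture):
        spec, amp, _ = dup_fixture
        for locus in (300_000, 700_000):
            assert not any(iv.start <= locus + 30_000 < iv.end for iv in amp)

    def test_symmetry_of_qualifying_windows(self, dup_fixture):
        """If locus A qualifies because of B, B's windows also qualify."""
        _, _, hits = dup_fixture
        q = {h["window"].start: h["qualifies"] for h in hits}
        for off in range(0, 120_000, 5_000):
            assert q.get(100_000 + off) == q.get(500_000 + off)

    def test_min_span_monotonicity(self, dup_fixture):
        spec, amp, _ = dup_fixture
        record, track, _ = synth.generate_chromosome(spec)
        bigger, _ = ampliconic_windows(record, track,
                                       WindowParams(min_span_bp=150_000))
        amp_bases = sum(len(iv) for iv in amp)
        assert sum(len(iv) for iv in bigger) <= amp_bases

    def test_excluded_regions_never_qualify(self, dup_fixture):
        spec, _, _ = dup_fixture
        record, track, _ = synth.generate_chromosome(spec)
        amp, hits = ampliconic_windows(
            record, track, exclude=[GenomicInterval("chrA", 0, 250_000)])
        assert not any(h["qualifies"] for h in hits if h["window"].start < 250_000)
        assert not any(iv.start < 250_000 for iv in amp)

    def test_bad_window_size_rejected(self, rng):
        rec = SequenceRecord("c", synth.random_sequence(20_000, rng))
        with pytest.raises(ValueError):
            ampliconic_windows(rec, RepeatTrack(), WindowParams(window_bp=0))


class TestAssignClasses:
    def _pal(self, chrom, a1s, arm, spacer):
        a1e = a1s + arm
        a2s, a2e = a1e + spacer, a1e + spacer + arm
        return Palindrome("p", chrom, GenomicInterval(chrom, a1s, a1e),
                          GenomicInterval(chrom, a2s, a2e),
                          GenomicInterval(chrom, a1e, a2s) if spacer else None,
                          99.0, 0.0)

    def test_perfect_tiling_on_random_fixtures(self, rng):
        for _ in range(100):
            L = int(rng.integers(100_000, 500_000))
            par, sat, amp, pals = [], [], [], []
            if rng.random() < 0.8:
                par.append((GenomicInterval("c", 0, int(rng.integers(10_000, 50_000))),
                            "PAR1"))
            if rng.random() < 0.7:
                s = int(rng.integers(50_000, L - 60_000))
                sat.append(GenomicInterval("c", s, s + int(rng.integers(5_000, 50_000))))
            if rng.random() < 0.7:
                s = int(rng.integers(40_000, L - 50_000))
                amp.append(GenomicInterval("c", s, s + int(rng.integers(5_000, 40_000))))
            if rng.random() < 0.5:
                a1s = int(rng.integers(30_000, L - 50_000))
                pals.append(self._pal("c", a1s, 5_000, 8_000))
            ann = assign_classes(L, "c", par=par, sat=sat, amp_candidates=amp,
                                 palindromes=pals)
            ann.validate()  # zero gap, zero overlap by construction of validate
            # independent per-base check
            mask = np.zeros(L, dtype=np.int16)
            for iv, _ in ann.segments:
                mask[iv.start:iv.end] += 1
            assert (mask == 1).all()

    def test_precedence_par_over_sat(self):
        ann = assign_classes(
            100_000, "c",
            par=[(GenomicInterval("c", 0, 30_000), "PAR1")],
            sat=[GenomicInterval("c", 20_000, 50_000)])
        assert ann.class_of_position(25_000) == "PAR"
        assert ann.class_of_position(35_000) == "SAT"

    def test_amp_is_union_of_palindromes_and_candidates(self):
        pal = self._pal("c", 10_000, 5_000, 2_000)
        ann = assign_classes(
            100_000, "c", amp_candidates=[GenomicInterval("c", 50_000, 70_000)],
            palindromes=[pal])
        assert ann.class_of_position(15_000) == "AMP"   # arm
        assert ann.class_of_position(16_000) == "AMP"   # spacer included
        assert ann.class_of_position(60_000) == "AMP"   # candidate
        assert ann.class_of_position(90_000) == "ANC"

    def test_y_gene_refinement_assigns_amp(self):
        genes = RepeatTrack([GenomicInterval("c", 40_000, 42_000),
                             GenomicInterval("c", 80_000, 82_000)],
                            ["ampliconic", "ancestral"])
        ann = assign_classes(
            100_000, "c", sat=[GenomicInterval("c", 0, 20_000)],
            gene_track=genes, is_y=True)
        # the ANC run [20k,100k) overlaps an ampliconic gene -> AMP
        assert ann.class_of_position(50_000) == "AMP"

    def test_y_gene_refinement_keeps_ancestral_runs(self):
        genes = RepeatTrack([GenomicInterval("c", 80_000, 82_000)], ["ancestral"])
        ann = assign_classes(100_000, "c", sat=[GenomicInterval("c", 0, 20_000)],
                             gene_track=genes, is_y=True)
        assert ann.class_of_position(50_000) == "ANC"

    def test_input_past_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="past chromosome"):
            assign_classes(10_000, "c", sat=[GenomicInterval("c", 5_000, 20_000)])

    def test_validate_rejects_gap(self):
        ann = SeqClassAnnotation("c", 100, [(GenomicInterval("c", 0, 50), "ANC"),
                                           (GenomicInterval("c", 60, 100), "ANC")])
        with pytest.raises(ValueError, match="tiling"):
            ann.validate()


class TestSegDupFilter:
    def _rec(self, identity, length, sat):
        return SegDupRecord(
            locus_a=GenomicInterval("c", 0, length),
            locus_b=GenomicInterval("c", 100_000, 100_000 + length),
            identity_pct=identity, satellite_fraction=sat)

    @pytest.mark.parametrize("identity,length,sat,kept", [
        (89.0, 5_000, 0.10, False),   # identity too low
        (95.0, 900, 0.10, False),     # too short
        (95.0, 2_000, 0.75, False),   # too satellite-rich
        (95.0, 2_000, 0.10, True),
        (90.0, 2_000, 0.10, False),   # boundary strict: >90 required
        (95.0, 1_000, 0.10, False),   # boundary strict: >1 kb required
        (95.0, 2_000, 0.70, False),   # boundary strict: <70% required
    ])
    def test_rules_all_strict(self, identity, length, sat, kept):
        recs = [self._rec(identity, length, sat)]
        assert (len(filter_segdups(recs)) == 1) is kept
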