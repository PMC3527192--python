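"""Precursor windows, star finding, duplex criteria and read signatures."""

from __future__ import annotations

import numpy as np
import pytest

from mircross.config import PipelineConfig, revcomp
from mircross.folding import BASELINE_ENGINE, fold_baseline
from mircross.hairpin import (
    HairpinCandidate,
    PrecursorWindow,
    call_mirnas,
    check_plant_criteria,
    duplex_report,
    extract_window,
    find_star,
    merge_loci,
    signature_consistency,
    trim_and_refold,
)
from mircross.mapping import Alignment
from mircross.preprocess import CleanTag
from mircross.simulate import (
    SimulationConfig,
    generate_genome,
    random_mature,
    synthesize_precursor,
)


def make_genome(rng, n=10_000):
    return {"chr1": "".join(rng.choice(list("ACGT"), size=n))}


class TestExtractWindow:
    def test_central_tag_window_length(self, rng):
        genome = make_genome(rng)
        aln = Alignment(genome["chr1"][5000:5021], "chr1", 5000, "+")
        w = extract_window(aln, genome, 500)
        assert len(w.sequence) == 1021 and w.mature_offset == 500

    def test_left_clipped_window(self, rng):
        genome = make_genome(rng)
        aln = Alignment(genome["chr1"][100:121], "chr1", 100, "+")
        w = extract_window(aln, genome, 500)
        assert len(w.sequence) == 621 and w.mature_offset == 100

    def test_minus_strand_round_trip(self, rng):
        """Re-extracting from the reverse-complemented genome on + gives the
        identical window sequence and offset."""
        genome = make_genome(rng)
        n = len(genome["chr1"])
        start = 4000
        tag_rc = revcomp(genome["chr1"][start : start + 21])
        aln = Alignment(tag_rc, "chr1", start, "-")
        w = extract_window(aln, genome, 500)
        mirror = {"chr1": revcomp(genome["chr1"])}
        m_start = n - (start + 21)
        aln2 = Alignment(tag_rc, "chr1", m_start, "+")
        w2 = extract_window(aln2, mirror, 500)
        assert w.sequence == w2.sequence
        assert w.mature_offset == w2.mature_offset

    def test_out_of_bounds_raises(self, rng):
        genome = make_genome(rng, 100)
        with pytest.raises(ValueError):
            extract_window(Alignment("A" * 21, "chr1", 90, "+"), genome, 10)


class TestFindStar:
    def test_planted_star_recovered(self, rng):
        mature = random_mature(rng)
        precursor, star_seq, star_off = synthesize_precursor(mature, 0, 0, 10, rng)
        structure, _ = fold_baseline(precursor)
        found = find_star(structure, (0, len(mature)))
        assert found is not None
        start, length = found
        assert abs(start - star_off) <= 2
        assert abs((start + length) - (star_off + len(star_seq))) <= 2

    def test_mature_in_terminal_loop_is_none(self):
        #           0123456789012345678901234567890
        structure = "((((((......................))))))"
        # mature right in the loop: nothing to pair with
        assert find_star(structure, (8, 18)) is None

    def test_low_pairing_is_none(self):
        structure = "((((" + "." * 30 + "))))"
        # only 4 of 21 mature bases are paired: below the 50% floor
        assert find_star(structure, (0, 21)) is None


class TestTrimRefold:
    def test_trim_arithmetic(self, rng):
        window = "".join(rng.choice(list("ACGT"), size=700))
        pre, _, _, mat, star, lo = trim_and_refold(
            window, (480, 21), (560, 21), BASELINE_ENGINE, 15
        )
        assert lo == 465 and lo + len(pre) == 596
        assert mat == (15, 21) and star == (95, 21)

    def test_margin_larger_than_window(self, rng):
        window = "".join(rng.choice(list("ACGT"), size=100))
        pre, *_ = trim_and_refold(window, (10, 21), (60, 21), BASELINE_ENGINE, 500)
        assert pre == window

    def test_trim_preserves_planted_duplex_pass(self, rng):
        for _ in range(5):
            mature = random_mature(rng)
            precursor, star_seq, star_off = synthesize_precursor(mature, 1, 0, 12, rng)
            flank_l = "".join(rng.choice(list("ACGT"), size=60))
            flank_r = "".join(rng.choice(list("ACGT"), size=60))
            window = flank_l + precursor + flank_r
            m = (len(flank_l), len(mature))
            structure, _ = fold_baseline(window)
            star = find_star(structure, m)
            if star is None:
                continue
            pre, st, en, m2, s2, _ = trim_and_refold(window, m, star,
                                                     BASELINE_ENGINE, 15)
            rep = duplex_report(st, m2, s2)
            assert rep.mismatches <= 4
            assert rep.paired_fraction_mature >= 0.5


class TestDuplexReport:
    def fold_planted(self, rng, k, bulge):
        mature = random_mature(rng)
        precursor, star_seq, star_off = synthesize_precursor(
            mature, k, bulge, 10, rng
        )
        structure, _ = fold_baseline(precursor)
        star = find_star(structure, (0, len(mature)))
        assert star is not None
        return duplex_report(structure, (0, len(mature)), star)

    def test_perfect_duplex(self, rng):
        rep = self.fold_planted(rng, 0, 0)
        assert rep.mismatches == 0
        assert rep.largest_asymmetric_bulge == 0
        assert rep.overhang_3p_mature == 2
        assert rep.overhang_3p_star in (1, 2, 3)

    def test_planted_mismatches_counted(self, rng):
        # the generator guarantees the fold never shows more mismatches than
        # planted; most draws retain at least one (the fold may absorb some
        # imperfections into bulges or shifted pairing)
        hits = 0
        for _ in range(20):
            rep = self.fold_planted(rng, 3, 0)
            assert rep.mismatches <= 3
            hits += rep.mismatches >= 1
        assert hits >= 10

    def test_planted_bulge_detected(self, rng):
        seen = []
        for _ in range(20):
            rep = self.fold_planted(rng, 0, 2)
            seen.append(rep.largest_asymmetric_bulge)
            assert rep.largest_asymmetric_bulge <= 2
        assert max(seen) >= 1


def make_candidate(rng, mismatches=0, structure_override=None,
                   star_override=None):
    mature = random_mature(rng)
    precursor, star_seq, star_off = synthesize_precursor(mature, mismatches, 0, 10, rng)
    structure, energy = fold_baseline(precursor)
    star = star_override or find_star(structure, (0, len(mature)))
    rep = duplex_report(structure, (0, len(mature)), star)
    window = PrecursorWindow("chr1", 0, len(precursor), "+", precursor, 0,
                             len(mature))
    return HairpinCandidate(
        window=window, precursor_sequence=precursor,
        precursor_interval=(0, len(precursor)),
        structure=structure_override or structure, energy=energy,
        mature=(0, len(mature)), star=star, duplex=rep,
        mature_sequence=mature, mature_count=100,
    )


class TestPlantCriteria:
    def test_generator_valid_candidate_passes(self, rng):
        cand = make_candidate(rng, 0)
        ok, reasons = check_plant_criteria(cand)
        assert ok, reasons

    def test_excess_mismatches_fail(self, rng):
        cand = make_candidate(rng, 0)
        cand.duplex.mismatches = 5
        ok, reasons = check_plant_criteria(cand)
        assert not ok and "duplex_mismatches" in reasons

    def test_overlapping_arms_fail(self, rng):
        cand = make_candidate(rng, 0)
        cand.star = (5, 21)  # overlaps the mature at (0, 21)
        ok, reasons = check_plant_criteria(cand)
        assert not ok and "arm_overlap" in reasons


class TestSignature:
    def test_all_reads_at_mature_end(self):
        reads = [(500, 100)]
        assert signature_consistency(reads, 500, 560) == 1.0

    def test_uniform_reads_reject(self, rng):
        positions = rng.integers(0, 1021, size=1_000)
        reads = [(int(p), 1) for p in positions]
        consistency = signature_consistency(reads, 500, 560)
        direct = sum(
            1 for p, _ in reads
            if abs(p - 500) <= 2 or abs(p - 560) <= 2
        ) / len(reads)
        assert consistency == pytest.approx(direct)
        assert consistency < 0.05   # ~10/1021 expected

    def test_copy_gate_is_strict(self, rng):
        """A mature with exactly 25 pooled copies is skipped before folding."""
        mature = random_mature(rng)
        precursor, *_ = synthesize_precursor(mature, 0, 0, 10, rng)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=400))
                  + precursor + "".join(rng.choice(list("ACGT"), size=400))}
        aln = Alignment(mature, "chr1", 400, "+")
        reps = [(aln, CleanTag(mature, 25, "pooled"))]
        assert call_mirnas(reps, genome, BASELINE_ENGINE) == []
        found = call_mirnas(
            reps, genome, BASELINE_ENGINE,
            counts={mature: 26},
        )
        assert len(found) == 1


class TestCallMirnas:
    def test_empty_input(self, rng):
        genome = make_genome(rng, 1000)
        assert call_mirnas([], genome, BASELINE_ENGINE) == []

    def test_background_only_no_candidates(self, rng):
        """Random tags on a random genome yield no accepted precursor.

        Uses the thermodynamic engine (the discovery default): random windows
        occasionally satisfy the purely structural duplex criteria under
        maximum-pairing folding, but not the energy criterion."""
        from mircross.folding import get_engine

        genome = make_genome(rng, 30_000)
        reps = []
        for i in range(30):
            start = int(rng.integers(0, 29_000))
            tag = genome["chr1"][start : start + 21]
            reps.append((Alignment(tag, "chr1", start, "+"),
                         CleanTag(tag, 100, "pooled")))
        out = call_mirnas(reps, genome, get_engine("rnafold"))
        assert sum(c.accepted for c in out) == 0
        # with realistic (low) background counts the copy gate alone blocks
        low = [(a, CleanTag(t.sequence, 2, "pooled")) for a, t in reps]
        assert call_mirnas(low, genome, BASELINE_ENGINE) == []

    def test_merging_idempotent(self, rng):
        cands = [make_candidate(rng, 0) for _ in range(4)]
        for i, c in enumerate(cands):
            c.precursor_interval = (i * 10, i * 10 + 60)  # overlapping chain
        merged = merge_loci(cands)
        assert merge_loci(merged) == merged
        assert len(merged) == 1
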