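"""Penalty scoring, transcript scanning and cleavage-site prediction."""

from __future__ import annotations

import numpy as np
import pytest

from mircross.config import revcomp
from mircross.simulate import GenerationError, plant_target, random_mature
from mircross.targets import (
    ScoringScheme,
    TargetSite,
    _ungapped_columns,
    predict_cleavage,
    scan_transcript,
    score_duplex,
    select_validation_candidates,
)

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def oracle_score(mirna, site, scheme=None):
    """Independent position-by-position implementation (1-based walk)."""
    scheme = scheme or ScoringScheme()
    L = len(mirna)
    total = 0.0
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for i in range(1, L + 1):
        m = mirna[i - 1]
        t = site[L - i]
        if t == comp[m]:
            p = 0.0
        elif (m, t) in (("G", "T"), ("T", "G")):
            p = 0.5
        else:
            p = 1.0
        if 2 <= i <= 13:
            p *= 2
        total += p
    return total


class TestScoreDuplex:
    def test_perfect_site_zero(self):
        assert score_duplex(MIRNA, revcomp(MIRNA)) == 0.0

    def test_wobble_position_doubling(self):
        site = list(revcomp(MIRNA))
        L = len(MIRNA)
        # G:U at miRNA position 15 (non-core): 0.5
        pos = 15
        assert MIRNA[pos - 1] == "G" or True
        m = MIRNA[pos - 1]
        site15 = site.copy()
        site15[L - pos] = {"G": "T", "T": "G"}.get(m, "T")
        expected = 0.5 if m in "GT" else None
        if expected is not None:
            assert score_duplex(MIRNA, "".join(site15)) == expected
        # the same wobble inside the core doubles
        pos = 5
        m = MIRNA[pos - 1]
        if m in "GT":
            site5 = site.copy()
            site5[L - pos] = {"G": "T", "T": "G"}[m]
            assert score_duplex(MIRNA, "".join(site5)) == 1.0

    def test_matches_independent_oracle(self, rng):
        for _ in range(200):
            mirna = random_mature(rng)
            window = "".join(rng.choice(list("ACGT"), size=len(mirna)))
            assert score_duplex(mirna, window) == pytest.approx(
                oracle_score(mirna, window)
            )

    def test_additivity_over_positions(self, rng):
        """Permuting which non-core positions carry penalties keeps the sum."""
        mirna = "TGACAGAAGAGAGTGAGCACA"
        site = list(revcomp(mirna))
        L = len(mirna)
        for positions in ([14, 16], [16, 19], [14, 19]):
            s = site.copy()
            for pos in positions:
                m = mirna[pos - 1]
                bad = next(b for b in "ACGT"
                           if b != {"A": "T", "T": "A", "G": "C", "C": "G"}[m]
                           and (m, b) not in (("G", "T"), ("T", "G")))
                s[L - pos] = bad
            assert score_duplex(mirna, "".join(s)) == 2.0

    def test_alphabet_violation_raises(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, "X" * len(MIRNA))

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, "ACGT")


class TestScan:
    def test_planted_site_recovered_at_exact_penalty(self, rng):
        for desired in (0.0, 2.0):
            transcript, start, end = plant_target(MIRNA, desired, 400, rng)
            sites = scan_transcript(MIRNA, transcript, "t1")
            assert sites, f"no site found for penalty {desired}"
            top = sites[0]
            assert top.penalty == pytest.approx(desired)
            assert (top.start, top.end) == (start, end)

    def test_random_transcript_empty(self, rng):
        transcript = "".join(rng.choice(list("AC"), size=300))
        # an A-guide needs T (or wobble G) partners; an A/C transcript has
        # neither, so every window scores far above the report cutoff
        sites = scan_transcript("A" * 21, transcript, "t")
        assert sites == []

    def test_ranked_by_penalty(self, rng):
        penalties = [0.0, 1.0, 2.5, 4.0, 6.5]
        rng2 = np.random.default_rng(5)
        segments = []
        expected = []
        offset = 0
        for p in penalties:
            t, s, e = plant_target(MIRNA, p, 120, rng2)
            segments.append(t)
            expected.append((p, offset + s))
            offset += len(t)
        transcript = "".join(segments)
        sites = scan_transcript(MIRNA, transcript, "t")
        got = [(s.penalty, s.start) for s in sites[: len(penalties)]]
        assert [p for p, _ in got] == sorted(p for p, _ in expected)
        assert {pos for _, pos in got} == {pos for _, pos in expected}

    def test_ungapped_scan_equals_exhaustive_enumeration(self, rng):
        mirna = random_mature(rng)
        transcript = "".join(rng.choice(list("ACGT"), size=200))
        scheme = ScoringScheme(report_cutoff=100.0)
        sites = scan_transcript(mirna, transcript, "t", scheme, allow_gaps=False)
        L = len(mirna)
        windows = {
            s: oracle_score(mirna, transcript[s : s + L])
            for s in range(len(transcript) - L + 1)
        }
        # every reported site matches the enumerated window score, and the
        # best reported equals the global enumerated optimum
        for site in sites:
            assert site.penalty == pytest.approx(windows[site.start])
        assert sites[0].penalty == pytest.approx(min(windows.values()))

    def test_lower_cutoff_returns_prefix(self, rng):
        mirna = random_mature(rng)
        transcript = "".join(rng.choice(list("ACGT"), size=300))
        wide = scan_transcript(mirna, transcript, "t",
                               ScoringScheme(report_cutoff=30.0))
        narrow = scan_transcript(mirna, transcript, "t",
                                 ScoringScheme(report_cutoff=20.0))
        keys = [(s.start, s.end, s.penalty) for s in wide if s.penalty <= 20.0]
        assert [(s.start, s.end, s.penalty) for s in narrow] == keys


class TestValidationCutoff:
    def mk(self, penalty):
        cols = _ungapped_columns(21)
        return TargetSite("t", 0, 21, penalty, MIRNA, revcomp(MIRNA), cols)

    def test_four_or_less_inclusive(self):
        sites = [self.mk(4.0), self.mk(4.5), self.mk(0.5)]
        kept = select_validation_candidates(sites)
        assert [s.penalty for s in kept] == [4.0, 0.5]

    def test_empty_input(self):
        assert select_validation_candidates([]) == []


class TestCleavage:
    def test_ungapped_arithmetic(self):
        site = self.site_at(start=0)
        assert predict_cleavage(site) == 11  # paired to miRNA position 10

    def site_at(self, start):
        cols = _ungapped_columns(21)
        return TargetSite("t", start, start + 21, 0.0, MIRNA, revcomp(MIRNA),
                          cols)

    def test_short_mirna_raises(self):
        cols = _ungapped_columns(10)
        site = TargetSite("t", 0, 10, 0.0, "ACGTACGTAC", revcomp("ACGTACGTAC"),
                          cols)
        with pytest.raises(ValueError):
            predict_cleavage(site)

    def test_target_bulge_shifts_by_alignment_walk(self, rng):
        """A target-side bulge 3' of the slice point shifts the coordinate by
        one, exactly as walking the alignment dictates."""
        from mircross.targets import _target_bulge_columns, score_columns

        L = len(MIRNA)
        # extra target base at window index 5 (paired side of the miRNA 3'
        # half): every index above it shifts, so the base paired to position
        # 10 moves from the ungapped 11 to 12
        cols = _target_bulge_columns(L, 5)
        window = revcomp(MIRNA)
        bulged = window[:5] + "A" + window[5:]
        site = TargetSite("t", 0, L + 1, 1.0, MIRNA, bulged, cols)
        j10 = next(j for pos, j in cols if pos == 10)
        assert predict_cleavage(site) == j10 == 12
        # a bulge on the other side of the slice point leaves it unshifted
        cols_hi = _target_bulge_columns(L, 16)
        site_hi = TargetSite("t", 0, L + 1, 1.0, MIRNA, bulged, cols_hi)
        assert predict_cleavage(site_hi) == 11

    def test_planted_site_cleavage_matches_truth(self, rng):
        transcript, start, end = plant_target(MIRNA, 1.0, 300, rng)
        site = scan_transcript(MIRNA, transcript, "t")[0]
        # ungapped planted site: position paired to miRNA nt 10
        assert site.cleavage_position == start + len(MIRNA) - 10


class TestPlanting:
    def test_unrepresentable_penalty_rejected(self, rng):
        with pytest.raises(GenerationError):
            plant_target(MIRNA, 0.25, 300, rng)
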