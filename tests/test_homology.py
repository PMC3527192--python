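"""Catalogue matching, conserved/novel classification and family grouping."""

from __future__ import annotations

import pytest

from mircross.homology import (
    STATUS_CONSERVED,
    STATUS_NOVEL,
    STATUS_RESCUED,
    AnnotatedMiRNA,
    KnownMiRNA,
    batch_match_known,
    classify_candidates,
    group_families,
    match_known,
    parse_family,
    rescue_unmapped,
    _overlap_mismatches,
)
from mircross.simulate import make_catalogue, random_mature


def brute_force_best(seq, catalogue, max_mm, max_shift):
    """Exhaustive enumeration over every entry and shift."""
    best = None
    for known in catalogue:
        for shift in range(-max_shift, max_shift + 1):
            mm = _overlap_mismatches(seq, known.sequence, shift)
            if mm <= max_mm:
                key = (mm, abs(shift), known.name, shift)
                if best is None or key < best:
                    best = key
    return best


class TestParseFamily:
    @pytest.mark.parametrize(
        "name,family",
        [
            ("miR156a", "miR156"),
            ("miR156f", "miR156"),
            ("ath-miR172c-3p", "miR172"),
            ("MIR399b", "miR399"),
            ("weird-name", "weird-name"),
        ],
    )
    def test_examples(self, name, family):
        assert parse_family(name) == family


class TestMatchKnown:
    def catalogue(self, rng):
        return make_catalogue(rng, n_entries=50)

    def test_identical_tag_perfect_hit(self, rng):
        cat = self.catalogue(rng)
        hit = match_known(cat[3].sequence, cat)
        assert hit.known_name == cat[3].name
        assert hit.mismatches == 0 and hit.offset_shift == 0

    def test_distance_three_from_everything_is_none(self, rng):
        cat = self.catalogue(rng)
        seq = list(cat[0].sequence)
        for i in (2, 8, 14):  # 3 mutations; catalogue spacing >= 5 keeps others far
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        assert match_known("".join(seq), cat, max_mm=2) is None

    def test_empty_catalogue_raises(self):
        with pytest.raises(ValueError):
            match_known("ACGT" * 5 + "A", [])

    def test_matches_brute_force_enumeration(self, rng):
        cat = self.catalogue(rng)
        for _ in range(100):
            if rng.random() < 0.5:
                seq = random_mature(rng)
            else:  # near-catalogue tag
                base = list(cat[int(rng.integers(len(cat)))].sequence)
                for i in rng.choice(len(base), size=int(rng.integers(0, 4)),
                                    replace=False):
                    base[i] = "ACGT"[int(rng.integers(4))]
                seq = "".join(base)
            hit = match_known(seq, cat)
            expect = brute_force_best(seq, cat, 2, 2)
            if expect is None:
                assert hit is None
            else:
                assert (hit.mismatches, abs(hit.offset_shift), hit.known_name,
                        hit.offset_shift) == expect

    def test_batch_agrees_with_scalar(self, rng):
        cat = self.catalogue(rng)
        seqs = [random_mature(rng) for _ in range(40)] + [
            cat[i].sequence for i in range(5)
        ]
        batch = batch_match_known(seqs, cat)
        for s in seqs:
            scalar = match_known(s, cat)
            got = batch[s]
            if scalar is None:
                assert got is None
            else:
                assert (got.known_name, got.mismatches, got.offset_shift) == (
                    scalar.known_name, scalar.mismatches, scalar.offset_shift
                )

    def test_monotone_in_max_mm(self, rng):
        cat = self.catalogue(rng)
        for _ in range(30):
            seq = random_mature(rng)
            for mm in range(3):
                lo = match_known(seq, cat, max_mm=mm)
                hi = match_known(seq, cat, max_mm=mm + 1)
                if lo is not None:
                    assert hi is not None and hi.mismatches <= lo.mismatches


class TestClassification:
    def test_planted_partition(self, rng):
        cat = make_catalogue(rng, n_entries=20)
        conserved = [cat[i].sequence for i in range(10)]
        invented = []
        while len(invented) < 5:
            m = random_mature(rng)
            if brute_force_best(m, cat, 2, 2) is None:
                invented.append(m)
        annotated = classify_candidates(conserved + invented, cat)
        statuses = [m.status for m in annotated]
        assert statuses[:10] == [STATUS_CONSERVED] * 10
        assert statuses[10:] == [STATUS_NOVEL] * 5

    def test_classification_idempotent(self, rng):
        cat = make_catalogue(rng, n_entries=10)
        seqs = [cat[0].sequence, random_mature(rng)]
        once = classify_candidates(seqs, cat)
        twice = classify_candidates([m.sequence for m in once], cat)
        assert [m.status for m in once] == [m.status for m in twice]

    def test_rescue_keeps_catalogue_tags_only(self, rng):
        cat = make_catalogue(rng, n_entries=20)
        planted = [cat[i].sequence for i in range(5)]
        background = []
        while len(background) < 20:
            m = random_mature(rng)
            if brute_force_best(m, cat, 2, 2) is None:
                background.append(m)
        rescued = rescue_unmapped(planted + background, cat)
        assert len(rescued) == 5
        assert all(m.status == STATUS_RESCUED for m in rescued)
        assert {m.sequence for m in rescued} == set(planted)


class TestFamilies:
    def mk(self, seq, status=STATUS_CONSERVED, family="", total=10):
        m = AnnotatedMiRNA(seq, status, family=family)
        m.counts = {"s1": total}
        return m

    def test_conserved_variants_share_family(self, rng):
        a = self.mk(random_mature(rng), family="miR156")
        b = self.mk(random_mature(rng), family="miR156")
        fams = group_families([a, b])
        assert len(fams) == 1 and fams[0].name == "miR156"
        assert fams[0].counts == {"s1": 20}

    def test_single_mismatch_novels_cluster(self):
        seq = "TGACAGAAGAGAGTGAGCACA"
        variant = seq[:5] + "C" + seq[6:]
        a = self.mk(seq, STATUS_NOVEL, total=50)
        b = self.mk(variant, STATUS_NOVEL, total=5)
        fams = group_families([a, b])
        assert len(fams) == 1 and fams[0].name == "Ng1"
        assert fams[0].major.sequence == seq

    def test_clusters_match_single_linkage_oracle(self, rng):
        novels = [self.mk(random_mature(rng), STATUS_NOVEL,
                          total=int(rng.integers(1, 100))) for _ in range(25)]
        fams = group_families(novels)

        # brute-force single linkage
        from mircross.homology import _novel_linked
        import itertools

        parent = {id(m): id(m) for m in novels}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(novels, 2):
            if _novel_linked(a.sequence, b.sequence):
                parent[find(id(a))] = find(id(b))
        expected_clusters = {}
        for m in novels:
            expected_clusters.setdefault(find(id(m)), set()).add(m.sequence)
        got_clusters = {}
        for f in fams:
            got_clusters[f.name] = {m.sequence for m in f.members}
        assert sorted(map(sorted, expected_clusters.values())) == sorted(
            map(sorted, got_clusters.values())
        )
        # every miRNA in exactly one family; counts add up
        all_members = [m for f in fams for m in f.members]
        assert len(all_members) == len(novels)
        assert sum(f.counts["s1"] for f in fams) == sum(
            m.total_count for m in novels
        )
        # Ng numbering follows descending total count
        totals = [sum(m.total_count for m in f.members) for f in fams]
        assert totals == sorted(totals, reverse=True)
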