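"""Hairpin precursor discovery and validation.

For every mapped, sufficiently expressed representative tag the pipeline cuts
a genomic window (tag +/- 500 bp by default, in transcription orientation),
folds it, locates the partner strand (miRNA*) implied by the base pairing of
the mature arm, trims to the mature/star duplex +/- 15 bp and refolds, and
then judges the refolded precursor against plant miRNA annotation criteria:
18-26 nt mature, at most 4 duplex mismatches, no asymmetric bulge larger than
2 nt, both arms on a single stem, and ~2-nt 3' overhangs on both duplex ends
(1-3 nt tolerated).  A read-signature filter then requires the locus to be
expressed above the copy-number gate (> 25 reads) with most window reads
stacking at the mature or star 5' end, the footprint Dicer-like processing
leaves in sRNA data.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .config import PipelineConfig, revcomp
from .folding import FoldingEngine, pair_table
from .mapping import Alignment
from .preprocess import CleanTag


@dataclass
class PrecursorWindow:
    """Genomic window around a mapped tag, in transcription orientation."""

    seq_id: str
    start: int   # genomic, 0-based half-open, + strand coordinates
    end: int
    strand: str
    sequence: str
    mature_offset: int  # 0-based offset of the tag within `sequence`
    mature_length: int

    def __post_init__(self) -> None:
        if self.mature_offset + self.mature_length > len(self.sequence):
            raise ValueError("mature extends past window")


@dataclass
class DuplexReport:
    mismatches: int
    largest_asymmetric_bulge: int
    overhang_3p_mature: int
    overhang_3p_star: int
    paired_fraction_mature: float


@dataclass
class HairpinCandidate:
    window: PrecursorWindow
    precursor_sequence: str
    precursor_interval: Tuple[int, int]      # genomic, 0-based half-open
    structure: str                           # dot-bracket of the precursor
    energy: float
    mature: Tuple[int, int]                  # (offset, length) in precursor coords
    star: Optional[Tuple[int, int]]
    duplex: Optional[DuplexReport]
    mature_sequence: str
    mature_count: int
    signature_consistency: float = 0.0
    accepted: bool = False
    rejection_reasons: List[str] = field(default_factory=list)


def extract_window(
    alignment: Alignment, genome: Mapping[str, str], margin: int = 500
) -> PrecursorWindow:
    """Cut the genomic window tag +/- margin, clipped at contig ends.

    Minus-strand windows are reverse complemented so the tag reads in sense
    orientation; ``mature_offset`` is mapped accordingly.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    seq = genome[alignment.seq_id].upper()
    n = len(seq)
    if not (0 <= alignment.start and alignment.end <= n):
        raise ValueError("alignment outside genome bounds")
    g_start = max(0, alignment.start - margin)
    g_end = min(n, alignment.end + margin)
    window = seq[g_start:g_end]
    if alignment.strand == "-":
        window = revcomp(window)
        offset = g_end - alignment.end
    else:
        offset = alignment.start - g_start
    return PrecursorWindow(
        seq_id=alignment.seq_id,
        start=g_start,
        end=g_end,
        strand=alignment.strand,
        sequence=window,
        mature_offset=offset,
        mature_length=alignment.length,
    )


def find_star(
    structure: str, mature: Tuple[int, int], min_paired_fraction: float = 0.5
) -> Optional[Tuple[int, int]]:
    """Locate the miRNA* interval implied by the mature arm's base pairing.

    The star is the region pairing with the mature arm, placed so the duplex
    carries 2-nt 3' overhangs on both ends.  Returns None when the mature sits
    in a loop (partners on both sides), or fewer than half its bases pair.
    """
    off, length = mature
    partner = pair_table(structure)
    pairs = [(i, partner[i]) for i in range(off, off + length) if partner[i] != -1]
    if not pairs:
        return None
    left = [(i, q) for i, q in pairs if q < off]
    right = [(i, q) for i, q in pairs if q >= off + length]
    # the star arm is wherever most partners point; a few bases snagging the
    # flank are tolerated, but a substantial split means the mature straddles
    # the terminal loop
    side = right if len(right) >= len(left) else left
    if len(side) < 0.7 * len(pairs):
        return None
    if len(side) < min_paired_fraction * length:
        return None
    # in a duplex with 2-nt 3' overhangs, mature base r (0-based within the
    # mature) pairs star_end - 3 - r; invert for the star's exclusive end
    ends = Counter(q + (i - off) + 3 for i, q in side)
    star_end = max(sorted(ends), key=lambda e: ends[e])
    star_start = star_end - length
    star_start = max(0, star_start)
    star_end = min(len(structure), max(star_end, star_start + 1))
    return (star_start, star_end - star_start)


def trim_and_refold(
    window_sequence: str,
    mature: Tuple[int, int],
    star: Tuple[int, int],
    engine: FoldingEngine,
    refold_margin: int = 15,
) -> Tuple[str, str, float, Tuple[int, int], Tuple[int, int], int]:
    """Trim to duplex +/- margin and refold.

    Returns (precursor, structure, energy, mature', star', trim_offset) with
    intervals re-expressed in precursor coordinates.
    """
    if refold_margin < 0:
        raise ValueError("refold_margin must be >= 0")
    lo = max(0, min(mature[0], star[0]) - refold_margin)
    hi = min(len(window_sequence), max(mature[0] + mature[1], star[0] + star[1]) + refold_margin)
    precursor = window_sequence[lo:hi]
    structure, energy = engine.fold(precursor)
    new_mature = (mature[0] - lo, mature[1])
    new_star = (star[0] - lo, star[1])
    return precursor, structure, energy, new_mature, new_star, lo


def duplex_report(
    structure: str, mature: Tuple[int, int], star: Tuple[int, int]
) -> DuplexReport:
    """Walk the mature/star pairing and summarise duplex imperfections.

    Between consecutive paired anchors, the shorter of the two facing
    unpaired runs counts as mismatches and the length difference as an
    asymmetric bulge.  3' overhangs are the unpaired tails beyond the last
    anchor on each arm.
    """
    m_off, m_len = mature
    s_off, s_len = star
    n = len(structure)
    if not (0 <= m_off and m_off + m_len <= n and 0 <= s_off and s_off + s_len <= n):
        raise ValueError("interval outside structure")
    partner = pair_table(structure)
    s_end = s_off + s_len
    anchors = [
        (i, partner[i])
        for i in range(m_off, m_off + m_len)
        if partner[i] != -1 and s_off <= partner[i] < s_end
    ]
    if not anchors:
        return DuplexReport(m_len, 0, m_len, s_len, 0.0)
    mismatches = 0
    bulge = 0
    for (i1, q1), (i2, q2) in zip(anchors, anchors[1:]):
        gap_m = i2 - i1 - 1
        gap_s = max(0, q1 - q2 - 1)
        mismatches += min(gap_m, gap_s)
        bulge = max(bulge, abs(gap_m - gap_s))
    first_i, first_q = anchors[0]
    last_i, last_q = anchors[-1]
    # overhangs are measured against the facing strand's end rather than its
    # last paired base: terminal helix breathing leaves facing bases unpaired
    # on both arms and must not masquerade as a longer overhang
    raw_mature = (m_off + m_len - 1) - last_i
    facing_star_gap = max(0, last_q - s_off)
    overhang_mature = max(0, raw_mature - facing_star_gap)
    # the star's 3' end is inferred: place it 2 nt past the partner of the
    # mature 5' end in the modal pairing register of this structure
    registers = Counter(q + (i - m_off) + 3 for i, q in anchors)
    est_end = max(sorted(registers), key=lambda e: registers[e])
    raw_star = max(0, (est_end - 1) - first_q)
    facing_mature_gap = first_i - m_off
    overhang_star = max(0, raw_star - facing_mature_gap)
    return DuplexReport(
        mismatches=mismatches,
        largest_asymmetric_bulge=bulge,
        overhang_3p_mature=overhang_mature,
        overhang_3p_star=overhang_star,
        paired_fraction_mature=len(anchors) / m_len,
    )


def check_plant_criteria(
    candidate: HairpinCandidate, config: Optional[PipelineConfig] = None,
    thermodynamic: bool = False,
) -> Tuple[bool, List[str]]:
    """Judge a folded candidate against plant miRNA annotation criteria."""
    cfg = config or PipelineConfig()
    reasons: List[str] = []
    m_off, m_len = candidate.mature
    if not (cfg.min_len <= m_len <= cfg.max_len):
        reasons.append("mature_length")
    if candidate.star is None or candidate.duplex is None:
        reasons.append("no_star")
        return False, reasons
    s_off, s_len = candidate.star
    if m_off < s_off + s_len and s_off < m_off + m_len:
        reasons.append("arm_overlap")
        return False, reasons
    rep = candidate.duplex
    if rep.mismatches > cfg.duplex_max_mismatch:
        reasons.append("duplex_mismatches")
    if rep.largest_asymmetric_bulge > cfg.max_bulge:
        reasons.append("asymmetric_bulge")
    if rep.paired_fraction_mature < 0.5:
        reasons.append("insufficient_pairing")
    # the canonical 2-nt 3' overhang geometry is imposed when the star is
    # located; re-measuring it on an MFE structure is noisy at helix ends
    # (breathing, loop-internal pairing), so the check here is a sanity
    # bound only: neither end may stray past the overhang tolerance plus
    # the bulge allowance
    slack = cfg.max_overhang + cfg.max_bulge
    if rep.overhang_3p_mature > slack or rep.overhang_3p_star > slack:
        reasons.append("overhang_3p")
    # single-stem requirement, two parts: (i) the bulk of the mature's
    # pairing must point into the star region (helix extension past the
    # estimated star ends is tolerated within a 6-nt slack); (ii) the
    # path from the innermost duplex pair to the terminal loop must be
    # linear — a true precursor continues as one helix, whereas spurious
    # long-range duplexes enclose a multiloop somewhere on that path
    partner = pair_table(candidate.structure)
    lo, hi = s_off - 6, s_off + s_len + 6
    partners = [partner[i] for i in range(m_off, m_off + m_len) if partner[i] != -1]
    stray = sum(1 for q in partners if not (lo <= q < hi))
    if partners and stray > 0.2 * len(partners):
        reasons.append("multi_stem")
    elif _inter_arm_branches(candidate.structure, partner,
                             (m_off, m_len), (s_off, s_len)) >= 2:
        reasons.append("multi_stem")
    if thermodynamic and candidate.energy / max(1, len(candidate.precursor_sequence)) > -0.2:
        reasons.append("unstable")
    return not reasons, reasons


def _inter_arm_branches(
    structure: str,
    partner: Sequence[int],
    mature: Tuple[int, int],
    star: Tuple[int, int],
) -> int:
    """Maximum number of sibling helix branches on the path to the loop.

    Walks the segment enclosed by the mature/star anchor pair closest to the
    loop.  At every nesting level the substantial (>= 2 base pair) sibling
    groups are counted; trivial single-pair groups inside loops are ignored.
    A genuine precursor continues from the duplex as one linear stem (with
    bulges and internal loops) to a single terminal loop, so the maximum is
    at most 1 everywhere; a branched structure has a node with >= 2.
    """
    m_off, m_len = mature
    s_off, s_len = star
    s_end = s_off + s_len
    anchors = [
        (i, partner[i]) for i in range(m_off, m_off + m_len)
        if partner[i] != -1 and s_off <= partner[i] < s_end
    ]
    if not anchors:
        return 0
    a, b = min((tuple(sorted(p)) for p in anchors), key=lambda p: p[1] - p[0])

    def max_siblings(lo: int, hi: int) -> int:
        """Worst sibling count over the pair tree of structure[lo:hi]."""
        children = []
        i = lo
        while i < hi:
            q = partner[i]
            if q != -1 and q > i:
                children.append((i, q))
                i = q + 1
            else:
                i += 1
        substantial = [
            (ci, cq) for ci, cq in children
            if sum(1 for k in range(ci, cq + 1)
                   if partner[k] > k and ci <= partner[k] <= cq) >= 2
        ]
        worst = len(substantial)
        for ci, cq in substantial:
            worst = max(worst, max_siblings(ci + 1, cq))
        return worst

    return max_siblings(a + 1, b)


def signature_consistency(
    window_reads: Sequence[Tuple[int, int]],
    mature_5p: int,
    star_5p: Optional[int],
    slop: int = 2,
) -> float:
    """Fraction of window reads whose 5' end stacks at a duplex end.

    ``window_reads`` are (5'-offset-in-window, read count) pairs.  Reads whose
    5' end lies within +/-``slop`` nt of the mature or star 5' end count as
    consistent; loop and scatter reads do not.
    """
    total = sum(c for _, c in window_reads)
    if total == 0:
        return 0.0
    ends = [mature_5p] + ([star_5p] if star_5p is not None else [])
    good = sum(
        c for pos, c in window_reads if any(abs(pos - e) <= slop for e in ends)
    )
    return good / total


class _ReadIndex:
    """5'-position lookup of mapped reads, per (seq_id, strand)."""

    def __init__(self, alignments: Mapping[str, Sequence[Alignment]],
                 counts: Mapping[str, int]):
        buckets: Dict[Tuple[str, str], list] = defaultdict(list)
        for seq, alns in alignments.items():
            c = counts.get(seq, 0)
            for a in alns:
                buckets[(a.seq_id, a.strand)].append((a.five_prime, c))
        self._pos: Dict[Tuple[str, str], list] = {}
        self._cnt: Dict[Tuple[str, str], list] = {}
        for key, items in buckets.items():
            items.sort()
            self._pos[key] = [p for p, _ in items]
            self._cnt[key] = [c for _, c in items]

    def window_reads(self, window: PrecursorWindow) -> List[Tuple[int, int]]:
        """Reads on the window's strand, 5' offsets in window coordinates."""
        key = (window.seq_id, window.strand)
        pos = self._pos.get(key, [])
        lo = bisect_left(pos, window.start)
        hi = bisect_right(pos, window.end - 1)
        out = []
        for p, c in zip(pos[lo:hi], self._cnt[key][lo:hi]):
            off = p - window.start if window.strand == "+" else (window.end - 1) - p
            out.append((off, c))
        return out


def call_mirnas(
    representatives: Sequence[Tuple[Alignment, CleanTag]],
    genome: Mapping[str, str],
    engine: FoldingEngine,
    config: Optional[PipelineConfig] = None,
    all_alignments: Optional[Mapping[str, Sequence[Alignment]]] = None,
    counts: Optional[Mapping[str, int]] = None,
) -> List[HairpinCandidate]:
    """Full precursor discovery over representative mapped tags.

    Returns one candidate per locus (overlapping accepted precursors merged,
    highest-count mature retained), ordered genomically.  ``all_alignments``
    and ``counts`` feed the read-signature filter; when omitted only the
    representative reads themselves form the signature.
    """
    cfg = config or PipelineConfig()
    if engine is None or not genome:
        raise ValueError("genome and folding engine are required")
    counts = counts or {t.sequence: t.count for _, t in representatives}
    if all_alignments is None:
        all_alignments = {t.sequence: [a] for a, t in representatives}
    reads = _ReadIndex(all_alignments, counts)
    candidates: List[HairpinCandidate] = []
    for aln, tag in representatives:
        total = counts.get(tag.sequence, tag.count)
        if total <= cfg.min_copies:     # strict >, per the copy-number gate
            continue
        window = extract_window(aln, genome, cfg.window_margin)
        structure, energy = engine.fold(window.sequence)
        mature_w = (window.mature_offset, window.mature_length)
        star_w = find_star(structure, mature_w)
        if star_w is None:
            candidates.append(HairpinCandidate(
                window=window, precursor_sequence=window.sequence,
                precursor_interval=(window.start, window.end),
                structure=structure, energy=energy, mature=mature_w, star=None,
                duplex=None, mature_sequence=tag.sequence, mature_count=total,
                accepted=False, rejection_reasons=["no_star"],
            ))
            continue
        precursor, p_struct, p_energy, mature_p, star_p, lo = trim_and_refold(
            window.sequence, mature_w, star_w, engine, cfg.refold_margin
        )
        hi = lo + len(precursor)
        if window.strand == "+":
            interval = (window.start + lo, window.start + hi)
        else:
            interval = (window.end - hi, window.end - lo)
        # the refold may shift pairing; relocate the star on the refolded
        # structure, falling back to the window-derived interval
        star_r = find_star(p_struct, mature_p) or star_p
        rep = duplex_report(p_struct, mature_p, star_r)
        cand = HairpinCandidate(
            window=window, precursor_sequence=precursor,
            precursor_interval=interval, structure=p_struct, energy=p_energy,
            mature=mature_p, star=star_r, duplex=rep,
            mature_sequence=tag.sequence, mature_count=total,
        )
        ok, reasons = check_plant_criteria(cand, cfg, thermodynamic=engine.thermodynamic)
        consistency = signature_consistency(
            reads.window_reads(window), window.mature_offset,
            star_w[0] if star_w else None,
        )
        cand.signature_consistency = consistency
        if consistency < cfg.min_consistency:
            ok = False
            reasons.append("read_signature")
        cand.accepted = ok
        cand.rejection_reasons = reasons
        candidates.append(cand)
    return merge_loci(candidates)


def merge_loci(candidates: Sequence[HairpinCandidate]) -> List[HairpinCandidate]:
    """Merge candidates with overlapping precursor loci on one strand.

    The highest-count mature wins a merged locus (accepted candidates beat
    rejected ones).  Output is genomically ordered; idempotent.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.window.seq_id, c.window.strand, c.precursor_interval),
    )
    merged: List[HairpinCandidate] = []
    for cand in ordered:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.window.seq_id == cand.window.seq_id
            and prev.window.strand == cand.window.strand
            and cand.precursor_interval[0] < prev.precursor_interval[1]
        ):
            if (cand.accepted, cand.mature_count) > (prev.accepted, prev.mature_count):
                merged[-1] = cand
        else:
            merged.append(cand)
    merged.sort(key=lambda c: (c.window.seq_id, c.precursor_interval, c.window.strand))
    return merged
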