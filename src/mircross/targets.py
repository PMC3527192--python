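"""miRNA target prediction by duplex penalty scoring.

A miRNA is aligned antiparallel to every candidate transcript window and
charged per miRNA position (1-based from the 5' end): Watson-Crick pair 0,
G:U wobble 0.5, mismatch 1, gapped position 1, all doubled inside the core
(positions 2-13), where plant miRNA-target pairing is critical.  Sites up to
the report cutoff (default 7) are returned; "validation grade" means penalty
<= 4 (inclusive).  The predicted cleavage site — where an Argonaute complex
slices the transcript, between the bases paired to miRNA positions 10 and
11 — is reported as the transcript coordinate paired to position 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .config import to_dna, to_rna

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@dataclass
class ScoringScheme:
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 1.0
    core_start: int = 2          # 1-based miRNA positions, inclusive
    core_end: int = 13
    core_multiplier: float = 2.0
    report_cutoff: float = 7.0
    validation_cutoff: float = 4.0

    def multiplier(self, pos: int) -> float:
        return self.core_multiplier if self.core_start <= pos <= self.core_end else 1.0


# an alignment is a list of columns (mirna_pos | None, window_index | None);
# mirna_pos is 1-based from the miRNA 5' end; window_index is 0-based on the
# transcript window read 5'->3'.  None marks the bulged (gapped) side.
Column = Tuple[Optional[int], Optional[int]]


@dataclass
class TargetSite:
    transcript_id: str
    start: int                   # transcript coords, 0-based half-open
    end: int
    penalty: float
    mirna: str                   # DNA alphabet internally
    window: str
    columns: List[Column] = field(default_factory=list)
    cleavage_position: Optional[int] = None

    @property
    def alignment_text(self) -> str:
        return render_alignment(self.mirna, self.window, self.columns)


def _base_penalty(mirna_base: str, target_base: str, scheme: ScoringScheme) -> float:
    pair = (mirna_base, target_base)
    if pair in _WC:
        return 0.0
    if pair in _GU:
        return scheme.gu_penalty
    return scheme.mismatch_penalty


def score_duplex(
    mirna: str, site: str, scheme: Optional[ScoringScheme] = None
) -> float:
    """Penalty of the ungapped antiparallel duplex (equal lengths required)."""
    scheme = scheme or ScoringScheme()
    m = to_dna(mirna.upper())
    s = to_dna(site.upper())
    if len(m) != len(s):
        raise ValueError("ungapped scoring needs equal-length sequences")
    if set(m + s) - set("ACGT"):
        raise ValueError("non-ACGU characters in duplex")
    return score_columns(m, s, _ungapped_columns(len(m)), scheme)


def _ungapped_columns(length: int) -> List[Column]:
    # miRNA position i pairs window index length - i (antiparallel)
    return [(i, length - i) for i in range(1, length + 1)]


def score_columns(
    mirna: str, window: str, columns: Sequence[Column], scheme: ScoringScheme
) -> float:
    """Additive penalty of an explicit (possibly gapped) alignment."""
    total = 0.0
    for pos, j in columns:
        if pos is None:              # extra target base (target-side bulge):
            # charge with the multiplier of the miRNA position 3' of the gap
            left = next((p for p, jj in columns if p is not None and jj == j + 1),
                        None)
            anchor = (left + 1) if left is not None else 1
            total += scheme.gap_penalty * scheme.multiplier(anchor)
        elif j is None:              # unpaired miRNA base (miRNA-side bulge)
            total += scheme.gap_penalty * scheme.multiplier(pos)
        else:
            total += _base_penalty(mirna[pos - 1], window[j], scheme) * scheme.multiplier(pos)
    return total


def _target_bulge_columns(length: int, bulge_index: int) -> List[Column]:
    """Window of length+1 with the target base at ``bulge_index`` unpaired."""
    cols: List[Column] = []
    for i in range(1, length + 1):
        j = length + 1 - i
        if j <= bulge_index:
            j -= 1
        cols.append((i, j))
        if j == bulge_index + 1:
            cols.append((None, bulge_index))
    return cols


def _mirna_bulge_columns(length: int, bulge_pos: int) -> List[Column]:
    """Window of length-1 with miRNA position ``bulge_pos`` unpaired."""
    cols: List[Column] = []
    for i in range(1, length + 1):
        if i == bulge_pos:
            cols.append((i, None))
            continue
        j = (length - 1) - i if i < bulge_pos else length - i
        cols.append((i, j))
    return cols


def scan_transcript(
    mirna: str,
    transcript: str,
    transcript_id: str = "transcript",
    scheme: Optional[ScoringScheme] = None,
    allow_gaps: bool = True,
) -> List[TargetSite]:
    """All non-overlapping sites with penalty <= report_cutoff.

    Every ungapped window is scored, plus (when ``allow_gaps``) every
    placement with exactly one single-nucleotide bulge on either strand.
    Results are sorted by ascending penalty, ties by position; overlapping
    hits are resolved in that order.
    """
    scheme = scheme or ScoringScheme()
    m = to_dna(mirna.upper())
    t = to_dna(transcript.upper())
    L, n = len(m), len(t)
    if n < L:
        raise ValueError("transcript shorter than miRNA")
    hits: List[TargetSite] = []

    def consider(start: int, wlen: int, columns: List[Column]) -> None:
        window = t[start : start + wlen]
        penalty = score_columns(m, window, columns, scheme)
        if penalty <= scheme.report_cutoff:
            site = TargetSite(transcript_id, start, start + wlen, penalty, m,
                              window, columns)
            site.cleavage_position = predict_cleavage(site)
            hits.append(site)

    for s in range(n - L + 1):
        consider(s, L, _ungapped_columns(L))
    if allow_gaps:
        for s in range(n - L):
            for g in range(1, L):
                consider(s, L + 1, _target_bulge_columns(L, g))
        for s in range(n - L + 2):
            for b in range(2, L):
                consider(s, L - 1, _mirna_bulge_columns(L, b))

    hits.sort(key=lambda h: (h.penalty, h.start, h.end))
    chosen: List[TargetSite] = []
    for h in hits:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    return chosen


def select_validation_candidates(
    sites: Sequence[TargetSite], scheme: Optional[ScoringScheme] = None
) -> List[TargetSite]:
    """Sites suitable for experimental (5' RACE) validation: penalty <= 4."""
    cutoff = (scheme or ScoringScheme()).validation_cutoff
    return [s for s in sites if s.penalty <= cutoff]


def predict_cleavage(site: TargetSite) -> int:
    """Transcript coordinate of the base paired to miRNA position 10.

    Slicing occurs between the target bases paired to miRNA nt 10 and 11;
    the returned coordinate is the last base of the 5' cleavage fragment.
    """
    if len(site.mirna) < 11:
        raise ValueError("miRNA shorter than 11 nt has no canonical slice site")
    j10 = next((j for pos, j in site.columns if pos == 10), None)
    if j10 is None:  # position 10 bulged on the miRNA side: use the boundary
        j10 = next(j for pos, j in site.columns if pos == 11 and j is not None)
        j10 += 1
    return site.start + j10


def render_alignment(mirna: str, window: str, columns: Sequence[Column]) -> str:
    """Three-line duplex text: target 5'->3', pair symbols, miRNA 3'->5'."""
    top, mid, bot = [], [], []
    for pos, j in reversed(list(columns)):   # render left-to-right on target
        tb = window[j] if j is not None else "-"
        mb = mirna[pos - 1] if pos is not None else "-"
        top.append(to_rna(tb) if tb != "-" else "-")
        bot.append(to_rna(mb) if mb != "-" else "-")
        if pos is None or j is None:
            mid.append(" ")
        elif (mb, tb) in _WC:
            mid.append("|")
        elif (mb, tb) in _GU:
            mid.append("o")
        else:
            mid.append(" ")
    return (
        "5' " + "".join(top) + " 3' target\n"
        "   " + "".join(mid) + "\n"
        "3' " + "".join(bot) + " 5' miRNA"
    )
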