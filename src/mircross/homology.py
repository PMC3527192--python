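"""Homology classification against a known-miRNA catalogue.

Hairpin-validated matures matching a catalogue entry (miRBase-style, e.g.
miR156a) within 2 mismatches and a 2-nt terminal shift are conserved; the
rest are novel.  Tags that never mapped to the surrogate genome get a second
chance: a catalogue hit rescues them as conserved miRNAs that were missed
because the surrogate genome diverged at their locus.  Families group
conserved members by catalogue family (miR156a, miR156f -> miR156) and novel
members by single-linkage sequence clustering, named Ng1, Ng2, ... in
descending-abundance order.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .config import to_dna, to_rna

STATUS_CONSERVED = "conserved_mapped"
STATUS_NOVEL = "novel_mapped"
STATUS_RESCUED = "conserved_rescued"

_FAMILY_RE = re.compile(r"(?:^|-)((?:miR|MIR)\d+)", re.IGNORECASE)


def parse_family(name: str) -> str:
    """Family from a catalogue name: strip the variant suffix of miR<number>.

    'miR156a' -> 'miR156'; 'ath-miR172c-3p' -> 'miR172'; unparseable names are
    their own (singleton) family.
    """
    m = _FAMILY_RE.search(name)
    if m:
        return "miR" + re.sub(r"\D", "", m.group(1))
    return name


@dataclass(frozen=True)
class KnownMiRNA:
    name: str
    sequence: str           # stored as DNA; presented as RNA
    species: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_dna(self.sequence.upper()))
        if not self.family:
            object.__setattr__(self, "family", parse_family(self.name))
        if not (10 <= len(self.sequence) <= 30):
            raise ValueError(f"{self.name}: implausible miRNA length")


@dataclass(frozen=True)
class HomologyHit:
    tag_sequence: str
    known_name: str
    family: str
    mismatches: int
    offset_shift: int


@dataclass
class AnnotatedMiRNA:
    sequence: str                       # mature, DNA alphabet
    status: str                         # conserved_mapped / novel_mapped / conserved_rescued
    family: str = ""                    # known family or Ng<k>
    hit: Optional[HomologyHit] = None
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)


def _overlap_mismatches(a: str, b: str, shift: int) -> int:
    """Hamming distance over the overlap of ``a`` vs ``b`` offset by shift.

    ``shift`` > 0 slides ``b`` rightward relative to ``a``; bases outside the
    overlap are not compared (terminal shifts are tolerated, not penalised —
    the shift itself is a tie-break).
    """
    start = max(0, shift)
    end = min(len(a), len(b) + shift)
    if end <= start:
        return max(len(a), len(b))
    return sum(1 for i in range(start, end) if a[i] != b[i - shift])


def match_known(
    tag_sequence: str,
    catalogue: Sequence[KnownMiRNA],
    max_mm: int = 2,
    max_shift: int = 2,
) -> Optional[HomologyHit]:
    """Best ungapped catalogue hit within the mismatch/shift tolerance.

    Ties break by smaller |shift|, then lexicographic catalogue name.
    """
    if not catalogue:
        raise ValueError("empty known-miRNA catalogue")
    seq = to_dna(tag_sequence.upper())
    best: Optional[Tuple[int, int, str, int]] = None
    for known in catalogue:
        for shift in range(-max_shift, max_shift + 1):
            mm = _overlap_mismatches(seq, known.sequence, shift)
            key = (mm, abs(shift), known.name, shift)
            if mm <= max_mm and (best is None or key < best):
                best = key
    if best is None:
        return None
    mm, _, name, shift = best
    family = next(k.family for k in catalogue if k.name == name)
    return HomologyHit(seq, name, family, mm, shift)


def batch_match_known(
    sequences: Sequence[str],
    catalogue: Sequence[KnownMiRNA],
    max_mm: int = 2,
    max_shift: int = 2,
) -> Dict[str, Optional[HomologyHit]]:
    """Vectorised :func:`match_known` over many tags (identical results).

    Tags are grouped by length and compared to every catalogue entry at every
    terminal shift with numpy; iteration follows the tie-break priority
    (mismatches, |shift|, name, shift) so the winner matches the scalar path.
    """
    import numpy as np

    if not catalogue:
        raise ValueError("empty known-miRNA catalogue")
    seqs = [to_dna(s.upper()) for s in sequences]
    result: Dict[str, Optional[HomologyHit]] = {s: None for s in seqs}
    by_name = {k.name: k for k in catalogue}
    ordered_names = sorted(by_name)
    by_len: Dict[int, List[str]] = defaultdict(list)
    for s in set(seqs):
        by_len[len(s)].append(s)
    shifts: List[int] = []
    for a in range(max_shift + 1):
        shifts.extend([-a, a] if a else [0])
    for length, group in by_len.items():
        group.sort()
        arr = np.frombuffer("".join(group).encode(), dtype=np.uint8)
        arr = arr.reshape(len(group), length)
        best_mm = np.full(len(group), max_mm + 1, dtype=np.int32)
        best_hit: List[Optional[Tuple[str, int, int]]] = [None] * len(group)
        for abs_shift in range(max_shift + 1):
            for name in ordered_names:
                known = by_name[name]
                kb = np.frombuffer(known.sequence.encode(), dtype=np.uint8)
                for shift in ([0] if abs_shift == 0 else [-abs_shift, abs_shift]):
                    start = max(0, shift)
                    end = min(length, len(kb) + shift)
                    if end <= start:
                        continue
                    mm = (arr[:, start:end] != kb[start - shift : end - shift]).sum(axis=1)
                    better = mm < best_mm
                    best_mm[better] = mm[better]
                    for i in np.nonzero(better)[0]:
                        best_hit[i] = (name, int(mm[i]), shift)
        for i, s in enumerate(group):
            if best_hit[i] is not None and best_mm[i] <= max_mm:
                name, mm, shift = best_hit[i]
                result[s] = HomologyHit(s, name, by_name[name].family, mm, shift)
    return result


def classify_candidates(
    mature_sequences: Sequence[str],
    catalogue: Sequence[KnownMiRNA],
    max_mm: int = 2,
    max_shift: int = 2,
) -> List[AnnotatedMiRNA]:
    """Split hairpin-validated matures into conserved vs novel."""
    out = []
    for seq in mature_sequences:
        hit = match_known(seq, catalogue, max_mm, max_shift)
        if hit is not None:
            out.append(AnnotatedMiRNA(to_dna(seq.upper()), STATUS_CONSERVED,
                                      family=hit.family, hit=hit))
        else:
            out.append(AnnotatedMiRNA(to_dna(seq.upper()), STATUS_NOVEL))
    return out


def rescue_unmapped(
    unmapped_sequences: Sequence[str],
    catalogue: Sequence[KnownMiRNA],
    max_mm: int = 2,
    max_shift: int = 2,
) -> List[AnnotatedMiRNA]:
    """Catalogue hits among genome-unmapped tags become conserved_rescued."""
    rescued = []
    for seq in unmapped_sequences:
        hit = match_known(seq, catalogue, max_mm, max_shift)
        if hit is not None:
            rescued.append(AnnotatedMiRNA(to_dna(seq.upper()), STATUS_RESCUED,
                                          family=hit.family, hit=hit))
    return rescued


def _novel_linked(a: str, b: str, max_mm: int = 2) -> bool:
    """Single-linkage criterion for novel matures: length +/-1, best-overlap
    comparison within ``max_mm`` mismatches."""
    if abs(len(a) - len(b)) > 1:
        return False
    span = abs(len(a) - len(b)) + 1
    return any(
        _overlap_mismatches(a, b, s) <= max_mm for s in range(-span, span + 1)
    )


@dataclass
class Family:
    name: str
    members: List[AnnotatedMiRNA]

    @property
    def counts(self) -> Dict[str, int]:
        total: Dict[str, int] = defaultdict(int)
        for m in self.members:
            for sample, c in m.counts.items():
                total[sample] += c
        return dict(total)

    @property
    def major(self) -> AnnotatedMiRNA:
        """The family's representative: its highest-count member."""
        return min(self.members, key=lambda m: (-m.total_count, m.sequence))


def group_families(annotated: Sequence[AnnotatedMiRNA], max_mm: int = 2) -> List[Family]:
    """Group annotated miRNAs into families.

    Conserved members share their catalogue family.  Novel members are
    single-linkage clustered and the clusters named Ng1, Ng2, ... ordered by
    descending total count then lexicographic major sequence; members are
    renamed in place.  Every input appears in exactly one family.
    """
    conserved: Dict[str, List[AnnotatedMiRNA]] = defaultdict(list)
    novel: List[AnnotatedMiRNA] = []
    for m in annotated:
        if m.status == STATUS_NOVEL:
            novel.append(m)
        else:
            conserved[m.family].append(m)
    families = [Family(name, members) for name, members in sorted(conserved.items())]

    # union-find single linkage over novel matures
    parent = list(range(len(novel)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(novel)):
        for j in range(i + 1, len(novel)):
            if _novel_linked(novel[i].sequence, novel[j].sequence, max_mm):
                parent[find(i)] = find(j)

    clusters: Dict[int, List[AnnotatedMiRNA]] = defaultdict(list)
    for i, m in enumerate(novel):
        clusters[find(i)].append(m)
    ordered = sorted(
        clusters.values(),
        key=lambda ms: (-sum(m.total_count for m in ms),
                        min(m.sequence for m in ms)),
    )
    for k, members in enumerate(ordered, start=1):
        name = f"Ng{k}"
        for m in members:
            m.family = name
        families.append(Family(name, members))
    return families
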