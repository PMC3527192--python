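"""Read pre-processing: adapter trimming, quality/length/ambiguity filters,
tag collapsing, ncRNA subtraction and low-complexity masking.

Raw sRNA-seq reads carry the sequencing adapter 3' of the short insert.  The
insert is recovered by locating the leftmost occurrence of the adapter (either
a full internal match or a terminal adapter prefix of at least ``min_overlap``
bases), then filtered to 18-26 nt without ambiguous bases, collapsed to unique
tags with per-sample read counts, purged of fragments of structural ncRNAs
(rRNA/tRNA/snRNA/snoRNA, matched as exact substrings on either strand) and of
low-complexity tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import revcomp

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "other")


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: Optional[Sequence[int]] = None  # Phred scores

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class CleanTag:
    """A unique sRNA sequence with its per-sample read count."""

    sequence: str
    count: int
    sample_id: str


@dataclass
class NcRNAReference:
    """Named structural-ncRNA sequences used for subtraction."""

    entries: list  # of (name, rna_class, sequence)

    def __post_init__(self) -> None:
        for name, cls, seq in self.entries:
            if cls not in NCRNA_CLASSES:
                raise ValueError(f"{name}: unknown ncRNA class {cls!r}")
            if not seq:
                raise ValueError(f"{name}: empty reference sequence")


@dataclass
class StageCounts:
    """Per-sample accounting mirroring the stage report of the pipeline."""

    total_reads: int = 0
    no_adapter: int = 0
    empty_insert: int = 0
    low_quality: int = 0
    bad_length_or_n: int = 0
    trimmed_reads: int = 0          # reads surviving trimming + quality + length
    unique_tags: int = 0
    ncrna_tags: int = 0
    ncrna_reads: int = 0
    masked_tags: int = 0
    masked_reads: int = 0
    kept_tags: int = 0
    kept_reads: int = 0
    ncrna_by_class: Counter = field(default_factory=Counter)


def trim_adapter(read: RawRead, adapter: str, min_overlap: int = 6) -> Optional[str]:
    """Return the insert preceding the leftmost adapter occurrence, or None.

    An occurrence is either the full adapter anywhere in the read, or a prefix
    of the adapter of length >= ``min_overlap`` flush with the read's 3' end.
    Reads without a detectable adapter and empty inserts are rejected (None).
    """
    if not (1 <= min_overlap <= len(adapter)):
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = read.sequence
    if not seq:
        raise ValueError("empty read")
    n, m = len(seq), len(adapter)
    best = None
    # full internal match
    pos = seq.find(adapter)
    if pos != -1:
        best = pos
    # terminal partial match: suffix of read == prefix of adapter
    limit = n - min_overlap if best is None else min(best, n - min_overlap)
    for i in range(limit + 1):
        k = n - i
        if k < m and seq[i:] == adapter[:k]:
            best = i
            break
    if best is None or best == 0:
        return None
    return seq[:best]


def passes_quality(read: RawRead, phred_floor: int = 20) -> bool:
    """True unless any base quality (when present) falls below the floor."""
    if read.quality is None:
        return True
    return min(read.quality) >= phred_floor


def filter_length_ambiguity(sequence: str, min_len: int = 18, max_len: int = 26) -> bool:
    """Keep iff min_len <= length <= max_len and no ambiguous base."""
    return min_len <= len(sequence) <= max_len and "N" not in sequence.upper()


def collapse_unique(inserts: Iterable[str], sample_id: str) -> list[CleanTag]:
    """Collapse insert sequences to unique counted tags.

    Order is deterministic: descending count, then lexicographic sequence.
    """
    counts = Counter(inserts)
    return [
        CleanTag(seq, n, sample_id)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_ncrna(
    tags: Sequence[CleanTag], reference: NcRNAReference
) -> tuple[list[CleanTag], list[tuple[CleanTag, str]]]:
    """Partition tags into (kept, removed-with-class) by exact substring match.

    A tag is removed iff its sequence occurs verbatim inside any reference
    sequence or inside its reverse complement.
    """
    if not reference.entries:
        raise ValueError("empty ncRNA reference")
    refs = [(cls, seq.upper(), revcomp(seq.upper())) for _, cls, seq in reference.entries]
    kept: list[CleanTag] = []
    removed: list[tuple[CleanTag, str]] = []
    for tag in tags:
        hit = next(
            (cls for cls, fwd, rev in refs if tag.sequence in fwd or tag.sequence in rev),
            None,
        )
        if hit is None:
            kept.append(tag)
        else:
            removed.append((tag, hit))
    return kept, removed


def is_low_complexity(sequence: str, max_mono_fraction: float = 0.8) -> bool:
    """True for near-homopolymers (>80% one base) or pure 1-2 nt repeats."""
    n = len(sequence)
    if n == 0:
        return True
    if max(Counter(sequence).values()) / n > max_mono_fraction:
        return True
    for period in (1, 2):
        unit = sequence[:period]
        if n >= 2 * period and sequence == (unit * (n // period + 1))[:n]:
            return True
    return False


def mask_low_complexity(tags: Sequence[CleanTag]) -> tuple[list[CleanTag], list[CleanTag]]:
    """Split tags into (kept, masked) by the low-complexity rule."""
    kept, masked = [], []
    for tag in tags:
        (masked if is_low_complexity(tag.sequence) else kept).append(tag)
    return kept, masked


def preprocess_reads(
    reads: Iterable[RawRead],
    sample_id: str,
    reference: Optional[NcRNAReference] = None,
    adapter: str = "ATCTCGTATGCCGTCTTCTGCTTG",
    min_overlap: int = 6,
    phred_floor: int = 20,
    min_len: int = 18,
    max_len: int = 26,
) -> tuple[list[CleanTag], StageCounts]:
    """Run the full pre-processing chain for one sample.

    Returns the surviving tags and a :class:`StageCounts` record whose fields
    reconcile: total = kept reads + reads rejected at each stage.
    """
    stats = StageCounts()
    inserts: list[str] = []
    for read in reads:
        stats.total_reads += 1
        if not passes_quality(read, phred_floor):
            stats.low_quality += 1
            continue
        insert = trim_adapter(read, adapter, min_overlap)
        if insert is None:
            if adapter in read.sequence or read.sequence in adapter:
                stats.empty_insert += 1
            else:
                stats.no_adapter += 1
            continue
        if not filter_length_ambiguity(insert, min_len, max_len):
            stats.bad_length_or_n += 1
            continue
        inserts.append(insert)
    stats.trimmed_reads = len(inserts)
    tags = collapse_unique(inserts, sample_id)
    stats.unique_tags = len(tags)
    if reference is not None and reference.entries:
        tags, removed = filter_ncrna(tags, reference)
        stats.ncrna_tags = len(removed)
        stats.ncrna_reads = sum(t.count for t, _ in removed)
        for _, cls in removed:
            stats.ncrna_by_class[cls] += 1
    tags, masked = mask_low_complexity(tags)
    stats.masked_tags = len(masked)
    stats.masked_reads = sum(t.count for t in masked)
    stats.kept_tags = len(tags)
    stats.kept_reads = sum(t.count for t in tags)
    return tags, stats
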