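"""Exact-match placement of sRNA tags on a surrogate (cross-species) genome.

Because the study organism lacks an assembled genome, tags are placed on the
closest sequenced relative by *perfect*, full-length matching on both strands.
A fixed-length seed table accelerates lookup; every seed hit is verified
against the genomic slice, so results are identical to a naive scan.  Tags
hitting more than ``max_loci`` positions are discarded as repeats; tags with
no hit are routed to the homology-rescue path.  Among tags sharing a 5'
genomic end on one strand, the highest-count tag is kept as the
representative of the read stack.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .config import revcomp
from .preprocess import CleanTag


@dataclass(frozen=True)
class Alignment:
    """A perfect full-length placement of a tag; 0-based half-open coords."""

    tag_sequence: str
    seq_id: str
    start: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return len(self.tag_sequence)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the tag's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeIndex:
    """Seed-and-verify exact-match index over a set of named sequences."""

    def __init__(self, sequences: Mapping[str, str], seed_length: int = 16):
        if not sequences:
            raise ValueError("empty genome")
        if not (1 <= seed_length <= 18):
            raise ValueError("seed_length must be in 1..18")
        names = list(sequences)
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names")
        self.sequences: Dict[str, str] = {k: v.upper() for k, v in sequences.items()}
        self.seed_length = seed_length
        self._table: Dict[str, list] = defaultdict(list)
        k = seed_length
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._table[seq[i : i + k]].append((name, i))

    def lookup(self, query: str) -> List[Tuple[str, int]]:
        """All positions where ``query`` occurs verbatim (forward only)."""
        q = query.upper()
        if len(q) < self.seed_length:
            raise ValueError(
                f"query shorter than seed_length {self.seed_length}: {len(q)}"
            )
        hits = []
        for name, i in self._table.get(q[: self.seed_length], ()):
            if self.sequences[name][i : i + len(q)] == q:
                hits.append((name, i))
        return hits


def build_index(sequences: Mapping[str, str], seed_length: int = 16) -> GenomeIndex:
    return GenomeIndex(sequences, seed_length)


def map_exact(tag: CleanTag, index: GenomeIndex) -> List[Alignment]:
    """All perfect full-length alignments of a tag on both strands.

    Sorted by (seq_id, start, strand).  A '-' strand alignment means the tag
    equals the reverse complement of the genomic slice.
    """
    seq = tag.sequence.upper()
    alns = [Alignment(seq, name, i, "+") for name, i in index.lookup(seq)]
    alns += [Alignment(seq, name, i, "-") for name, i in index.lookup(revcomp(seq))]
    alns.sort(key=lambda a: (a.seq_id, a.start, a.strand))
    return alns


def filter_multiloci(
    alignments_by_tag: Mapping[str, Sequence[Alignment]], max_loci: int = 10
) -> tuple[dict, list, list]:
    """Partition tags by mapping multiplicity.

    Returns (kept: tag -> alignments for 1..max_loci hits,
             discarded: tags with > max_loci hits,
             unmapped: tags with 0 hits — candidates for homology rescue).
    """
    if max_loci < 1:
        raise ValueError("max_loci must be >= 1")
    kept: dict = {}
    discarded: list = []
    unmapped: list = []
    for tag, alns in alignments_by_tag.items():
        if not alns:
            unmapped.append(tag)
        elif len(alns) <= max_loci:
            kept[tag] = list(alns)
        else:
            discarded.append(tag)
    return kept, discarded, unmapped


def select_representative(group: Sequence[CleanTag]) -> CleanTag:
    """The representative of tags sharing one 5' genomic position and strand.

    Highest count wins; ties go to the longer tag, then the lexicographically
    smaller sequence.
    """
    if not group:
        raise ValueError("empty group")
    return min(group, key=lambda t: (-t.count, -len(t.sequence), t.sequence))


def representatives_by_position(
    kept: Mapping[str, Sequence[Alignment]], tags: Mapping[str, CleanTag]
) -> List[Tuple[Alignment, CleanTag]]:
    """Group mapped tags by (seq_id, 5' position, strand); pick one per group.

    Returns (alignment, representative tag) pairs in genomic order.
    """
    groups: dict = defaultdict(list)
    for seq, alns in kept.items():
        for aln in alns:
            groups[(aln.seq_id, aln.five_prime, aln.strand)].append(aln)
    out = []
    for key in sorted(groups):
        alns = groups[key]
        rep_tag = select_representative([tags[a.tag_sequence] for a in alns])
        rep_aln = next(a for a in alns if a.tag_sequence == rep_tag.sequence)
        out.append((rep_aln, rep_tag))
    return out


def alignments_to_bed(alignments: Iterable[Alignment], counts: Mapping[str, int]) -> str:
    """BED6 text (0-based half-open; score = read count)."""
    lines = []
    for a in alignments:
        score = counts.get(a.tag_sequence, 0)
        lines.append(
            f"{a.seq_id}\t{a.start}\t{a.end}\ttag\t{score}\t{a.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
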