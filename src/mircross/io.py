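"""Plain-text file formats: FASTA/FASTQ via Biopython, GFF3 and TSV writers.

Conventions: collapsed-tag FASTA headers are ``>tag<serial>_x<count>``;
known-miRNA catalogue headers are ``>name family species``; genomic feature
output is GFF3 (1-based inclusive) with pre_miRNA parents and miRNA /
miRNA_star children; all coordinates inside the package stay 0-based
half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import to_rna
from .hairpin import HairpinCandidate
from .homology import KnownMiRNA
from .preprocess import CleanTag, NcRNAReference, RawRead

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path: PathLike, records: Iterable[Tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_fastq(path: PathLike) -> List[RawRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(RawRead(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            quality=list(rec.letter_annotations["phred_quality"]),
        ))
    return reads


def write_fastq(path: PathLike, reads: Iterable[RawRead]) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = (
                list(r.quality) if r.quality is not None else [40] * len(r.sequence)
            )
            yield rec
    SeqIO.write(records(), str(path), "fastq")


_TAG_HEADER = re.compile(r"^tag(\d+)_x(\d+)$")


def write_collapsed_fasta(path: PathLike, tags: Sequence[CleanTag]) -> None:
    """Collapsed unique tags as ``>tag<serial>_x<count>`` FASTA."""
    write_fasta(
        path,
        ((f"tag{i + 1}_x{t.count}", t.sequence) for i, t in enumerate(tags)),
    )


def read_collapsed_fasta(path: PathLike, sample_id: str) -> List[CleanTag]:
    tags = []
    for name, seq in read_fasta(path).items():
        m = _TAG_HEADER.match(name)
        if not m:
            raise ValueError(f"not a collapsed-tag header: {name!r}")
        tags.append(CleanTag(seq, int(m.group(2)), sample_id))
    return tags


def read_catalogue(path: PathLike) -> List[KnownMiRNA]:
    """Known-miRNA FASTA with ``>name family species`` headers."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        name = parts[0]
        family = parts[1] if len(parts) > 1 else ""
        species = parts[2] if len(parts) > 2 else ""
        entries.append(KnownMiRNA(
            name=name, sequence=str(rec.seq), species=species, family=family
        ))
    return entries


def write_catalogue(path: PathLike, catalogue: Sequence[KnownMiRNA]) -> None:
    def records():
        for k in catalogue:
            rec = SeqRecord(Seq(to_rna(k.sequence)), id=k.name,
                            description=f"{k.family} {k.species}".strip())
            yield rec
    SeqIO.write(records(), str(path), "fasta")


def read_ncrna_fasta(path: PathLike) -> NcRNAReference:
    """ncRNA FASTA; the class is the second header token (default 'other')."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        cls = parts[1] if len(parts) > 1 else "other"
        entries.append((rec.id, cls, str(rec.seq).upper().replace("U", "T")))
    return NcRNAReference(entries)


def candidates_to_gff3(candidates: Sequence[HairpinCandidate]) -> str:
    """Accepted precursors as GFF3: pre_miRNA with miRNA / miRNA_star kids."""
    lines = ["##gff-version 3"]
    for idx, cand in enumerate(candidates, start=1):
        if not cand.accepted:
            continue
        seqid = cand.window.seq_id
        strand = cand.window.strand
        p_start, p_end = cand.precursor_interval
        pid = f"pre_mir{idx}"
        lines.append(
            f"{seqid}\tmircross\tpre_miRNA\t{p_start + 1}\t{p_end}\t"
            f"{cand.mature_count}\t{strand}\t.\tID={pid}"
        )
        for kind, interval in (("miRNA", cand.mature), ("miRNA_star", cand.star)):
            if interval is None:
                continue
            off, length = interval
            if strand == "+":
                g_start = p_start + off
            else:
                g_start = p_end - off - length
            lines.append(
                f"{seqid}\tmircross\t{kind}\t{g_start + 1}\t{g_start + length}\t"
                f".\t{strand}\t.\tID={pid}_{kind};Parent={pid}"
            )
    return "\n".join(lines) + "\n"


def structures_to_text(candidates: Sequence[HairpinCandidate]) -> str:
    """Paired sequence / dot-bracket text for accepted precursors."""
    blocks = []
    for idx, cand in enumerate(candidates, start=1):
        if not cand.accepted:
            continue
        blocks.append(
            f">pre_mir{idx} {cand.window.seq_id}:{cand.precursor_interval[0] + 1}"
            f"-{cand.precursor_interval[1]}({cand.window.strand})"
            f" energy={cand.energy:.6g}\n"
            f"{to_rna(cand.precursor_sequence)}\n{cand.structure}"
        )
    return "\n".join(blocks) + ("\n" if blocks else "")
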