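"""End-to-end orchestration: preprocess -> map -> discover -> annotate ->
(optional) targets -> comparative profiles, with stage accounting and fixed-
format report files.

The pipeline is deterministic: identical inputs, configuration and seed give
byte-identical outputs (report files carry no wall-clock timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import io as mcio
from .config import PipelineConfig, to_rna
from .folding import get_engine
from .hairpin import HairpinCandidate, call_mirnas
from .homology import (
    STATUS_NOVEL,
    STATUS_RESCUED,
    AnnotatedMiRNA,
    Family,
    KnownMiRNA,
    batch_match_known,
    group_families,
)
from .mapping import (
    build_index,
    filter_multiloci,
    map_exact,
    representatives_by_position,
)
from .preprocess import CleanTag, NcRNAReference, RawRead, StageCounts, preprocess_reads
from .profiles import (
    CountProfile,
    call_enrichment,
    composition_profile,
    conservation_partition,
)
from .targets import ScoringScheme, TargetSite, scan_transcript, select_validation_candidates

log = logging.getLogger("mircross")


@dataclass
class PipelineInputs:
    """In-memory inputs; file-based entry points load into this form."""

    reads_by_sample: Dict[str, List[RawRead]]
    genome: Mapping[str, str]
    ncrna: Optional[NcRNAReference] = None
    catalogue: Sequence[KnownMiRNA] = ()
    transcripts: Optional[Mapping[str, str]] = None
    explicit_totals: Optional[Mapping[str, float]] = None


@dataclass
class PipelineResults:
    samples: List[str]
    stage_counts: Dict[str, StageCounts]
    tags_by_sample: Dict[str, List[CleanTag]]
    candidates: List[HairpinCandidate]
    annotated: List[AnnotatedMiRNA]
    families: List[Family]
    profile: Optional[CountProfile]
    enrichment: Optional[pd.DataFrame]
    venn: Optional[pd.DataFrame]
    composition: Optional[pd.DataFrame]
    target_sites: List[TargetSite]
    n_mapped_tags: int = 0
    n_multi_locus: int = 0
    n_unmapped: int = 0


@dataclass
class RunManifest:
    config_text: str
    input_digests: Dict[str, str] = field(default_factory=dict)
    stage_table: Dict[str, Dict[str, int]] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    version: str = "0.1.0"
    started: float = 0.0          # not serialised: byte-identical reruns
    finished: float = 0.0
    failed_stage: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config_text,
                "inputs": self.input_digests,
                "stages": self.stage_table,
                "outputs": sorted(self.outputs),
                "failed_stage": self.failed_stage,
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    inputs: PipelineInputs,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Path] = None,
) -> Tuple[PipelineResults, RunManifest]:
    """Execute the whole workflow; optionally write the report files."""
    cfg = config or PipelineConfig()
    if not inputs.reads_by_sample:
        raise ValueError("no read libraries supplied")
    if not inputs.genome:
        raise ValueError("no genome supplied")
    manifest = RunManifest(config_text=cfg.to_text(), started=time.time())
    t0 = time.time()

    # -- stage 1: preprocessing ------------------------------------------
    samples = list(inputs.reads_by_sample)
    stage_counts: Dict[str, StageCounts] = {}
    tags_by_sample: Dict[str, List[CleanTag]] = {}
    for sample in samples:
        tags, stats = preprocess_reads(
            inputs.reads_by_sample[sample], sample,
            reference=inputs.ncrna, adapter=cfg.adapter,
            min_overlap=cfg.min_overlap, phred_floor=cfg.phred_floor,
            min_len=cfg.min_len, max_len=cfg.max_len,
        )
        tags_by_sample[sample] = tags
        stage_counts[sample] = stats
        log.info("preprocess %s: %d reads -> %d tags (%.1fs)",
                 sample, stats.total_reads, stats.kept_tags, time.time() - t0)

    per_sample_counts: Dict[str, Dict[str, int]] = {
        s: {t.sequence: t.count for t in tags} for s, tags in tags_by_sample.items()
    }
    pooled: Dict[str, int] = defaultdict(int)
    for counts in per_sample_counts.values():
        for seq, c in counts.items():
            pooled[seq] += c

    # -- stage 2: genome mapping -----------------------------------------
    index = build_index(inputs.genome, cfg.seed_length)
    alignments = {
        seq: map_exact(CleanTag(seq, c, "pooled"), index)
        for seq, c in sorted(pooled.items())
    }
    kept, discarded, unmapped = filter_multiloci(alignments, cfg.max_loci)
    pooled_tags = {seq: CleanTag(seq, pooled[seq], "pooled") for seq in kept}
    reps = representatives_by_position(kept, pooled_tags)
    log.info("mapping: %d mapped, %d multi-locus, %d unmapped (%.1fs)",
             len(kept), len(discarded), len(unmapped), time.time() - t0)

    # -- stage 3: hairpin discovery --------------------------------------
    engine = get_engine(cfg.engine)
    candidates = call_mirnas(
        reps, inputs.genome, engine, cfg,
        all_alignments=kept, counts=dict(pooled),
    )
    accepted = [c for c in candidates if c.accepted]
    log.info("discovery: %d candidate loci, %d accepted (engine=%s, %.1fs)",
             len(candidates), len(accepted), engine.name, time.time() - t0)

    # -- stage 4: homology annotation ------------------------------------
    annotated: List[AnnotatedMiRNA] = []
    if inputs.catalogue:
        mature_seqs = sorted({c.mature_sequence for c in accepted})
        hits = batch_match_known(
            mature_seqs, inputs.catalogue, cfg.homology_max_mm, cfg.homology_max_shift
        )
        for seq in mature_seqs:
            hit = hits[seq]
            if hit is not None:
                annotated.append(AnnotatedMiRNA(seq, "conserved_mapped",
                                                family=hit.family, hit=hit))
            else:
                annotated.append(AnnotatedMiRNA(seq, STATUS_NOVEL))
        rescue_hits = batch_match_known(
            sorted(unmapped), inputs.catalogue,
            cfg.homology_max_mm, cfg.homology_max_shift,
        )
        for seq in sorted(unmapped):
            hit = rescue_hits[seq]
            if hit is not None:
                annotated.append(AnnotatedMiRNA(seq, STATUS_RESCUED,
                                                family=hit.family, hit=hit))
    else:
        annotated = [AnnotatedMiRNA(seq, STATUS_NOVEL)
                     for seq in sorted({c.mature_sequence for c in accepted})]
    for mir in annotated:
        mir.counts = {
            s: per_sample_counts[s].get(mir.sequence, 0) for s in samples
        }
    families = group_families(annotated, cfg.homology_max_mm)
    log.info("annotation: %d miRNAs in %d families (%.1fs)",
             len(annotated), len(families), time.time() - t0)

    # -- stage 5: target prediction (optional) ---------------------------
    target_sites: List[TargetSite] = []
    if inputs.transcripts:
        scheme = ScoringScheme(
            report_cutoff=cfg.target_report_cutoff,
            validation_cutoff=cfg.validation_cutoff,
        )
        majors = sorted(
            {f.major.sequence for f in families if f.members}
        )
        for mirna in majors:
            for tid in sorted(inputs.transcripts):
                target_sites.extend(
                    scan_transcript(mirna, inputs.transcripts[tid], tid, scheme)
                )
        target_sites.sort(key=lambda s: (s.penalty, s.transcript_id, s.start))
        log.info("targets: %d sites over %d transcripts (%.1fs)",
                 len(target_sites), len(inputs.transcripts), time.time() - t0)

    # -- stage 6: comparative profiles -----------------------------------
    profile = enrichment = venn_df = comp = None
    if annotated:
        totals = (
            dict(inputs.explicit_totals)
            if cfg.normalization_totals == "explicit" and inputs.explicit_totals
            else None
        )
        profile = CountProfile.from_counts(
            {to_rna(m.sequence): m.counts for m in annotated},
            library_totals=totals, samples=samples,
        )
        if len(samples) >= 2 and all(
            profile.library_totals[s] > 0 for s in samples
        ):
            enrichment = call_enrichment(profile, cfg.alpha, cfg.enrichment_mode)
        tag_sets = {
            s: {to_rna(m.sequence) for m in annotated if m.counts.get(s, 0) > 0}
            for s in samples
        }
        partition = conservation_partition(tag_sets)
        venn_df = pd.DataFrame(
            sorted(
                (
                    ("+".join(sorted(sig)), len(tags))
                    for sig, tags in partition.regions.items()
                ),
                key=lambda r: (-r[1], r[0]),
            ),
            columns=["samples", "n_tags"],
        )
        comp = composition_profile(
            {m.sequence: m.total_count for m in annotated}
        )

    results = PipelineResults(
        samples=samples, stage_counts=stage_counts,
        tags_by_sample=tags_by_sample, candidates=candidates,
        annotated=annotated, families=families, profile=profile,
        enrichment=enrichment, venn=venn_df, composition=comp,
        target_sites=target_sites,
        n_mapped_tags=len(kept), n_multi_locus=len(discarded),
        n_unmapped=len(unmapped),
    )
    manifest.stage_table = stage_report(results).to_dict()
    if out_dir is not None:
        write_reports(results, Path(out_dir), manifest)
    manifest.finished = time.time()
    return results, manifest


def stage_report(results: PipelineResults) -> pd.DataFrame:
    """Per-sample stage accounting table (read and tag counts)."""
    rows = {}
    for s in results.samples:
        st = results.stage_counts[s]
        rows[s] = {
            "total_reads": st.total_reads,
            "low_quality": st.low_quality,
            "no_adapter": st.no_adapter + st.empty_insert,
            "bad_length_or_n": st.bad_length_or_n,
            "trimmed_reads": st.trimmed_reads,
            "unique_tags": st.unique_tags,
            "ncrna_tags": st.ncrna_tags,
            "masked_tags": st.masked_tags,
            "kept_tags": st.kept_tags,
            "kept_reads": st.kept_reads,
            "annotated_mirnas": sum(
                1 for m in results.annotated if m.counts.get(s, 0) > 0
            ),
            "rescued_mirnas": sum(
                1 for m in results.annotated
                if m.status == STATUS_RESCUED and m.counts.get(s, 0) > 0
            ),
            "mirna_families": sum(
                1 for f in results.families
                if any(m.counts.get(s, 0) > 0 for m in f.members)
            ),
        }
    return pd.DataFrame(rows)


def annotation_table(results: PipelineResults) -> pd.DataFrame:
    rows = []
    for m in results.annotated:
        row = {
            "tag": to_rna(m.sequence),
            "status": m.status,
            "family": m.family,
            "known_name": m.hit.known_name if m.hit else "",
            "mismatches": m.hit.mismatches if m.hit else "",
        }
        row.update({s: m.counts.get(s, 0) for s in results.samples})
        rows.append(row)
    return pd.DataFrame(rows)


def targets_table(results: PipelineResults) -> pd.DataFrame:
    rows = []
    for s in results.target_sites:
        rows.append({
            "mirna": to_rna(s.mirna),
            "transcript": s.transcript_id,
            "start": s.start + 1,               # 1-based inclusive in reports
            "end": s.end,
            "penalty": s.penalty,
            "cleavage_position": (s.cleavage_position + 1
                                  if s.cleavage_position is not None else ""),
            "validation_grade": s.penalty <= 4.0,
        })
    return pd.DataFrame(rows)


def write_reports(
    results: PipelineResults, out_dir: Path, manifest: RunManifest
) -> List[Path]:
    """Write the fixed-format report files; returns the paths written.

    P-values use scientific notation with 6 significant digits; re-parsing
    every TSV round-trips.  Empty result sets still produce headers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit(name: str, text: str) -> None:
        path = out_dir / name
        path.write_text(text)
        written.append(path)
        manifest.outputs.append(name)

    emit("stage_report.tsv", stage_report(results).to_csv(sep="\t"))
    emit("annotation.tsv", annotation_table(results).to_csv(sep="\t", index=False))
    emit("precursors.gff3", mcio.candidates_to_gff3(results.candidates))
    emit("structures.txt", mcio.structures_to_text(results.candidates))
    accepted = [c for c in results.candidates if c.accepted]
    fasta_lines = [
        f">pre_mir{i + 1}\n{to_rna(c.precursor_sequence)}"
        for i, c in enumerate(accepted)
    ]
    emit("precursors.fasta", "\n".join(fasta_lines) + ("\n" if fasta_lines else ""))
    if results.enrichment is not None:
        df = results.enrichment.copy()
        df["p"] = df["p"].map("{:.6g}".format)
        df["p_bh"] = df["p_bh"].map("{:.6g}".format)
        emit("enrichment.tsv", df.to_csv(sep="\t", index=False))
    if results.venn is not None:
        emit("venn.tsv", results.venn.to_csv(sep="\t", index=False))
    if results.composition is not None:
        emit("composition.tsv", results.composition.to_csv(sep="\t"))
    if results.target_sites:
        emit("targets.tsv", targets_table(results).to_csv(sep="\t", index=False))
    else:
        emit("targets.tsv", targets_table(results).reindex(
            columns=["mirna", "transcript", "start", "end", "penalty",
                     "cleavage_position", "validation_grade"]
        ).to_csv(sep="\t", index=False))
    emit("manifest.json", manifest.to_json())
    return written
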