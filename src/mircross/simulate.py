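"""Synthetic-data generator with machine-readable ground truth.

Every stage of the discovery pipeline can be exercised without downloads:
the generator plants pre-miRNA hairpins (mature/star duplexes with a bounded
number of mismatches, an optional asymmetric bulge and 2-nt 3' overhangs by
construction) into a random genome, synthesises multi-sample adapter-tagged
read libraries with heavy-tailed mature abundances, 5'-jittered processing
noise, genomic background and ncRNA contamination, plants target sites of an
exactly known penalty into random transcripts, and draws null/differential
count profiles for the digital-expression test.  A fixed seed makes every
output byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .config import DEFAULT_ADAPTER, revcomp
from .folding import fold_baseline
from .hairpin import duplex_report, find_star
from .preprocess import NcRNAReference, RawRead
from .homology import KnownMiRNA
from .targets import ScoringScheme

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {"G": "T", "T": "G"}


class GenerationError(RuntimeError):
    """Raised when a requested construct is infeasible."""


@dataclass
class SampleSpec:
    name: str
    library_size: int = 50_000
    fold_changes: Dict[str, float] = field(default_factory=dict)  # hairpin id -> fc

    def fold_change(self, hairpin_id: str) -> float:
        return self.fold_changes.get(hairpin_id, 1.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic libraries.

    Defaults emulate the sequenced flower libraries at desk scale: a 100 kb
    surrogate genome with 20 valid planted hairpins, mature lengths centred
    on 21 nt with a 5'-U bias, log-normal mature abundances (median ~150
    reads, heavy tail), 10% star reads, 10% 5'-jitter, genomic background and
    a small structural-ncRNA contamination, all behind the Illumina 3'
    adapter.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.4
    n_hairpins: int = 20
    duplex_mismatch_range: Tuple[int, int] = (0, 3)
    bulge_range: Tuple[int, int] = (0, 1)
    loop_length_range: Tuple[int, int] = (8, 15)
    mature_length_range: Tuple[int, int] = (20, 22)
    abundance_mu: float = 5.0        # log-normal over mature read counts
    abundance_sigma: float = 0.8
    jitter_prob: float = 0.1
    star_fraction: float = 0.1
    background_fraction: float = 0.3
    genomic_background_fraction: float = 0.2  # share of background that maps
    ncrna_fraction: float = 0.05
    conserved_fraction: float = 0.6  # matures drawn from the catalogue
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    min_locus_gap: int = 1_200       # keeps planted windows from overlapping
    samples: List[SampleSpec] = field(default_factory=lambda: [SampleSpec("s1")])

    def __post_init__(self) -> None:
        if not (0 <= self.duplex_mismatch_range[0] <= self.duplex_mismatch_range[1] <= 4):
            raise GenerationError("duplex mismatches must stay within 0..4")
        if not (0 <= self.bulge_range[0] <= self.bulge_range[1] <= 2):
            raise GenerationError("bulge must stay within 0..2 nt")
        if not (18 <= self.mature_length_range[0] <= self.mature_length_range[1] <= 26):
            raise GenerationError("mature length must stay within 18..26 nt")
        for frac in (self.gc_content, self.jitter_prob, self.star_fraction,
                     self.background_fraction, self.ncrna_fraction,
                     self.conserved_fraction):
            if not (0.0 <= frac <= 1.0):
                raise GenerationError("fractions must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass
class TruthRecord:
    hairpin_id: str
    seq_id: str
    start: int            # precursor interval, genomic 0-based half-open
    end: int
    strand: str
    mature_sequence: str  # sense orientation
    star_sequence: str
    mature_start: int     # genomic, + strand coords of the mature slice
    mature_end: int
    planted_mismatches: int
    planted_bulge: int
    conserved: bool
    known_name: str = ""
    base_abundance: int = 0
    expected_counts: Dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_mature(rng: np.random.Generator,
                  length_range: Tuple[int, int] = (20, 22),
                  five_prime_u_prob: float = 0.65) -> str:
    """A mature-like sequence; most begin with U (T), like canonical miRNAs."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    seq = _random_seq(rng, length)
    if rng.random() < five_prime_u_prob:
        seq = "T" + seq[1:]
    return seq


def synthesize_precursor(
    mature: str,
    mismatches: int = 0,
    bulge: int = 0,
    loop_length: int = 10,
    rng: Optional[np.random.Generator] = None,
    verify: bool = True,
    max_retries: int = 30,
) -> Tuple[str, str, int]:
    """Build a hairpin precursor = mature + loop + star.

    The star is the reverse complement of the paired part of the mature,
    mutated at ``mismatches`` internal positions (to bases that neither
    Watson-Crick nor G:U pair) with an optional ``bulge``-nt insertion, and
    2-nt 3' overhangs on both duplex ends by construction.  When ``verify``,
    candidate draws are folded with the baseline engine until the recovered
    duplex shows at most the planted number of mismatches.

    Returns (precursor, star_sequence, star_offset_in_precursor).
    """
    rng = rng or np.random.default_rng(0)
    L = len(mature)
    if not (18 <= L <= 26):
        raise GenerationError("mature must be 18-26 nt")
    if not (0 <= mismatches <= 4):
        raise GenerationError("planted mismatches outside the 0..4 design range")
    if not (0 <= bulge <= 2):
        raise GenerationError("planted bulge outside the 0..2 design range")
    last_error = None
    for _ in range(max_retries):
        star = [_COMP[mature[L - 3 - j]] for j in range(L - 2)]
        if mismatches:
            # internal paired star positions; star index j pairs mature L-3-j
            positions = rng.choice(np.arange(3, L - 5), size=mismatches, replace=False)
            for j in positions:
                m_base = mature[L - 3 - j]
                options = [b for b in "ACGT"
                           if b != _COMP[m_base] and _WOBBLE.get(b) != m_base]
                star[j] = str(rng.choice(options))
        if bulge:
            at = int(rng.integers(4, L - 6))
            star[at:at] = list(_random_seq(rng, bulge))
        star += list(_random_seq(rng, 2))  # star 3' overhang
        star_seq = "".join(star)
        # the loop's terminal bases must not pair the mature 3' overhang,
        # otherwise folding extends the helix and erases the planted 2-nt
        # overhang geometry
        loop = list(_random_seq(rng, loop_length))
        for k, m_base in ((1, mature[L - 2]), (2, mature[L - 1])):
            while (_COMP[loop[-k]] == m_base
                   or _WOBBLE.get(loop[-k]) == m_base):
                loop[-k] = str(rng.choice(list("ACGT")))
        loop = "".join(loop)
        precursor = mature + loop + star_seq
        star_offset = L + loop_length
        if not verify:
            return precursor, star_seq, star_offset
        structure, _ = fold_baseline(precursor)
        found = find_star(structure, (0, L))
        if found is None:
            last_error = "star not recovered from baseline fold"
            continue
        rep = duplex_report(structure, (0, L), found)
        if rep.mismatches <= mismatches and rep.largest_asymmetric_bulge <= max(bulge, 2):
            return precursor, star_seq, star_offset
        last_error = f"fold shows {rep.mismatches} mismatches (planted {mismatches})"
    raise GenerationError(f"could not realise precursor: {last_error}")


def make_catalogue(
    rng: np.random.Generator,
    n_entries: int = 30,
    length: int = 21,
    min_distance: int = 5,
    species: str = "syn",
) -> List[KnownMiRNA]:
    """A synthetic known-miRNA catalogue with minimum pairwise Hamming
    distance, so homology matching at <=2 mismatches cannot cross-assign."""
    seqs: List[str] = []
    guard = 0
    while len(seqs) < n_entries:
        cand = random_mature(rng, (length, length))
        if all(sum(a != b for a, b in zip(cand, s)) >= min_distance for s in seqs):
            seqs.append(cand)
        guard += 1
        if guard > 100 * n_entries:
            raise GenerationError("catalogue sampling failed")
    return [
        KnownMiRNA(name=f"miR{100 + i}a", sequence=s, species=species)
        for i, s in enumerate(seqs)
    ]


def generate_genome(
    config: SimulationConfig,
    catalogue: Optional[Sequence[KnownMiRNA]] = None,
) -> Tuple[Dict[str, str], List[TruthRecord]]:
    """Random genome with non-overlapping planted precursors on both strands."""
    if config.genome_length < config.n_hairpins * 200:
        raise GenerationError("genome too short for the requested hairpins")
    rng = config.rng(stream=1)
    genome = list(_random_seq(rng, config.genome_length, config.gc_content))
    truths: List[TruthRecord] = []
    occupied: List[Tuple[int, int]] = []
    catalogue = list(catalogue) if catalogue else []
    unused = list(range(len(catalogue)))
    planted_matures: set = set()
    for h in range(config.n_hairpins):
        conserved = bool(unused) and rng.random() < config.conserved_fraction
        if conserved:
            known = catalogue[unused.pop(int(rng.integers(len(unused))))]
            mature, known_name = known.sequence, known.name
        else:
            known_name = ""
            mature = random_mature(rng, config.mature_length_range)
            while mature in planted_matures:
                mature = random_mature(rng, config.mature_length_range)
        planted_matures.add(mature)
        k = int(rng.integers(config.duplex_mismatch_range[0],
                             config.duplex_mismatch_range[1] + 1))
        b = int(rng.integers(config.bulge_range[0], config.bulge_range[1] + 1))
        loop = int(rng.integers(config.loop_length_range[0],
                                config.loop_length_range[1] + 1))
        precursor, star_seq, star_off = synthesize_precursor(
            mature, k, b, loop, rng
        )
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, config.genome_length - len(precursor)))
            end = start + len(precursor)
            lo = start - config.min_locus_gap
            hi = end + config.min_locus_gap
            if all(e <= lo or s >= hi for s, e in occupied):
                placed = True
                break
        if not placed:
            raise GenerationError("could not place hairpin without overlap")
        occupied.append((start, end))
        embedded = precursor if strand == "+" else revcomp(precursor)
        genome[start:end] = list(embedded)
        if strand == "+":
            m_start, m_end = start, start + len(mature)
        else:
            m_start, m_end = end - len(mature), end
        abundance = max(2, int(round(float(
            rng.lognormal(config.abundance_mu, config.abundance_sigma)
        ))))
        truths.append(TruthRecord(
            hairpin_id=f"hp{h + 1}", seq_id="chr1", start=start, end=end,
            strand=strand, mature_sequence=mature, star_sequence=star_seq,
            mature_start=m_start, mature_end=m_end,
            planted_mismatches=k, planted_bulge=b, conserved=conserved,
            known_name=known_name, base_abundance=abundance,
        ))
    return {"chr1": "".join(genome)}, truths


def make_ncrna_reference(rng: np.random.Generator, n_entries: int = 6,
                         length: int = 120) -> NcRNAReference:
    classes = ["rRNA", "tRNA", "snRNA", "snoRNA"]
    entries = [
        (f"nc{i + 1}", classes[i % len(classes)], _random_seq(rng, length))
        for i in range(n_entries)
    ]
    return NcRNAReference(entries)


def _jittered_insert(genome: Mapping[str, str], truth: TruthRecord,
                     shift: int) -> str:
    """The mature read sequence with its 5' end shifted by ``shift`` nt."""
    seq = genome[truth.seq_id]
    length = truth.mature_end - truth.mature_start
    if truth.strand == "+":
        s = truth.mature_start + shift
        return seq[s : s + length]
    s = truth.mature_end - shift
    return revcomp(seq[s - length : s])


def simulate_sample(
    genome: Mapping[str, str],
    truths: Sequence[TruthRecord],
    sample: SampleSpec,
    config: SimulationConfig,
    ncrna: Optional[NcRNAReference] = None,
    stream: int = 10,
) -> Tuple[List[RawRead], Dict[str, int]]:
    """One adapter-tagged read library plus its per-tag truth counts.

    Mature reads follow the abundance model scaled by the sample's
    fold-change, with a ``jitter_prob`` chance of a +/-1-2 nt 5' offset; star
    reads are a fixed fraction of mature reads; genomic background and ncRNA
    fragments fill in contamination.  Reads carry the adapter 3' of the
    insert and uniform high qualities, truncated to ``read_length``.
    """
    rng = config.rng(stream=stream)
    reads: List[RawRead] = []
    truth_counts: Dict[str, int] = {}
    serial = 0

    def emit(insert: str) -> None:
        nonlocal serial
        serial += 1
        full = (insert + config.adapter)[: config.read_length]
        reads.append(RawRead(
            id=f"{sample.name}_{serial}",
            sequence=full,
            quality=[40] * len(full),
        ))

    for truth in truths:
        count = max(1, int(round(truth.base_abundance * sample.fold_change(truth.hairpin_id))))
        truth.expected_counts[sample.name] = count
        truth_counts[truth.mature_sequence] = (
            truth_counts.get(truth.mature_sequence, 0) + count
        )
        n_jitter = rng.binomial(count, config.jitter_prob)
        for _ in range(int(n_jitter)):
            shift = int(rng.choice([-2, -1, 1, 2]))
            insert = _jittered_insert(genome, truth, shift)
            if 18 <= len(insert) <= 26:
                emit(insert)
            else:
                emit(truth.mature_sequence)
        for _ in range(count - int(n_jitter)):
            emit(truth.mature_sequence)
        for _ in range(int(round(count * config.star_fraction))):
            emit(truth.star_sequence)

    # background: mostly fragments of transcripts absent from the surrogate
    # genome (cross-species mapping leaves most sRNA tags unmapped), plus a
    # genomic component of degradation fragments
    n_background = int(sample.library_size * config.background_fraction)
    n_genomic = int(n_background * config.genomic_background_fraction)
    chrom_names = list(genome)
    for i in range(n_background):
        length = int(rng.integers(18, 27))
        if i < n_genomic:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            seq = genome[chrom]
            start = int(rng.integers(0, len(seq) - length))
            frag = seq[start : start + length]
            if rng.random() < 0.5:
                frag = revcomp(frag)
        else:
            frag = _random_seq(rng, length, config.gc_content)
        emit(frag)

    if ncrna is not None and config.ncrna_fraction > 0:
        n_nc = int(sample.library_size * config.ncrna_fraction)
        for _ in range(n_nc):
            _, _, ref = ncrna.entries[int(rng.integers(len(ncrna.entries)))]
            length = int(rng.integers(18, 27))
            start = int(rng.integers(0, len(ref) - length))
            emit(ref[start : start + length])
    return reads, truth_counts


def plant_target(
    mirna: str,
    desired_penalty: float,
    transcript_length: int = 500,
    rng: Optional[np.random.Generator] = None,
    scheme: Optional[ScoringScheme] = None,
    max_retries: int = 50,
) -> Tuple[str, int, int]:
    """Transcript with one planted site of exactly ``desired_penalty``.

    Edits are applied to the perfect reverse-complement site with known
    contributions (non-core mismatch 1, core mismatch 2, wobble 0.5 doubled
    in core), summing exactly to the requested penalty.  Returns
    (transcript, site_start, site_end).
    """
    rng = rng or np.random.default_rng(0)
    scheme = scheme or ScoringScheme()
    m = mirna.upper().replace("U", "T")
    L = len(m)
    if transcript_length < L + 2:
        raise GenerationError("transcript too short")
    if desired_penalty < 0 or (round(desired_penalty * 2) != desired_penalty * 2):
        raise GenerationError(
            f"penalty {desired_penalty} not representable in 0.5 steps"
        )
    for _ in range(max_retries):
        try:
            site = _build_site(m, desired_penalty, rng, scheme)
        except GenerationError:
            continue
        start = int(rng.integers(1, transcript_length - L - 1))
        transcript = (
            _random_seq(rng, start) + site
            + _random_seq(rng, transcript_length - start - len(site))
        )
        return transcript, start, start + len(site)
    raise GenerationError(
        f"penalty {desired_penalty} not realisable for this miRNA"
    )


def _build_site(m: str, desired: float, rng: np.random.Generator,
                scheme: ScoringScheme) -> str:
    L = len(m)
    site = [_COMP[b] for b in m][::-1]          # perfect antiparallel site

    def site_index(pos: int) -> int:            # miRNA pos (1-based) -> index
        return L - pos

    core = [p for p in range(scheme.core_start, min(scheme.core_end, L) + 1)]
    # terminal positions are excluded: an edit there can tie with a bulged
    # alignment of a shifted window, making the planted interval ambiguous
    noncore = [p for p in range(2, L) if p not in core]
    rng.shuffle(core)
    rng.shuffle(noncore)
    remaining = desired
    while remaining > 1e-9:
        if remaining >= 2 and core:
            p = core.pop()
            mb = m[p - 1]
            options = [b for b in "ACGT" if b != _COMP[mb] and _WOBBLE.get(b) != mb]
            site[site_index(p)] = str(rng.choice(options))
            remaining -= 2
        elif remaining >= 1 and noncore:
            p = noncore.pop()
            mb = m[p - 1]
            options = [b for b in "ACGT" if b != _COMP[mb] and _WOBBLE.get(b) != mb]
            site[site_index(p)] = str(rng.choice(options))
            remaining -= 1
        elif remaining >= 1 and any(m[p - 1] in _WOBBLE for p in core):
            p = next(p for p in core if m[p - 1] in _WOBBLE)
            core.remove(p)
            site[site_index(p)] = _WOBBLE[m[p - 1]]
            remaining -= 1
        elif remaining >= 0.5 and any(m[p - 1] in _WOBBLE for p in noncore):
            p = next(p for p in noncore if m[p - 1] in _WOBBLE)
            noncore.remove(p)
            site[site_index(p)] = _WOBBLE[m[p - 1]]
            remaining -= 0.5
        else:
            raise GenerationError("cannot compose the requested penalty")
    return "".join(site)


def simulate_profiles(
    n_tags: int,
    samples: Sequence[Tuple[str, int]],
    fold_changes: Optional[Mapping[int, Mapping[str, float]]] = None,
    base_rate_per_million: float = 100.0,
    seed: int = 0,
):
    """Poisson count profiles for the digital-expression test.

    ``samples`` are (name, library_size); ``fold_changes`` maps tag index ->
    {sample: fc}.  Returns (CountProfile, truth_labels) where a truth label
    is True for tags carrying any non-unit fold-change.
    """
    from .profiles import CountProfile
    import pandas as pd

    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng((seed, 99))
    fold_changes = fold_changes or {}
    names = [s for s, _ in samples]
    sizes = {s: n for s, n in samples}
    counts = {}
    labels = {}
    for t in range(n_tags):
        tag = f"tag{t + 1}"
        fcs = fold_changes.get(t, {})
        labels[tag] = any(abs(f - 1.0) > 1e-12 for f in fcs.values())
        counts[tag] = {
            s: int(rng.poisson(base_rate_per_million * sizes[s] / 1e6
                               * fcs.get(s, 1.0)))
            for s in names
        }
    if not counts:
        df = pd.DataFrame(columns=names, dtype=int)
        return CountProfile(df, {s: float(sizes[s]) for s in names}), labels
    profile = CountProfile.from_counts(
        counts, {s: float(sizes[s]) for s in names}, samples=names
    )
    return profile, labels
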