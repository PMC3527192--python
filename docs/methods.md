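# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data model behind the tests, and the
numerical and design choices made where the design was genuinely open.

## Problem setting

MicroRNA discovery from small-RNA sequencing normally requires an assembled
genome: candidate precursors are cut from the genomic neighbourhood of
mapped reads, folded, and accepted only when the structure and the read
stack look like products of Dicer-like (DCL) processing.  For species
without a genome, the pipeline substitutes the genome of a close relative —
a *surrogate* — exploiting the strong conservation of pre-miRNA hairpins.
The cost is that many genuine tags no longer map (sequence divergence), so a
homology-rescue path against a known-miRNA catalogue recovers conserved
miRNAs that the surrogate cannot host.

## Pre-processing

Reads are trimmed at the leftmost occurrence of the 3′ sequencing adapter
(full internal match anywhere, or a terminal adapter prefix of at least
`min_overlap` = 6 nt); reads with no detectable adapter are discarded since
the insert boundary cannot be confirmed.  When qualities are present, reads
with any base below a Phred floor of 20 are dropped (FASTA input skips this
stage).  Inserts are kept at 18–26 nt with no ambiguous base, collapsed to
unique tags with per-sample counts, filtered against structural ncRNAs by
exact substring match on either strand (deterministic and conservative; no
mismatch tolerance), and masked when a single nucleotide exceeds 80 % of
positions (strict) or the tag is a pure 1–2-nt repeat.  Masking is
sequence-intrinsic; genome-repeat masking is handled separately by the
multi-locus filter.  Per-sample accounting reconciles exactly: every input
read is either kept or attributed to one rejection stage.

## Mapping and representatives

Placement on the surrogate genome is perfect-match, full-length, on both
strands, via a 16-nt seed table with full verification (identical to a
naive scan by construction; the seed length is purely an engineering
choice).  Tags with more than `max_loci` = 10 placements are discarded as
repeat-derived.  The two readings of the locus filter ("fewer than 10" vs
"more than 10 discarded") are one configuration value apart; the package
keeps tags with ≤ 10 loci.  Tags sharing a 5′ genomic end and strand form a
read stack; the highest-count tag represents the stack (ties: longer tag,
then lexicographically smaller), matching how DCL products pile up with a
common 5′ end.

## Folding engines

Two interchangeable engines satisfy one contract (same length, balanced
brackets, deterministic, lower energy = more stable):

* **Baseline** — maximum-weight non-crossing pairing (Nussinov-style DP)
  with GC = 3, AU = 2, GU = 1, hairpin loop ≥ 3, and a fully specified
  traceback (pair the leftmost base with its largest admissible partner).
  Deterministic and dependency-free, so structural unit tests are
  engine-independent.  Its limitation is intrinsic: with no loop or stacking
  penalties, random 1 kb windows pair promiscuously, so the baseline cannot
  by itself separate genuine stem-loops from background at window scale.
* **RNAfold** (ViennaRNA, via subprocess) — thermodynamic minimum free
  energy, the engine precursor discovery defaults to when the executable is
  available (`engine = auto`).  When a thermodynamic engine is active, an
  additional stability criterion applies: energy per nucleotide of the
  trimmed precursor ≤ −0.2 kcal/mol/nt.

## Hairpin discovery

Each representative with pooled count > 25 (a strict gate; pooling across
samples is this package's choice, so a locus well expressed in any library
can be discovered once for the study) nucleates a genomic window of the tag
± 500 nt, reverse-complemented into sense orientation on the − strand.  The
window is folded; the miRNA* is located from the pairing of the mature arm:
the partner side holding ≥ 70 % of paired mature bases is taken as the star
arm (a few bases snagging the flank are tolerated; a substantial split means
the tag straddles the terminal loop), at least half the mature must pair,
and the star interval is placed in the modal pairing register with 2-nt 3′
overhangs imposed — the overhang is the *definition* of the star, as in
standard annotation practice.  The region from the duplex ± 15 nt is then
trimmed and refolded, and the refolded structure is judged:

* mature length 18–26 nt;
* duplex mismatches ≤ 4 (facing unpaired runs, counted pairwise as
  min(run, run));
* largest asymmetric bulge ≤ 2 nt (|run − run|);
* single stem: ≥ 80 % of the mature's pairing points into the star region,
  and the path from the innermost duplex pair to the terminal loop is
  linear — at no nesting level may two or more substantial (≥ 2-pair)
  sibling helices branch off.  A real precursor continues as one helix
  (bulges and internal loops allowed); spurious long-range duplexes enclose
  a multiloop somewhere on that path;
* 3′ overhangs: measured against the facing strand's *end* (so terminal
  helix breathing does not masquerade as a longer overhang) and held to a
  sanity bound of ≤ max_overhang + max_bulge (5 nt by default) on both
  ends.  A hard 1–3 nt window proved fragile against MFE-structure noise
  (loop-internal pairing can legally consume or extend duplex ends), and
  the canonical geometry is already imposed where the star is defined;
* energy per nt ≤ −0.2 (thermodynamic engines only).

The probabilistic biogenesis scoring of miRDeep-style tools is replaced by a
deterministic **read-signature filter**: the fraction of window-mapped reads
whose 5′ end lies within ± 2 nt of the mature or star 5′ end must reach
0.75.  Loop and scatter reads count against it, because DCL products stack
at duplex ends.  The consistency fraction is recorded as the candidate's
score.  Overlapping precursor loci are merged; an accepted candidate beats a
rejected one, then higher mature count wins; merging is idempotent.

## Homology annotation and families

A mature is conserved when an ungapped comparison against the catalogue
within a ± 2-nt terminal shift finds ≤ 2 mismatches (overlap-only Hamming;
the shift itself is a tie-break, then catalogue name).  The tolerance
mirrors common catalogue-matching practice; the source analysis states only
that a similarity search was used, and both knobs are configuration values.
Unmapped tags with a catalogue hit are rescued as conserved; other unmapped
tags leave the miRNA set.  Conserved members group by the family parsed
from the catalogue name (strip the variant suffix of `miR<number>`);
unparseable names form singleton families.  Novel members are
single-linkage clustered (length ± 1, best-overlap, ≤ 2 mismatches) and the
clusters named `Ng1`, `Ng2`, … by descending total count (then smallest
member sequence), so the numbering is deterministic.

## Target prediction

Scoring is per miRNA position, 1-based from the 5′ end, antiparallel to the
transcript window: Watson–Crick 0, G:U wobble 0.5, mismatch 1, gapped
position 1, doubled at positions 2–13 (the core).  Gap handling allows one
single-nucleotide bulge on either strand per site, enough to reproduce the
0.5-step score granularity of the reported tables while keeping the scan a
small dynamic enumeration.  A target-side bulge is charged with the
multiplier of the miRNA position 3′ of the gap.  Sites with penalty ≤ 7 are
reported non-overlapping, ranked by penalty then position; penalty ≤ 4.0
(inclusive) marks validation-grade targets.  The predicted cleavage site is
the transcript base paired to miRNA position 10 — slicing occurs between
the bases paired to positions 10 and 11 — computed by walking the actual
alignment, so bulges shift it correctly.  Only the sense strand of
transcripts is scanned (oriented mRNA).  In the full pipeline, scanning is
restricted to each family's major (highest-count) sequence.

## Digital expression comparison

For counts x (library 1, total N1) and y (library 2, total N2), with
r = N2/N1:

    P(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) )

evaluated via log-gamma.  The two-sided p-value doubles the smaller tail,
capped at 1; both tails include the observed count and are computed by
direct log-space summation (the upper tail sums forward to a bound of
mean + 60 SD rather than using 1 − CDF, avoiding cancellation).  The
statistic depends on the totals only through r, hence is scale invariant.
Enrichment defaults to one-vs-rest (a sample against all others pooled) at
α = 0.001 with the extra requirement that the sample's normalized rate
exceed the pooled rate; a pairwise-any mode is provided because some
reported calls are only explicable pairwise.  No multiple-testing
correction is applied in the calls (matching the source analysis); a
Benjamini–Hochberg column is emitted for information.  Under a null of a
common rate, the two-sided test is calibrated (rejection ≈ α); the
direction-gated flag for a given sample fires on about half of those
rejections by construction.  Normalization totals default to the per-sample
sum of annotated-miRNA reads; explicit totals (e.g. the printed per-library
18–26 nt totals) can be supplied instead.

Conservation is summarised by partitioning tags by the exact subset of
samples they appear in (Venn regions); composition as read-weighted
fractions over length (18–26) × first nucleotide.

## Synthetic data model

The generator emulates the sequenced flower libraries at desk scale:

* **Precursors** — mature (18–26 nt, 21-nt-centred, 65 % 5′-U) + loop
  (8–15 nt) + star, where the star is the reverse complement of the paired
  mature region mutated at ≤ 4 positions (to bases that neither pair nor
  wobble), optionally carrying a ≤ 2-nt bulge, with 2-nt 3′ overhangs by
  construction.  Loop ends are chosen not to pair the mature 3′ overhang
  (otherwise folding would legitimately extend the helix and erase the
  planted geometry).  Draws are verified by fold-and-report and retried.
* **Genome** — i.i.d. background at a set GC content (0.4) with precursors
  embedded at non-overlapping loci (≥ 1.2 kb apart so discovery windows
  stay disjoint) on random strands.
* **Libraries** — mature counts are log-normal (μ = 5.0, σ = 0.8 on the
  log scale; median ≈ 150 reads, heavy tail like real miRNA abundance
  spreads), scaled per sample by fold-changes; 10 % of reads jittered ± 1–2
  nt at the 5′ end; star reads at 10 % of mature (stars are degraded in
  vivo; the ratio is a configuration value); 30 % of the library is
  background, of which only 20 % is genomic — cross-species mapping leaves
  most real background unmapped, and a tiny surrogate genome would
  otherwise accumulate unrealistically dense per-window coverage; 5 % ncRNA
  fragments.  Every read carries the adapter 3′ of the insert, truncated to
  36 nt, with uniform high qualities.
* **Targets** — sites built from the perfect reverse complement by edits
  with known penalty contributions summing exactly to the requested score
  (terminal miRNA positions are excluded from edits, since a terminal edit
  can tie with a bulged alignment of a shifted window).
* **Profiles** — Poisson counts around library-scaled rates with designated
  fold-changes and emitted truth labels.

What the generator does **not** model: sequencing errors, RNA degradation
gradients, expression-correlated background (real degradation clusters on
expressed loci), isomiR end-heterogeneity beyond symmetric 5′ jitter,
genomic repeats, and polymorphism.  Passing tests therefore demonstrate
correctness of the machinery under clean biogenesis-like signals, not
performance on adversarial real libraries.

## Numerical and operational choices

* All coordinates are 0-based half-open internally; GFF3 and report tables
  are 1-based inclusive.  Internally DNA (T); mature/report output RNA (U).
* Deterministic orderings everywhere (stated tie-breaks), so reruns are
  byte-identical; report files carry no wall-clock timestamps.
* p-values print in scientific notation with 6 significant digits.  A
  p-value smaller than ~1e-308 underflows to 0.0 in double precision.
* Seeded randomness only, through numpy Generators keyed off a single
  configuration seed with named streams.
* Test problem sizes: the end-to-end recovery study uses a 100 kb genome
  with 20 hairpins and two 50 k-read libraries; the routine fixture is a
  30 kb genome with 6 hairpins, sized so that a discovery window spans only
  a few percent of the genome (keeping per-window background coverage in a
  realistic regime).

## Known limitations

* The baseline folder is a structural stand-in: window-scale discovery
  needs the thermodynamic engine for specificity (the package selects it
  automatically when present).
* When the mature-arm candidate of a locus fails structural criteria but
  the star-arm candidate passes, the locus is reported with the star arm as
  mature — the usual expression-based arm choice is only as good as the
  fold.
* Homology matching is ungapped; catalogue entries differing by indels are
  missed (configurable shift tolerance mitigates terminal cases only).
* The Audic–Claverie test treats libraries as exchangeable pools; no
  biological replication or overdispersion modelling is attempted.
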