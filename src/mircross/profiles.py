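"""Digital expression comparison of miRNA profiles across libraries.

The Audic-Claverie test asks whether observing ``y`` reads of a tag in a
library of ``N2`` total reads is surprising given ``x`` reads in a library of
``N1``.  With r = N2/N1 the conditional probability of the second count given
the first is

    P(y | x) = r**y * (x + y)! / (x! * y! * (1 + r)**(x + y + 1))

and a two-sided p-value doubles the smaller tail, capped at 1.  Everything is
evaluated in log space (log-gamma) with vectorised tail sums, so unequal and
very large library sizes (millions of reads) are handled exactly.

The module also produces one-vs-rest / pairwise enrichment calls at a fixed
significance threshold (the study used p < 0.001 with no multiplicity
correction; a Benjamini-Hochberg column is emitted for information only),
presence/absence conservation partitions across samples (Venn regions), and
read-weighted length x 5'-nucleotide composition profiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import to_rna


def _check_counts(x: int, y: int, n1: float, n2: float) -> None:
    for v in (x, y):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"counts must be non-negative integers, got {v!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def _log_prob(ks: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log P(k | x) for an array of k, with r = N2/N1."""
    log1pr = np.logaddexp(0.0, log_r)
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * log1pr
    )


def audic_probability(x: int, y: int, n1: float, n2: float) -> float:
    """P(y | x): probability of the second library's count given the first."""
    _check_counts(x, y, n1, n2)
    return float(np.exp(_log_prob(np.array([y], dtype=float), int(x),
                                  math.log(n2 / n1))[0]))


def _upper_tail_limit(x: int, y: int, log_r: float) -> int:
    # the distribution of Y|x has mean ~ (x+1) * r and sd ~ sqrt of that * (1+r)
    r = math.exp(log_r)
    mean = (x + 1) * r
    sd = math.sqrt(max(mean * (1 + r), 1.0))
    return int(max(y, mean) + 60 * sd + 1000)


def audic_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value: min(1, 2 * min(lower, upper) ).

    Both tails include the observed count; each tail is a direct log-space
    summation (no 1 - cumulative cancellation).  Depends on the totals only
    through their ratio, so it is scale invariant.
    """
    _check_counts(x, y, n1, n2)
    x, y = int(x), int(y)
    log_r = math.log(n2 / n1)
    lower = float(np.exp(logsumexp(_log_prob(np.arange(0, y + 1, dtype=float), x, log_r))))
    hi = _upper_tail_limit(x, y, log_r)
    upper = float(np.exp(logsumexp(_log_prob(np.arange(y, hi + 1, dtype=float), x, log_r))))
    return min(1.0, 2.0 * min(lower, upper))


@dataclass(frozen=True)
class AudicResult:
    x: int
    y: int
    n1: float
    n2: float
    p_two_sided: float
    direction: str  # up_in_2 / down_in_2 / none

    @staticmethod
    def test(x: int, y: int, n1: float, n2: float) -> "AudicResult":
        p = audic_pvalue(x, y, n1, n2)
        rate1, rate2 = x / n1, y / n2
        if rate2 > rate1:
            direction = "up_in_2"
        elif rate2 < rate1:
            direction = "down_in_2"
        else:
            direction = "none"
        return AudicResult(int(x), int(y), n1, n2, p, direction)


@dataclass
class CountProfile:
    """Tags/families x samples count matrix with per-sample library totals."""

    counts: pd.DataFrame                 # rows: tag/family; columns: samples
    library_totals: Dict[str, float]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if s not in self.library_totals:
                raise ValueError(f"missing library total for sample {s!r}")
            if self.library_totals[s] < self.counts[s].sum():
                raise ValueError(f"total for {s!r} below its column sum")

    @staticmethod
    def from_counts(
        counts: Mapping[str, Mapping[str, int]],
        library_totals: Optional[Mapping[str, float]] = None,
        samples: Optional[Sequence[str]] = None,
    ) -> "CountProfile":
        """Build from {tag: {sample: count}}; totals default to column sums."""
        df = pd.DataFrame(counts).T.fillna(0).astype(int)
        if samples is not None:
            df = df.reindex(columns=list(samples), fill_value=0)
        totals = (
            dict(library_totals)
            if library_totals is not None
            else {s: float(df[s].sum()) for s in df.columns}
        )
        return CountProfile(df, totals)

    def normalized(self) -> pd.DataFrame:
        """Counts per million of the library total."""
        return self.counts / pd.Series(self.library_totals) * 1e6


def call_enrichment(
    profile: CountProfile,
    alpha: float = 0.001,
    mode: str = "one_vs_rest",
) -> pd.DataFrame:
    """Per (tag, sample) enrichment table.

    ``one_vs_rest``: sample s is enriched for tag t iff its count is
    significantly high versus all other samples pooled and its normalized
    rate exceeds the pooled rate.  ``pairwise_any``: significant and higher
    versus at least one single other sample.  Columns: tag, sample, x, y,
    n1, n2, p, enriched, p_bh (Benjamini-Hochberg, informational only).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    samples = list(profile.counts.columns)
    if len(samples) < 2:
        raise ValueError("enrichment needs at least 2 samples")
    if mode not in ("one_vs_rest", "pairwise_any"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for tag, row in profile.counts.iterrows():
        for s in samples:
            y = int(row[s])
            n2 = profile.library_totals[s]
            if mode == "one_vs_rest":
                x = int(sum(row[o] for o in samples if o != s))
                n1 = sum(profile.library_totals[o] for o in samples if o != s)
                res = AudicResult.test(x, y, n1, n2)
                enriched = res.p_two_sided < alpha and res.direction == "up_in_2"
                rows.append((tag, s, x, y, n1, n2, res.p_two_sided, enriched))
            else:
                best = None
                enriched = False
                for o in samples:
                    if o == s:
                        continue
                    res = AudicResult.test(int(row[o]), y,
                                           profile.library_totals[o], n2)
                    if best is None or res.p_two_sided < best.p_two_sided:
                        best = res
                    if res.p_two_sided < alpha and res.direction == "up_in_2":
                        enriched = True
                rows.append((tag, s, best.x, y, best.n1, n2,
                             best.p_two_sided, enriched))
    df = pd.DataFrame(
        rows, columns=["tag", "sample", "x", "y", "n1", "n2", "p", "enriched"]
    )
    df["p_bh"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


@dataclass
class ConservationPartition:
    """Tags grouped by the exact subset of samples they occur in."""

    regions: Dict[FrozenSet[str], FrozenSet[str]]  # sample subset -> tags
    samples: Tuple[str, ...]

    def region_counts(self) -> Dict[FrozenSet[str], int]:
        return {sig: len(tags) for sig, tags in self.regions.items()}

    def shared_by_all(self) -> FrozenSet[str]:
        return self.regions.get(frozenset(self.samples), frozenset())


def conservation_partition(
    tag_sets: Mapping[str, set]
) -> ConservationPartition:
    """Venn-style partition of tags by presence/absence across samples."""
    if not tag_sets:
        raise ValueError("need at least one sample")
    samples = tuple(tag_sets)
    universe = set().union(*tag_sets.values())
    regions: Dict[FrozenSet[str], set] = {}
    for tag in universe:
        sig = frozenset(s for s in samples if tag in tag_sets[s])
        regions.setdefault(sig, set()).add(tag)
    return ConservationPartition(
        {sig: frozenset(tags) for sig, tags in regions.items()}, samples
    )


LENGTH_RANGE = range(18, 27)
FIRST_NT = ("A", "C", "G", "U")


def composition_profile(tags_with_counts: Mapping[str, int]) -> pd.DataFrame:
    """Read-weighted fractions over insert length x first nucleotide.

    Rows are lengths 18-26, columns A/C/G/U; entries sum to 1 over tags in
    range.  Index/columns cover the full grid even when empty.
    """
    if not tags_with_counts:
        raise ValueError("empty input")
    mat = pd.DataFrame(0.0, index=list(LENGTH_RANGE), columns=list(FIRST_NT))
    total = 0
    for seq, count in tags_with_counts.items():
        length = len(seq)
        first = to_rna(seq[0].upper())
        if length in LENGTH_RANGE and first in FIRST_NT:
            mat.loc[length, first] += count
            total += count
    if total:
        mat /= total
    return mat
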