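"""Pipeline configuration.

All numeric knobs of the discovery pipeline live in :class:`PipelineConfig`.
The defaults encode the analysis parameters of the rose-flower sRNA study this
package implements: Illumina 3' adapter, 18-26 nt insert range, at most 10
perfect-match genomic loci per tag, a 500 bp precursor window, a 15 bp refold
margin, a strict >25 read-copy gate before folding, homology tolerance of 2
mismatches / 2 nt terminal shift against the known-miRNA catalogue, a target
penalty report cutoff of 7 with a validation cutoff of 4 ("four or less"),
and an enrichment significance threshold of 0.001.

Config files are plain text ``key = value`` lines (``#`` comments allowed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

log = logging.getLogger("mircross")

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA presentation (T->U); internal storage is DNA."""
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


class ConfigError(ValueError):
    """Raised for out-of-range or unknown configuration values."""


# (low, high) inclusive validation ranges per numeric field
_RANGES = {
    "min_len": (10, 26),
    "max_len": (18, 50),
    "min_overlap": (1, 24),
    "phred_floor": (0, 60),
    "max_loci": (1, 10_000),
    "seed_length": (8, 18),
    "window_margin": (0, 10_000),
    "refold_margin": (0, 1_000),
    "min_copies": (0, 10**9),
    "min_consistency": (0.0, 1.0),
    "duplex_max_mismatch": (0, 10),
    "max_bulge": (0, 10),
    "min_overhang": (0, 5),
    "max_overhang": (0, 10),
    "homology_max_mm": (0, 10),
    "homology_max_shift": (0, 10),
    "target_report_cutoff": (0.0, 100.0),
    "validation_cutoff": (0.0, 100.0),
    "alpha": (0.0, 1.0),
    "seed": (0, 2**31 - 1),
}


@dataclass
class PipelineConfig:
    """End-to-end parameters; defaults reproduce the study's stated settings."""

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 6
    phred_floor: int = 20
    min_len: int = 18
    max_len: int = 26
    max_loci: int = 10
    seed_length: int = 16
    window_margin: int = 500
    refold_margin: int = 15
    min_copies: int = 25          # strict >: a mature needs more than this many reads
    min_consistency: float = 0.75
    duplex_max_mismatch: int = 4
    max_bulge: int = 2
    min_overhang: int = 1
    max_overhang: int = 3
    homology_max_mm: int = 2
    homology_max_shift: int = 2
    target_report_cutoff: float = 7.0
    validation_cutoff: float = 4.0
    alpha: float = 0.001
    enrichment_mode: str = "one_vs_rest"   # or "pairwise_any"
    normalization_totals: str = "auto"     # "auto" or "explicit"
    engine: str = "auto"                   # "baseline", "rnafold" or "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (lo, hi) in _RANGES.items():
            val = getattr(self, key)
            if not (lo <= val <= hi):
                raise ConfigError(f"{key} out of range [{lo}, {hi}]: {val!r}")
        if self.min_len > self.max_len:
            raise ConfigError("min_len exceeds max_len")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha out of range (0, 1)")
        if self.enrichment_mode not in ("one_vs_rest", "pairwise_any"):
            raise ConfigError(f"enrichment_mode unknown: {self.enrichment_mode!r}")
        if self.normalization_totals not in ("auto", "explicit"):
            raise ConfigError(
                f"normalization_totals unknown: {self.normalization_totals!r}"
            )
        if self.engine not in ("baseline", "rnafold", "auto"):
            raise ConfigError(f"engine unknown: {self.engine!r}")
        if not self.adapter or set(self.adapter) - set(DNA):
            raise ConfigError("adapter must be a non-empty ACGT string")
        if self.min_overlap > len(self.adapter):
            raise ConfigError("min_overlap exceeds adapter length")

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())


def load_config(path: Union[str, Path, None] = None, **overrides) -> PipelineConfig:
    """Load a key=value config file; missing keys fall back to defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming the
    key. ``overrides`` are applied after the file.
    """
    values: dict = {}
    if path is not None:
        known = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value': {raw!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ConfigError(f"unknown config key: {key!r}")
            values[key] = _coerce(key, val)
    values.update(overrides)
    return PipelineConfig(**values)


def _coerce(key: str, val: str):
    default = getattr(PipelineConfig, key, None)
    if isinstance(default, bool):
        return val.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        try:
            return int(val)
        except ValueError as exc:
            raise ConfigError(f"{key}: not an integer: {val!r}") from exc
    if isinstance(default, float):
        try:
            return float(val)
        except ValueError as exc:
            raise ConfigError(f"{key}: not a number: {val!r}") from exc
    return val
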