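"""RNA secondary-structure engines.

Two engines share one contract: ``fold(sequence) -> (dot_bracket, energy)``
with the structure the same length as the sequence, brackets balanced, no
pseudoknots, and deterministic output.  Lower energy means more stable.

* :class:`BaselineFolder` — a maximum-weight non-crossing pairing (weighted
  Nussinov dynamic programme; GC=3, AU=2, GU=1, hairpin loop >= 3) with a
  fully specified traceback, so every structure is reproducible without any
  thermodynamic parameter tables.  Its "energy" is minus the total pair
  weight, in arbitrary units.
* :class:`RNAfoldEngine` — minimum-free-energy folding through the RNAfold
  command-line program (ViennaRNA), energies in kcal/mol.  Preferred for
  precursor discovery when the executable is available, since thermodynamic
  folding isolates genuine stem-loops inside long genomic windows far better
  than a pure pair-count objective.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

from .config import to_rna

MIN_LOOP = 3  # unpaired bases required inside a hairpin loop

_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def pair_weight(a: str, b: str) -> int:
    """GC=3, AU=2, GU=1, else 0 (T and U equivalent)."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    return _PAIR_WEIGHT.get((a, b), 0)


@dataclass
class FoldingEngine:
    """A named, deterministic folding callable."""

    fold: Callable[[str], Tuple[str, float]]
    name: str
    thermodynamic: bool


def _weight_matrix(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)
    lut = np.zeros((256, 256), dtype=np.int32)
    for (a, b), w in _PAIR_WEIGHT.items():
        lut[ord(a), ord(b)] = w
    return lut[codes[:, None], codes[None, :]]


def _nussinov_table(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Fill W[i, j] = best pair weight on seq[i..j] (inclusive ends).

    Recursion: W[i,j] = max( W[i+1,j],
                             max_{k>=i+MIN_LOOP+1, k<=j, pairable}
                                 w(i,k) + W[i+1,k-1] + W[k+1,j] ).
    W is padded by one row/column of zeros so out-of-range lookups read 0.
    """
    n = len(seq)
    wt = _weight_matrix(seq)
    W = np.zeros((n + 1, n + 1), dtype=np.int32)
    cols = np.arange(n)
    for i in range(n - 2, -1, -1):
        ks = np.nonzero(wt[i, i + MIN_LOOP + 1 :])[0] + i + MIN_LOOP + 1
        row = W[i + 1, :n].copy()
        if ks.size:
            # candidate[j] = max_k ( w(i,k) + W[i+1,k-1] + W[k+1,j] ), k <= j
            B = wt[i, ks] + W[i + 1, ks - 1]
            M = B[:, None] + W[ks + 1, :n]
            M = np.where(cols[None, :] >= ks[:, None], M, -1)
            np.maximum(row, M.max(axis=0), out=row)
        row[:i] = 0
        W[i, :n] = row
    return W, wt


def fold_baseline(sequence: str) -> Tuple[str, float]:
    """Deterministic maximum-weight non-crossing fold.

    Traceback prefers pairing the leftmost base with the largest admissible
    partner; the bifurcation point is then fixed by that pair.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence.upper()) - set("ACGTUN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    n = len(sequence)
    if n < MIN_LOOP + 2:
        return "." * n, 0.0
    W, wt = _nussinov_table(sequence)
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = W[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(j, i + MIN_LOOP, -1):
            w = wt[i, k]
            if w and w + W[i + 1, k - 1] + W[k + 1, j] == target:
                structure[i] = "("
                structure[k] = ")"
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure), -float(W[0, n - 1])


def pair_table(structure: str) -> list:
    """partner[i] = index paired with i, or -1; rejects unbalanced input."""
    partner = [-1] * len(structure)
    stack: list = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"bad structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return partner


_RNAFOLD_RE = re.compile(r"^([.()]+)\s+\(\s*(-?\d+\.?\d*)\s*\)")


def fold_rnafold(sequence: str, executable: str = "RNAfold") -> Tuple[str, float]:
    """Minimum-free-energy fold via the RNAfold CLI (kcal/mol)."""
    if not sequence:
        raise ValueError("empty sequence")
    proc = subprocess.run(
        [executable, "--noPS"],
        input=to_rna(sequence.upper()) + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    for line in proc.stdout.splitlines():
        m = _RNAFOLD_RE.match(line.strip())
        if m:
            structure, energy = m.group(1), float(m.group(2))
            if len(structure) != len(sequence):
                raise RuntimeError("RNAfold structure length mismatch")
            return structure, energy
    raise RuntimeError(f"unparseable RNAfold output: {proc.stdout!r}")


BASELINE_ENGINE = FoldingEngine(fold=fold_baseline, name="baseline", thermodynamic=False)


def rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def get_engine(name: str = "auto") -> FoldingEngine:
    """Resolve an engine by name: 'baseline', 'rnafold', or 'auto'.

    'auto' prefers RNAfold when installed and falls back to the baseline.
    """
    if name == "baseline":
        return BASELINE_ENGINE
    if name == "rnafold":
        if not rnafold_available():
            raise RuntimeError("RNAfold executable not found on PATH")
        return FoldingEngine(fold=fold_rnafold, name="rnafold", thermodynamic=True)
    if name == "auto":
        return get_engine("rnafold") if rnafold_available() else BASELINE_ENGINE
    raise ValueError(f"unknown engine {name!r}")
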