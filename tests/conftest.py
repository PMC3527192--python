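"""Shared fixtures: small seeded simulations and independent oracles."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from mircross.simulate import (
    SampleSpec,
    SimulationConfig,
    generate_genome,
    make_catalogue,
    make_ncrna_reference,
    simulate_sample,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_sim():
    """A compact two-sample study: 30 kb genome, 6 planted hairpins."""
    sim = SimulationConfig(
        seed=7,
        genome_length=30_000,
        n_hairpins=6,
        min_locus_gap=1_200,
        samples=[SampleSpec("a", 8_000), SampleSpec("b", 8_000)],
    )
    catalogue = make_catalogue(sim.rng(stream=5), n_entries=12)
    genome, truths = generate_genome(sim, catalogue)
    ncrna = make_ncrna_reference(sim.rng(stream=6))
    reads = {}
    for k, spec in enumerate(sim.samples):
        r, _ = simulate_sample(genome, truths, spec, sim, ncrna, stream=10 + k)
        reads[spec.name] = r
    return {
        "sim": sim,
        "catalogue": catalogue,
        "genome": genome,
        "truths": truths,
        "ncrna": ncrna,
        "reads": reads,
    }


# ---------------------------------------------------------------------------
# independent extended-precision oracle for the digital expression test
# ---------------------------------------------------------------------------

def audic_term_exact(k: int, x: int, n1: int, n2: int) -> Fraction:
    """P(k | x) as an exact rational: r^k (x+k)! / (x! k! (1+r)^(x+k+1))."""
    r = Fraction(n2, n1)
    num = Fraction(1)
    # (x+k)! / (x! k!) = C(x+k, k)
    binom = Fraction(1)
    for i in range(1, k + 1):
        binom *= Fraction(x + i, i)
    return r**k * binom / (1 + r) ** (x + k + 1)


def audic_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided p by exact rational tail summation (the total mass is
    exactly 1, so the upper tail is 1 minus the strict lower tail)."""
    lower = sum(audic_term_exact(k, x, n1, n2) for k in range(0, y + 1))
    upper = 1 - (lower - audic_term_exact(y, x, n1, n2))
    p = 2 * min(lower, upper)
    return min(Fraction(1), p)
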