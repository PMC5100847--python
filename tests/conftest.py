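"""Shared fixtures: small simulated datasets reused across test modules.

Session scope keeps the expensive read simulations to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

import hapspec as hs


@pytest.fixture(scope="session")
def het_diploid():
    """200-kb diploid at 1.25% heterozygosity."""
    return hs.simulate_diploid(
        hs.DiploidSimConfig(genome_length=200_000, heterozygosity=0.0125, seed=101)
    )


@pytest.fixture(scope="session")
def het_reads(het_diploid):
    """Error-free 30x-per-haplotype reads from the 200-kb diploid."""
    return hs.simulate_reads(
        het_diploid,
        hs.ReadSimConfig(read_length=150, depth_per_haplotype=30.0, seed=102),
    )


@pytest.fixture(scope="session")
def het_assembly(het_diploid):
    """Draft assembly of the 200-kb diploid with half of het regions split."""
    return hs.simulate_assembly(
        het_diploid,
        hs.AssemblySimConfig(mean_fragment=8_000.0, split_probability=0.5, seed=103),
    )


@pytest.fixture(scope="session")
def het_depth_profile(het_reads, het_assembly):
    reads, _ = het_reads
    contigs, _ = het_assembly
    return hs.pseudo_map(reads, contigs)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-base rate."""
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)
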