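"""Shared synthetic fixtures.

Session-scoped because the planted-structure datasets (10^5-10^6 pairs) are
reused by several modules' recovery tests; each is fully determined by its
seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import loopscape as ls


def qc_chain(pairs, genome, chimeric_threshold=2000, chimeric_filter=True):
    """parse -> (chimeric filter) -> sort -> dedup -> classify."""
    parsed, stats = ls.parse_pairs(pairs, genome)
    if chimeric_filter:
        parsed, _ = ls.filter_chimeric(parsed, chimeric_threshold)
    deduped, _ = ls.deduplicate(ls.sort_pairs(parsed))
    return ls.classify(deduped), stats


def matrices_for(params: ls.SimParams, genome: ls.GenomeSpec, resolution=10_000):
    pairs, truth = ls.simulate_pairs(genome, params)
    classified, _ = qc_chain(pairs, genome, chimeric_filter=False)
    ms = ls.bin_pairs(classified, genome, resolution)
    return ms, truth


@pytest.fixture(scope="session")
def genome20():
    """One 20 Mb chromosome."""
    return ls.generate_genome(1, (20_000_000, 20_000_000), 2)


@pytest.fixture(scope="session")
def genome30():
    """One 30 Mb chromosome (loop fixtures)."""
    return ls.generate_genome(1, (30_000_000, 30_000_000), 4)


@pytest.fixture(scope="session")
def qc_fixture():
    """Two chromosomes, every QC path exercised (trans/dup/unmapped/short)."""
    genome = ls.generate_genome(2, (20_000_000, 20_000_000), 7)
    params = ls.SimParams(
        n_pairs=200_000,
        trans_fraction=0.30,
        duplicate_rate=0.20,
        unmapped_rate=0.10,
        short_fraction=0.05,
        seed=1,
    )
    pairs, truth = ls.simulate_pairs(genome, params)
    return pairs, truth, genome


@pytest.fixture(scope="session")
def comp_fixture(genome20):
    """Planted 1 Mb compartment checkerboard at 3x strength."""
    params = ls.SimParams(
        n_pairs=400_000,
        trans_fraction=0.0,
        duplicate_rate=0.0,
        unmapped_rate=0.0,
        short_fraction=0.0,
        compartment_size=1_000_000,
        compartment_strength=3.0,
        seed=5,
    )
    ms, truth = matrices_for(params, genome20)
    balanced = ls.balance(ms.cis["chr1"])
    return balanced, truth


@pytest.fixture(scope="session")
def tad_fixture(genome20):
    """Planted TAD blocks every 2 Mb at 4x within-block contrast."""
    bounds = tuple(range(2_000_000, 20_000_000, 2_000_000))
    params = ls.SimParams(
        n_pairs=500_000,
        trans_fraction=0.0,
        duplicate_rate=0.0,
        unmapped_rate=0.0,
        short_fraction=0.0,
        tad_boundaries={"chr1": bounds},
        tad_strength=4.0,
        seed=11,
    )
    ms, truth = matrices_for(params, genome20)
    balanced = ls.balance(ms.cis["chr1"])
    return balanced, truth


LOOP_SPOTS = [
    (3_000_000, 3_500_000),
    (8_000_000, 9_200_000),
    (12_000_000, 12_800_000),
    (18_000_000, 20_000_000),
    (25_000_000, 25_400_000),
]


@pytest.fixture(scope="session")
def loop_fixture(genome30):
    """Five planted loops at 10x over the local background, 10^6 pairs."""
    loops = tuple(ls.PlantedLoop("chr1", a, b, 10.0) for a, b in LOOP_SPOTS)
    params = ls.SimParams(
        n_pairs=1_000_000,
        trans_fraction=0.0,
        duplicate_rate=0.0,
        unmapped_rate=0.0,
        short_fraction=0.0,
        loops=loops,
        seed=9,
    )
    ms, truth = matrices_for(params, genome30)
    balanced = ls.balance(ms.cis["chr1"])
    return balanced, ms.cis["chr1"], truth


@pytest.fixture(scope="session")
def null_fixture(genome30):
    """Loop-free twin of the loop fixture (null calibration)."""
    params = ls.SimParams(
        n_pairs=1_000_000,
        trans_fraction=0.0,
        duplicate_rate=0.0,
        unmapped_rate=0.0,
        short_fraction=0.0,
        seed=21,
    )
    ms, _ = matrices_for(params, genome30)
    return ls.balance(ms.cis["chr1"]), ms.cis["chr1"]


@pytest.fixture(scope="session")
def alpha_decay_slopes():
    """Fitted P(s) slopes for generator decay exponents 0.8 / 1.0 / 1.2."""
    genome = ls.generate_genome(1, (50_000_000, 50_000_000), 12)
    out = {}
    for alpha, seed in ((0.8, 3), (1.0, 4), (1.2, 5)):
        params = ls.SimParams(
            n_pairs=500_000,
            alpha=alpha,
            trans_fraction=0.0,
            duplicate_rate=0.0,
            unmapped_rate=0.0,
            short_fraction=0.0,
            seed=seed,
        )
        ms, _ = matrices_for(params, genome)
        out[alpha] = ls.contact_decay(ms)["all"].slope()
    return out
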