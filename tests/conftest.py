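import numpy as np
import pytest

from g4scape.genome_io import GenomeIndex, Interval, IntervalSet
from g4scape.synthetic_data import SimSpec, simulate_all


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across test modules."""
    return simulate_all(SimSpec(seed=11))


@pytest.fixture(scope="session")
def conserved_repeat_set(study):
    cons = study.repeat_truth[study.repeat_truth.conserved]
    return IntervalSet(
        [Interval(r.chrom, int(r.start), int(r.end)) for r in cons.itertuples()],
        study.genome,
    )


@pytest.fixture
def small_genome():
    return GenomeIndex({"chr1": 10_000, "chr2": 5_000})


def random_interval_set(genome, n, rng, max_width=500):
    names = genome.names
    out = []
    for _ in range(n):
        chrom = names[rng.integers(0, len(names))]
        w = int(rng.integers(1, max_width))
        start = int(rng.integers(0, genome[chrom] - w))
        out.append(Interval(chrom, start, start + w))
    return IntervalSet(out, genome)
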