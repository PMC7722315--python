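import numpy as np
import pytest

from circscreen.intervals import GenomicInterval, IntervalSet
from circscreen.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One fully simulated dataset at the default study conditions."""
    return simulate_all(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_dataset_nogenome():
    return simulate_all(SimulationConfig(seed=0), with_sequence=False)


def base_set(intervals) -> set[int]:
    """Per-base oracle: the exact set of covered integer positions."""
    out: set[int] = set()
    for iv in intervals:
        if isinstance(iv, GenomicInterval):
            out |= set(range(iv.start, iv.end))
        else:
            out |= set(range(iv[0], iv[1]))
    return out


def random_interval_list(rng: np.random.Generator, chrom="chr1", max_n=10, max_coord=1000):
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        s = int(rng.integers(0, max_coord - 1))
        e = int(rng.integers(s + 1, min(max_coord, s + 1 + int(rng.integers(1, 120)))))
        out.append(GenomicInterval(chrom, s, e))
    return out


def assert_matches_base_oracle(result: IntervalSet, expected_bases: set[int]):
    got = base_set(result.intervals())
    assert got == expected_bases
    # structural invariants of any IntervalSet: disjoint, non-touching, sorted
    pairs = list(result)
    for (s1, e1), (s2, e2) in zip(pairs, pairs[1:]):
        assert e1 < s2
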