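import numpy as np
import pytest

from btiscan.diversity_neutrality import HaplotypeAlignment
from btiscan.io_formats import RunConfig, SyncRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cfg():
    return RunConfig(seed=1)


@pytest.fixture
def small_alignment():
    """Four haplotypes, L=10: site 3 splits 2/2, site 1 is a singleton A/G."""
    return HaplotypeAlignment(
        names=("h1", "h2", "h3", "h4"),
        sequences=("AACAAAAAAA", "AACAAAAAAA", "AATAAAAAAA", "GATAAAAAAA"),
        label="toy",
    )


def random_sync_records(rng, n=100, n_pools=2):
    """Random valid sync records for round-trip property tests."""
    records = []
    for i in range(n):
        pools = tuple(
            tuple(int(c) for c in rng.integers(0, 200, size=6))
            for _ in range(n_pools)
        )
        records.append(
            SyncRecord(
                chrom=f"sc{rng.integers(1, 5)}.{rng.integers(1, 999)}",
                pos=int(rng.integers(1, 10_000_000)),
                ref=str(rng.choice(list("ACGT"))),
                pool_counts=pools,
            )
        )
    return records
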