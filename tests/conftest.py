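import numpy as np
import pytest

import kzfpchip as k


@pytest.fixture(scope="session")
def bundle():
    """One shared default synthetic bundle (study-mimicking configuration)."""
    return k.simulate(k.paper_mimic_config(seed=1))


@pytest.fixture(scope="session")
def consensus_peaks(bundle):
    from kzfpchip.consensus import ReplicatePeakSet, consensus

    reps = [
        ReplicatePeakSet(f"rep{i + 1}", p) for i, p in enumerate(bundle.replicate_peaks)
    ]
    return consensus(reps, 2)


@pytest.fixture
def toy_genome():
    return k.GenomeDef(["chr1", "chr2"], [100_000, 50_000])


def random_intervals(rng, genome, n, max_len=500):
    """Uniform random interval list used by oracle-equivalence tests."""
    out = []
    for _ in range(n):
        ci = int(rng.integers(len(genome.chrom_names)))
        chrom = genome.chrom_names[ci]
        L = genome.chrom_lengths[ci]
        length = int(rng.integers(1, max_len))
        s = int(rng.integers(0, L - length))
        out.append(k.GenomicInterval(chrom, s, s + length))
    return out
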