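import numpy as np
import pytest

from orimfa import (
    Chromosome,
    OriginSpec,
    PipelineConfig,
    ReplicationParams,
    generate_genome,
)

ORB_CONSENSUS = "GGGGTCCACTGGAAACGGGGGC"  # 22-mer with G-strings


@pytest.fixture
def small_chrom():
    return Chromosome("chr", 200_000)


@pytest.fixture
def single_origin():
    """One always-firing origin at coordinate 0, everything cycling; the
    antipodal locus replicates exactly at the doubling time."""
    chrom = Chromosome("chr", 100_000)
    origins = [OriginSpec("ori", 0, 1.0)]
    params = ReplicationParams(fork_speed=1000.0, doubling_time=50.0,
                               cycling_fraction=1.0)
    return chrom, origins, params


@pytest.fixture
def three_origin_setup():
    """The wild-type study conditions: three unequal origins on a 2.9-Mb
    circle, half the population cycling, longest path 80% of a doubling."""
    cfg = PipelineConfig()
    return cfg.chromosome(), cfg.origin_specs()[:3], cfg.replication_params()


@pytest.fixture
def planted_genome():
    chrom, features = generate_genome(
        length=60_000,
        cdc6_loci=[(10_000, "+"), (40_000, "-")],
        orb_consensus=ORB_CONSENSUS,
        orb_spacing=30,
        seed=11,
    )
    return chrom, features


def random_dna(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
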