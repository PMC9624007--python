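import numpy as np
import pytest
from hypothesis import settings

import readscreen as rs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_params():
    """Small-k identity-hash parameters for exact brute-force oracles."""
    return rs.ScreenParams(
        k=5, read_length=50, error_rate=0.0, target_matches=2, hash_seed=None
    )


@pytest.fixture(scope="session")
def small_community():
    """8 dissimilar 100 kb genomes with 10 kb 1%-error reads and truth."""
    spec = rs.CommunitySpec(n_genomes=8, genome_length=100_000, rng_seed=7)
    genomes, _ = rs.generate_community(spec)
    reads = rs.simulate_reads(
        genomes, read_length=10_000, error_rate=0.01, coverage=0.5, seed=8
    )
    return genomes, reads


@pytest.fixture(scope="session")
def small_minhash_screen(small_community):
    genomes, _ = small_community
    params = rs.ScreenParams(
        k=21, read_length=10_000, error_rate=0.01, target_matches=100, hash_seed=11
    )
    return rs.build_screen(
        [(g, [s]) for g, s in genomes], rs.MethodParams(method="minhash"), params
    )
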