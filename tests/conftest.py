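import numpy as np
import pytest

from mnasebias import (
    DigestionParams,
    default_plan,
    digest_library,
    emit_reads,
    generate_genome,
    normalize_linear,
    normalize_log2,
    pileup,
)


@pytest.fixture(scope="session")
def demo_genome():
    """The 100-kb yeast-like demo genome (poly-A/T tracts + GC element)."""
    return generate_genome(default_plan(seed=11))


@pytest.fixture(scope="session")
def demo_library(demo_genome):
    """A deep simulated library on the demo genome: fragments + reads."""
    params = DigestionParams(seed=0)
    fragments = digest_library(demo_genome, params, n_copies=1000, seed=101)
    reads = emit_reads(fragments, seed=202)
    return fragments, reads


@pytest.fixture(scope="session")
def demo_tracks(demo_genome, demo_library):
    """Raw, log2-centered and linear-normalized coverage of the library."""
    _, reads = demo_library
    raw = pileup(reads, demo_genome)
    return raw, normalize_log2(raw), normalize_linear(raw)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
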