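import numpy as np
import pytest

import repweaver as rw


@pytest.fixture
def cfg():
    return rw.PipelineConfig(read_length=100)


@pytest.fixture(scope="session")
def small_simulation():
    """A 30 kb background with one 400 bp family at 40 copies, 10x reads."""
    fam = rw.RepeatFamilySpec(400, 40, divergence=0.01, indel_rate=0.002)
    truth = rw.generate_genome(30_000, [fam], seed=7)
    reads = rw.simulate_reads(truth, depth=10, read_length=100,
                              insert_mean=300, insert_sd=30,
                              base_error_rate=0.005, seed=8)
    return truth, reads


@pytest.fixture(scope="session")
def small_pipeline(small_simulation):
    truth, reads = small_simulation
    config = rw.PipelineConfig(read_length=100)
    return truth, reads, config, rw.run_assembly(reads, config)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
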