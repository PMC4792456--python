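"""Canonical planted-repeat study conditions used by tests and scripts.

Two scenarios exercise the two claims at the heart of the method:

* ``uniform_family`` — a 600 bp family at 60 copies with 1% substitutions
  and 0.2% indels in a 200 kb background, sequenced at 10x with 2x100 bp
  pairs (insert 300 +/- 30, 0.5% base error).  A well-behaved repeat the
  pipeline should recover essentially completely.

* ``divergent_core_family`` — a 1.2 kb family whose central 150 bp block
  carries 8% substitutions while the flanks carry 0.5%.  The copy number
  (120) puts the core's consensus k-mers marginally above the frequent
  threshold, so raw contigs fragment across the core and only the
  contig-graph merging step can reconstruct the full consensus: the
  motivating scenario for two-stage assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .seqio import ReadSet
from .simulate import RepeatFamilySpec, SimulationTruth, generate_genome, simulate_reads

READ_LENGTH = 100
DEPTH = 10.0
INSERT_MEAN = 300.0
INSERT_SD = 30.0
BASE_ERROR_RATE = 0.005
BACKGROUND_LENGTH = 200_000


@dataclass
class Scenario:
    truth: SimulationTruth
    reads: ReadSet
    config: PipelineConfig
    consensus: str


def _build(family: RepeatFamilySpec, seed: int) -> Scenario:
    truth = generate_genome(BACKGROUND_LENGTH, [family], seed)
    reads = simulate_reads(truth, DEPTH, READ_LENGTH, INSERT_MEAN, INSERT_SD,
                           BASE_ERROR_RATE, seed + 1)
    config = PipelineConfig(read_length=READ_LENGTH,
                            insert_size_mean=INSERT_MEAN,
                            insert_size_sd=INSERT_SD, rng_seed=seed)
    return Scenario(truth, reads, config, truth.consensus[family.name or "family0"])


def uniform_family(seed: int = 42) -> Scenario:
    fam = RepeatFamilySpec(length=600, copy_number=60,
                           divergence=0.01, indel_rate=0.002)
    return _build(fam, seed)


def divergent_core_family(seed: int = 42) -> Scenario:
    fam = RepeatFamilySpec(length=1200, copy_number=120,
                           divergence=0.005, indel_rate=0.0,
                           divergence_regions=((525, 675, 0.08),))
    return _build(fam, seed)
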