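"""Synthetic genomes with planted repeat families and paired-end reads.

The generator emulates the regime the assembler targets: a background
genome carrying repeat families at high copy number and low within-family
divergence.  Every mutation, copy placement and read placement is
recorded, so tests can compare pipeline output against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dna import BASES, revcomp
from .seqio import ReadSet


@dataclass
class RepeatFamilySpec:
    """One planted family: consensus length, copy number and mutation rates."""

    length: int
    copy_number: int
    divergence: float = 0.01     # expected per-base substitution rate per copy
    indel_rate: float = 0.0      # expected per-base indel rate per copy
    name: str = ""
    # optional (start, end, rate) consensus intervals whose substitution
    # rate overrides the family default, e.g. a divergent internal block
    divergence_regions: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0 or self.copy_number <= 0:
            raise ValueError("length and copy_number must be positive")
        if not (0.0 <= self.divergence < 0.5 and 0.0 <= self.indel_rate < 0.5):
            raise ValueError("divergence and indel_rate must be in [0, 0.5)")
        for start, end, rate in self.divergence_regions:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"region [{start},{end}) outside the consensus")
            if not (0.0 <= rate < 0.5):
                raise ValueError("region divergence must be in [0, 0.5)")

    def per_base_divergence(self) -> "np.ndarray":
        rates = np.full(self.length, self.divergence)
        for start, end, rate in self.divergence_regions:
            rates[start:end] = rate
        return rates


@dataclass
class CopyPlacement:
    family: str
    start: int            # genome coordinate of the copy
    end: int
    strand: str
    substitutions: int
    indels: int


@dataclass
class ReadPlacement:
    pair_index: int
    mate: int
    start: int            # genome coordinate of the read's leftmost base
    strand: str
    errors: int


@dataclass
class SimulationTruth:
    """Everything needed to verify pipeline output against ground truth."""

    genome: str
    consensus: dict[str, str]
    copies: list[CopyPlacement] = field(default_factory=list)
    reads: list[ReadPlacement] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _mutate_copy(rng: np.random.Generator, consensus: str,
                 divergence, indel_rate: float) -> tuple[str, int, int]:
    """Apply i.i.d. substitutions and single-base indels to one copy.

    ``divergence`` may be a scalar rate or a per-base rate array.
    """
    out: list[str] = []
    subs = indels = 0
    scalar = np.isscalar(divergence)
    for i, base in enumerate(consensus):
        rate = divergence if scalar else divergence[i]
        if indel_rate > 0 and rng.random() < indel_rate:
            indels += 1
            if rng.random() < 0.5:
                continue                      # deletion
            out.append(base)
            out.append(BASES[rng.integers(0, 4)])  # insertion after
            continue
        if rate > 0 and rng.random() < rate:
            subs += 1
            alternatives = BASES.replace(base, "")
            out.append(alternatives[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out), subs, indels


def generate_genome(background_length: int,
                    families: Sequence[RepeatFamilySpec],
                    seed: int) -> SimulationTruth:
    """Random background with mutated family copies spliced in.

    Copies are inserted at distinct uniform background positions on
    random strands; insertion points never overlap, and all realized
    placements and edit counts are recorded in the returned truth.
    """
    rng = np.random.default_rng(seed)
    total_planted = sum(f.length * f.copy_number for f in families)
    if families and total_planted >= background_length:
        raise ValueError(
            f"planted sequence ({total_planted} bp) does not fit in the "
            f"background ({background_length} bp)"
        )
    background = _random_seq(rng, background_length)
    consensus: dict[str, str] = {}
    insertions: list[tuple[int, str, str, str, int, int]] = []  # pos, fam, seq, strand, subs, indels
    taken: set[int] = set()
    for fi, fam in enumerate(families):
        name = fam.name or f"family{fi}"
        cons = _random_seq(rng, fam.length)
        consensus[name] = cons
        for _ in range(fam.copy_number):
            for _attempt in range(1000):
                pos = int(rng.integers(0, background_length))
                if pos not in taken:
                    taken.add(pos)
                    break
            else:
                raise ValueError("cannot place repeat copies without overlap")
            rates = fam.per_base_divergence() if fam.divergence_regions \
                else fam.divergence
            seq, subs, indels = _mutate_copy(rng, cons, rates, fam.indel_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            insertions.append((pos, name, seq, strand, subs, indels))

    insertions.sort(key=lambda item: item[0])
    pieces: list[str] = []
    copies: list[CopyPlacement] = []
    cursor = 0
    built = 0
    for pos, name, seq, strand, subs, indels in insertions:
        pieces.append(background[cursor:pos])
        built += pos - cursor
        copies.append(CopyPlacement(family=name, start=built,
                                    end=built + len(seq), strand=strand,
                                    substitutions=subs, indels=indels))
        pieces.append(seq)
        built += len(seq)
        cursor = pos
    pieces.append(background[cursor:])
    genome = "".join(pieces)
    return SimulationTruth(genome=genome, consensus=consensus, copies=copies)


def simulate_reads(truth: SimulationTruth, depth: float, read_length: int,
                   insert_mean: float, insert_sd: float,
                   base_error_rate: float, seed: int) -> ReadSet:
    """Paired-end reads at the requested depth with i.i.d. base errors.

    The pair count is round(depth * genome_length / (2 * read_length));
    fragment starts are uniform, fragment lengths normal, mate 2 is the
    reverse complement of the fragment's right end, and fragments sample
    both genome strands with equal probability.  Placements and realized
    error counts are appended to ``truth.reads``.
    """
    if insert_mean <= read_length:
        raise ValueError("insert_mean must exceed read_length")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    glen = len(genome)
    n_pairs = int(round(depth * glen / (2 * read_length)))
    pairs: list[tuple[str, str]] = []

    def with_errors(seq: str) -> tuple[str, int]:
        if base_error_rate <= 0:
            return seq, 0
        hits = np.flatnonzero(rng.random(len(seq)) < base_error_rate)
        if len(hits) == 0:
            return seq, 0
        chars = list(seq)
        for i in hits:
            alternatives = BASES.replace(chars[i], "")
            chars[i] = alternatives[rng.integers(0, 3)]
        return "".join(chars), len(hits)

    for pi in range(n_pairs):
        frag_len = int(round(rng.normal(insert_mean, insert_sd)))
        frag_len = max(read_length, min(frag_len, glen))
        start = int(rng.integers(0, glen - frag_len + 1))
        left = genome[start:start + read_length]
        right = revcomp(genome[start + frag_len - read_length:start + frag_len])
        if rng.random() < 0.5:
            mate1, mate2 = left, right
            placements = [(0, start, "+"), (1, start + frag_len - read_length, "-")]
        else:
            mate1, mate2 = right, left
            placements = [(0, start + frag_len - read_length, "-"), (1, start, "+")]
        mate1, err1 = with_errors(mate1)
        mate2, err2 = with_errors(mate2)
        pairs.append((mate1, mate2))
        for (mate, pos, strand), err in zip(placements, (err1, err2)):
            truth.reads.append(ReadPlacement(pair_index=pi, mate=mate,
                                             start=pos, strand=strand,
                                             errors=err))
    return ReadSet(pairs=pairs, read_length=read_length, source="simulated")
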