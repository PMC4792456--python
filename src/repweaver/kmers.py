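"""K-mer counting, frequent-k-mer selection and frequency binning.

Repeat families present at high copy number leave a signature in the
k-mer frequency spectrum of shotgun reads: k-mers inside repeat copies
occur roughly copy-number times more often than k-mers from unique
sequence.  This module builds the occurrence catalog, selects k-mers
whose counts exceed a multiple of the average frequency, and groups them
into overlapping frequency bins so that k-mers of similar abundance
(typically from the same family) are assembled together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .config import PipelineConfig
from .dna import revcomp


@dataclass
class KmerCatalog:
    """Occurrence counts for all observed (canonical) k-mers of one k."""

    k: int
    counts: dict[str, int]

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_count(self) -> int:
        return len(self.counts)


@dataclass
class FrequencyBin:
    """K-mers whose counts fall within a window around a target frequency."""

    target_frequency: float
    low: float
    high: float
    members: dict[str, int]


def count_kmers(reads, k: int, canonical: bool = True) -> KmerCatalog:
    """Count every length-k window of every read (both mates).

    Windows containing N are skipped.  With ``canonical`` (the default,
    appropriate for shotgun reads that sample both strands) each window
    is counted under the lexicographic minimum of itself and its reverse
    complement.
    """
    sequences: Iterable[str]
    if hasattr(reads, "mates"):
        if k >= reads.read_length:
            raise ValueError(f"k={k} must be smaller than the read length {reads.read_length}")
        sequences = reads.mates()
    else:
        sequences = reads

    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        segments = seq.split("N") if "N" in seq else (seq,)
        for seg in segments:
            n = len(seg) - k + 1
            if n <= 0:
                continue
            if canonical:
                rc = revcomp(seg)
                m = len(seg)
                for i in range(n):
                    fwd = seg[i:i + k]
                    rev = rc[m - i - k:m - i]
                    kmer = fwd if fwd <= rev else rev
                    counts[kmer] = counts.get(kmer, 0) + 1
            else:
                for i in range(n):
                    kmer = seg[i:i + k]
                    counts[kmer] = counts.get(kmer, 0) + 1
    return KmerCatalog(k=k, counts=counts)


def average_frequency(catalog: KmerCatalog) -> float:
    """Mean occurrence count over distinct observed k-mers."""
    if catalog.distinct_count == 0:
        raise ValueError("cannot take the average frequency of an empty catalog")
    return catalog.total_occurrences / catalog.distinct_count


def select_frequent(catalog: KmerCatalog, freq_cutoff_factor: float,
                    baseline: float | None = None) -> dict[str, int]:
    """K-mers whose count is strictly above cutoff-factor times the average.

    ``baseline`` substitutes the catalog's own average frequency (used by
    the depth-estimate mode, where the expected per-locus k-mer depth of
    the library is supplied instead).
    """
    avg = average_frequency(catalog) if baseline is None else baseline
    threshold = freq_cutoff_factor * avg
    return {kmer: c for kmer, c in catalog.counts.items() if c > threshold}


def make_frequency_bins(frequent: Mapping[str, int],
                        config: PipelineConfig) -> list[FrequencyBin]:
    """Partition frequent k-mers into overlapping frequency bins.

    Bin targets form a geometric sequence starting at the highest
    observed frequent count, each subsequent target divided by
    ``bin_ratio``; generation stops once a target at or below the lowest
    frequent count has been emitted, which guarantees every frequent
    k-mer lands in at least one bin.  Bins are ordered high to low.
    """
    if not frequent:
        raise ValueError("cannot bin an empty frequent k-mer set")
    max_count = max(frequent.values())
    min_count = min(frequent.values())
    bins: list[FrequencyBin] = []
    target = float(max_count)
    while True:
        low = config.bin_low_factor * target
        high = config.bin_high_factor * target
        members = {kmer: c for kmer, c in frequent.items() if low <= c <= high}
        bins.append(FrequencyBin(target_frequency=target, low=low, high=high,
                                 members=members))
        if target <= min_count:
            break
        target /= config.bin_ratio
    return bins


def write_kmer_table(catalog: KmerCatalog, path: str | Path) -> None:
    """Export counts as a 2-column TSV (k-mer, count)."""
    with open(path, "w") as handle:
        for kmer in sorted(catalog.counts):
            handle.write(f"{kmer}\t{catalog.counts[kmer]}\n")


def read_kmer_table(path: str | Path) -> KmerCatalog:
    """Import a pre-computed k-mer count table (2-column TSV)."""
    counts: dict[str, int] = {}
    k = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            try:
                kmer, count = line.split("\t")
                counts[kmer.upper()] = int(count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected '<kmer>\\t<count>'") from exc
            k = len(kmer)
    return KmerCatalog(k=k, counts=counts)
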