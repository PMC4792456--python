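"""Pipeline configuration.

A single flat configuration object is shared by every stage.  It can be
loaded from a plain ``key = value`` text file and overridden field by
field from CLI flags.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


@dataclass
class PipelineConfig:
    """Tunable parameters of the repeat-assembly pipeline.

    Parameters
    ----------
    kmer_lengths
        Odd k-mer sizes used for raw-contig assembly; all runs are
        combined into a single contig list.
    freq_cutoff_factor
        A k-mer is *frequent* when its count exceeds this factor times
        the average k-mer frequency of the catalog.
    bin_low_factor, bin_high_factor
        A frequency bin with target frequency ``f`` admits counts in
        ``[bin_low_factor * f, bin_high_factor * f]``.
    bin_ratio
        Each successive bin target is the previous one divided by this
        ratio; with the default window the bins overlap.
    min_overlap_bp
        Minimum suffix-prefix overlap length for a contig-graph edge.
    max_mismatch_rate
        Edits (substitutions + indels) in an overlap must be strictly
        below this fraction of the overlap length.
    prefilter_substring_len
        Length of the exact shared substring required before two contigs
        are aligned at all (cheap candidate-pair prefilter).
    min_read_pair_support
        Read pairs that must straddle a junction for the edge to be kept
        whenever straddling pairs are geometrically expected.
    min_avg_coverage
        Contigs whose mean mapped-read depth is below this are discarded;
        the same per-base threshold drives truncation of uneven contigs.
    read_length, insert_size_mean, insert_size_sd
        Library geometry used for read-pair support decisions.
    matching_cutoff
        Matched-span / query-length ratio above which an assembled repeat
        counts as hitting a reference library entry.
    rng_seed
        Seed for every randomized step.
    """

    kmer_lengths: tuple[int, ...] = (29, 39, 49)
    freq_cutoff_factor: float = 10.0
    bin_low_factor: float = 0.2
    bin_high_factor: float = 5.0
    bin_ratio: float = 2.0
    min_overlap_bp: int = 15
    max_mismatch_rate: float = 0.05
    prefilter_substring_len: int = 5
    min_read_pair_support: int = 1
    min_avg_coverage: float = 2.0
    read_length: int = 100
    insert_size_mean: float = 300.0
    insert_size_sd: float = 30.0
    matching_cutoff: float = 0.85
    rng_seed: int = 42
    # counting / mapping knobs
    canonical_kmers: bool = True
    freq_baseline: str = "distinct-mean"  # or "depth-estimate"
    seed_length: int = 20
    seed_stride: int = 5
    max_map_error_rate: float = 0.06
    insert_sd_window: float = 3.0

    def __post_init__(self) -> None:
        self.kmer_lengths = tuple(int(k) for k in self.kmer_lengths)
        if not self.kmer_lengths:
            raise ValueError("kmer_lengths must be non-empty")
        for k in self.kmer_lengths:
            if k <= 0 or k % 2 == 0:
                raise ValueError(f"k-mer lengths must be positive odd integers, got {k}")
        if not (self.bin_low_factor < 1.0 < self.bin_high_factor):
            raise ValueError("bin factors must satisfy bin_low_factor < 1 < bin_high_factor")
        if self.bin_ratio <= 1.0:
            raise ValueError("bin_ratio must be > 1")
        if self.bin_ratio >= self.bin_high_factor / self.bin_low_factor:
            raise ValueError("consecutive bins must overlap (bin_ratio < high/low)")
        if self.freq_cutoff_factor <= 0:
            raise ValueError("freq_cutoff_factor must be positive")
        if self.min_overlap_bp < self.prefilter_substring_len:
            raise ValueError("min_overlap_bp must be >= prefilter_substring_len")
        if not (0.0 <= self.max_mismatch_rate < 1.0):
            raise ValueError("max_mismatch_rate must be in [0, 1)")
        if not (0.0 <= self.matching_cutoff <= 1.0):
            raise ValueError("matching_cutoff must be in [0, 1]")
        if self.min_read_pair_support < 0:
            raise ValueError("min_read_pair_support must be non-negative")
        if self.min_avg_coverage < 0:
            raise ValueError("min_avg_coverage must be non-negative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if max(self.kmer_lengths) >= self.read_length:
            raise ValueError("all kmer_lengths must be < read_length")
        if self.insert_size_mean <= 0 or self.insert_size_sd <= 0:
            raise ValueError("insert size parameters must be positive")
        if self.freq_baseline not in ("distinct-mean", "depth-estimate"):
            raise ValueError("freq_baseline must be 'distinct-mean' or 'depth-estimate'")

    def replace(self, **updates) -> "PipelineConfig":
        return dataclasses.replace(self, **updates)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a flat ``key = value`` file; keyword overrides win."""
        values: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = (part.strip() for part in line.partition("="))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            values[key] = _coerce(val, fields[key].type)
        values.update(overrides)
        return cls(**values)


def _coerce(text: str, annotation) -> object:
    ann = str(annotation)
    if "tuple" in ann or "Sequence" in ann:
        return tuple(int(x) for x in text.replace(",", " ").split())
    if "bool" in ann:
        return text.lower() in ("1", "true", "yes", "on")
    if "int" in ann:
        return int(text)
    if "float" in ann:
        return float(text)
    return text
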