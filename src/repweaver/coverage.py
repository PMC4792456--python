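"""Coverage-based validation of contigs and merged repeats.

Reads are mapped back to the assembled sequences; contigs whose mean
per-base depth falls below a threshold are treated as mis-assemblies
and discarded, and contigs with uneven coverage are truncated to their
well-covered runs.  Multi-mapping placements each contribute one unit
of depth, since every copy of a repeat family legitimately covers the
family's contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import RawContig
from .config import PipelineConfig
from .mapping import Placement, map_reads_to_contigs
from .scaffold import AssembledRepeat


@dataclass
class CoverageProfile:
    """Per-base mapped-read depth of one contig."""

    contig_id: str
    per_base: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.per_base.mean()) if len(self.per_base) else 0.0


def profile_coverage(placements: Sequence[Placement],
                     contig: RawContig | AssembledRepeat) -> CoverageProfile:
    """Depth at every contig base from half-open placement spans."""
    length = contig.length
    diff = np.zeros(length + 1, dtype=np.int64)
    for p in placements:
        if p.contig_id != contig.id:
            continue
        if p.start < 0 or p.end > length or p.start >= p.end:
            raise RuntimeError(
                f"placement [{p.start},{p.end}) out of bounds for contig "
                f"{contig.id} of length {length}"
            )
        diff[p.start] += 1
        diff[p.end] -= 1
    return CoverageProfile(contig_id=contig.id,
                           per_base=np.cumsum(diff[:-1]))


def filter_contig(contig: RawContig, profile: CoverageProfile,
                  config: PipelineConfig,
                  min_run_length: int | None = None) -> list[RawContig]:
    """Apply the discard / keep / truncate rule to one contig.

    Mean depth below ``min_avg_coverage`` discards the contig outright.
    Otherwise every maximal run of bases at or above the threshold and
    at least ``min_run_length`` long (default: the largest assembly k,
    so no fragment shorter than a k-mer is emitted) becomes an output
    contig; a contig covered throughout is kept unchanged.
    """
    if profile.contig_id != contig.id or len(profile.per_base) != contig.length:
        raise ValueError("profile does not match contig")
    if min_run_length is None:
        min_run_length = max(config.kmer_lengths)
    if profile.mean < config.min_avg_coverage:
        return []
    ok = profile.per_base >= config.min_avg_coverage
    if ok.all():
        return [contig]
    pieces: list[RawContig] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for i, (start, end) in enumerate(zip(edges[::2], edges[1::2])):
        if end - start >= min_run_length:
            pieces.append(RawContig(
                id=f"{contig.id}t{i:02d}",
                sequence=contig.sequence[start:end],
                source_k=contig.source_k,
                source_bin_target=contig.source_bin_target,
            ))
    return pieces


def filter_contigs(contigs: Sequence[RawContig],
                   placements: Sequence[Placement],
                   config: PipelineConfig,
                   min_run_length: int | None = None) -> list[RawContig]:
    """Filter a whole contig list against one set of placements."""
    by_contig: dict[str, list[Placement]] = {}
    for p in placements:
        by_contig.setdefault(p.contig_id, []).append(p)
    result: list[RawContig] = []
    for contig in contigs:
        profile = profile_coverage(by_contig.get(contig.id, ()), contig)
        result.extend(filter_contig(contig, profile, config, min_run_length))
    return result


def annotate_repeats(repeats: Sequence[AssembledRepeat], reads,
                     config: PipelineConfig) -> list[AssembledRepeat]:
    """Re-map reads to merged repeats, fill mean coverage, re-filter.

    The same discard/truncate rules applied to raw contigs are applied
    to the merged sequences, so chimeric merges whose junctions attract
    no reads are split apart.
    """
    repeats = list(repeats)
    if not repeats:
        return []
    as_contigs = [RawContig(r.id, r.sequence, source_k=max(config.kmer_lengths))
                  for r in repeats]
    placements = map_reads_to_contigs(reads, as_contigs, config) \
        if reads is not None and len(reads.pairs) else []
    by_contig: dict[str, list[Placement]] = {}
    for p in placements:
        by_contig.setdefault(p.contig_id, []).append(p)

    final: list[AssembledRepeat] = []
    for rep, contig in zip(repeats, as_contigs):
        profile = profile_coverage(by_contig.get(rep.id, ()), contig)
        kept = filter_contig(contig, profile, config)
        for piece in kept:
            if piece.id == rep.id:
                cov = profile.mean
                final.append(AssembledRepeat(rep.id, rep.sequence, rep.path,
                                             rep.junctions, mean_coverage=cov))
            else:
                offset = rep.sequence.find(piece.sequence)
                span = profile.per_base[offset:offset + piece.length]
                final.append(AssembledRepeat(
                    id=piece.id, sequence=piece.sequence, path=rep.path,
                    junctions=[], mean_coverage=float(span.mean()),
                ))
    return final
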