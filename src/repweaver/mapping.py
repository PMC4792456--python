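"""Seed-and-extend short-read mapper used for coverage and pair support.

Exact seeds of configurable length are located through a hash index of
contig positions and extended by banded edit distance (edlib).  All
placements of a read are reported (multi-mapping allowed), which is the
behaviour repeat analysis needs: a read from any copy of a family should
count toward the family contig's coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .config import PipelineConfig
from .dna import revcomp


@dataclass(frozen=True)
class Placement:
    """One alignment of one mate to one contig (0-based, end-exclusive)."""

    read_id: int
    mate: int
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    edits: int


class ContigIndex:
    """Hash index of all fixed-length seeds occurring in a contig set."""

    def __init__(self, contigs, seed_length: int, seed_stride: int = 5):
        self.seed_length = seed_length
        self.seed_stride = seed_stride
        self.sequences: dict[str, str] = {}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for contig in contigs:
            cid, seq = contig.id, contig.sequence.upper()
            self.sequences[cid] = seq
            for pos in range(0, len(seq) - seed_length + 1):
                self.seeds.setdefault(seq[pos:pos + seed_length], []).append((cid, pos))

    def place(self, seq: str,
              error_rate: float) -> list[tuple[str, int, int, str, int]]:
        """All (contig, start, end, strand, edits) placements of one read.

        Reads may overhang contig ends: only the read segment overlapping
        the contig is aligned (soft-clip semantics), provided that segment
        is at least one seed long.  The edit allowance scales with the
        aligned segment length.
        """
        results: dict[tuple[str, int, str], tuple[int, int]] = {}
        sl = self.seed_length
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            rlen = len(oriented)
            if rlen < sl:
                continue
            positions = list(range(0, rlen - sl + 1, self.seed_stride))
            if positions[-1] != rlen - sl:
                positions.append(rlen - sl)
            diagonals: dict[str, set[int]] = {}
            for sp in positions:
                seed = oriented[sp:sp + sl]
                if "N" in seed:
                    continue
                for cid, cpos in self.seeds.get(seed, ()):
                    diagonals.setdefault(cid, set()).add(cpos - sp)
            for cid, diags in diagonals.items():
                contig = self.sequences[cid]
                clen = len(contig)
                tolerance = max(1, int(error_rate * rlen))
                for diag in _cluster(sorted(diags), tolerance):
                    ostart, oend = max(0, diag), min(clen, diag + rlen)
                    if oend - ostart < sl:
                        continue
                    segment = oriented[ostart - diag:oend - diag]
                    max_edits = int(error_rate * len(segment))
                    wstart = max(0, ostart - max_edits - 1)
                    wend = min(clen, oend + max_edits + 1)
                    aln = edlib.align(segment, contig[wstart:wend],
                                      mode="HW", task="locations", k=max_edits)
                    if aln["editDistance"] < 0:
                        continue
                    loc = aln["locations"][0]
                    start, end = wstart + loc[0], wstart + loc[1] + 1
                    key = (cid, start, strand)
                    best = results.get(key)
                    if best is None or aln["editDistance"] < best[1]:
                        results[key] = (end, aln["editDistance"])
        return [(cid, start, end, strand, edits)
                for (cid, start, strand), (end, edits) in sorted(results.items())]


def _cluster(diagonals: Sequence[int], tolerance: int) -> list[int]:
    """Collapse nearby seed diagonals into one representative each."""
    reps: list[int] = []
    for d in diagonals:
        if not reps or d - reps[-1] > tolerance:
            reps.append(d)
    return reps


def map_reads_to_contigs(reads, contigs, config: PipelineConfig) -> list[Placement]:
    """Map every mate of every pair against all contigs, reporting all hits."""
    contigs = list(contigs)
    if not contigs:
        raise ValueError("cannot map against an empty contig list")
    index = ContigIndex(contigs, config.seed_length, config.seed_stride)
    placements: list[Placement] = []
    for read_id, (fwd, rev) in enumerate(reads.pairs):
        for mate, seq in ((0, fwd), (1, rev)):
            for cid, start, end, strand, edits in index.place(
                    seq.upper(), config.max_map_error_rate):
                placements.append(Placement(read_id, mate, cid, start, end,
                                            strand, edits))
    return placements
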