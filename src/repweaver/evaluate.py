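"""Assembly quality statistics against a reference repeat library.

A library entry counts as *hit* when the matched span of its best local
alignment against some assembled repeat covers at least the matching
cutoff fraction of the entry.  Coverage of an entry by the assembly is
summarised two ways: by the best non-overlapping set of matched repeat
intervals (computed exactly with weighted interval scheduling) and by
the single longest matched interval.  N50 summarises repeat lengths.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .dna import revcomp


@dataclass
class MatchResult:
    """Best local alignment of a query against a reference (both strands)."""

    ratio: float                     # aligned query span / query length
    ref_interval: tuple[int, int] | None  # matched interval on the reference
    identity: float                  # matches / max(query span, ref span)
    score: float
    strand: str


@dataclass
class EvaluationReport:
    n_repeats: int
    n_hits: int
    avg_coverage: float
    max_single_coverage: float
    n50: int
    rows: list[dict] = field(default_factory=list)


def _aligner(match: float = 1.0, mismatch: float = -2.0,
             gap: float = -2.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def matching_ratio(query: str, reference: str,
                   match: float = 1.0, mismatch: float = -2.0,
                   gap: float = -2.5) -> MatchResult:
    """Matched-span ratio of the best local alignment on either strand.

    The ratio is the length of the query span covered by the best local
    alignment divided by the query length; the matched interval is
    reported in forward reference coordinates.  Scoring defaults follow
    megablast-like conventions (match +1, mismatch -2, gap -2.5).
    """
    if not query or not reference:
        raise ValueError("matching_ratio requires non-empty sequences")
    aligner = _aligner(match, mismatch, gap)
    best: MatchResult | None = None
    for strand, q in (("+", query.upper()), ("-", revcomp(query.upper()))):
        alignments = aligner.align(reference.upper(), q)
        if alignments.score <= 0:
            continue
        aln = alignments[0]
        ref_blocks, query_blocks = aln.aligned
        if len(ref_blocks) == 0:
            continue
        q_span = int(query_blocks[-1][1] - query_blocks[0][0])
        r_start, r_end = int(ref_blocks[0][0]), int(ref_blocks[-1][1])
        matches = 0
        for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
            matches += sum(a == b for a, b in
                           zip(aln.target[rs:re_], aln.query[qs:qe]))
        identity = matches / max(q_span, r_end - r_start)
        result = MatchResult(
            ratio=q_span / len(query),
            ref_interval=(r_start, r_end),
            identity=identity,
            score=float(alignments.score),
            strand=strand,
        )
        if best is None or result.score > best.score:
            best = result
    if best is None:
        return MatchResult(0.0, None, 0.0, 0.0, "+")
    return best


def count_hits(repeats: Sequence[str], library: Mapping[str, str],
               matching_cutoff: float = 0.85) -> int:
    """Library entries matched (entry as query) by >= 1 assembled repeat."""
    hits = 0
    for entry in library.values():
        for rep in repeats:
            if matching_ratio(entry, rep).ratio >= matching_cutoff:
                hits += 1
                break
    return hits


def greedy_max_coverage(reference_length: int,
                        intervals: Sequence[tuple[int, int]]) -> float:
    """Largest fraction coverable by pairwise non-overlapping intervals.

    Solved exactly by weighted interval scheduling (sort by end, DP with
    binary search); the weight of an interval is its length.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    for s, e in intervals:
        if s < 0 or e > reference_length or s >= e:
            raise ValueError(f"interval [{s},{e}) outside [0,{reference_length})")
    if not intervals:
        return 0.0
    ordered = sorted(intervals, key=lambda iv: iv[1])
    ends = [e for _, e in ordered]
    best = [0] * (len(ordered) + 1)
    for i, (s, e) in enumerate(ordered, 1):
        prev = bisect_right(ends, s, hi=i - 1)
        best[i] = max(best[i - 1], best[prev] + (e - s))
    return best[-1] / reference_length


def longest_single_coverage(reference_length: int,
                            intervals: Sequence[tuple[int, int]]) -> float:
    """Fraction covered by the single longest matched interval."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    if not intervals:
        return 0.0
    return max(e - s for s, e in intervals) / reference_length


def n50(lengths: Sequence[int]) -> int:
    """Length at which the descending cumulative sum reaches half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]


def evaluate_assembly(repeats: Sequence, library: Mapping[str, str],
                      matching_cutoff: float = 0.85) -> EvaluationReport:
    """Full evaluation of assembled repeats against a repeat library."""
    seqs = [r.sequence if hasattr(r, "sequence") else r for r in repeats]
    rows: list[dict] = []
    for name, entry in library.items():
        intervals: list[tuple[int, int]] = []
        for seq in seqs:
            m = matching_ratio(seq, entry)
            if m.ref_interval is not None:
                intervals.append(m.ref_interval)
        best_ratio = max(
            (matching_ratio(entry, seq).ratio for seq in seqs), default=0.0
        )
        rows.append({
            "library_id": name,
            "best_matching_ratio": best_ratio,
            "greedy_coverage": greedy_max_coverage(len(entry), intervals),
            "longest_single_coverage": longest_single_coverage(len(entry), intervals),
            "hit": best_ratio >= matching_cutoff,
        })
    hit_rows = [r for r in rows if r["hit"]]
    return EvaluationReport(
        n_repeats=len(seqs),
        n_hits=len(hit_rows),
        avg_coverage=(sum(r["greedy_coverage"] for r in hit_rows) / len(hit_rows)
                      if hit_rows else 0.0),
        max_single_coverage=(sum(r["longest_single_coverage"] for r in hit_rows)
                             / len(hit_rows) if hit_rows else 0.0),
        n50=n50([len(s) for s in seqs]) if seqs else 0,
        rows=rows,
    )
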