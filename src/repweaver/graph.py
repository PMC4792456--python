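"""Directed contig graph: overlap detection and read-pair confirmation.

Raw contigs are typically fragments of longer repeat consensus
sequences.  To merge them, a directed graph is built in which an edge
v1 -> v2 records a sufficiently long, sufficiently clean suffix-prefix
overlap (length >= min_overlap_bp, edit rate strictly below
max_mismatch_rate), confirmed -- whenever the library geometry makes
such evidence possible -- by read pairs straddling the junction.

Candidate pairs are prefiltered by an exact shared substring of length
k0: any qualifying overlap (>= 15 bp at < 5% edits) necessarily contains
an exact common 5-mer, so the prefilter loses nothing.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx

from .assembly import RawContig
from .config import PipelineConfig
from .dna import revcomp
from .mapping import Placement, map_reads_to_contigs


@dataclass(frozen=True)
class Overlap:
    """A verified suffix(source)-prefix(target) alignment."""

    source: str
    target: str
    length: int
    mismatches: int
    orientation: str  # '+' target as given, '-' reverse complement of target


@dataclass
class ContigGraph:
    """Directed graph over raw contigs with overlap/support edge data.

    ``contigs`` hold the (possibly re-oriented) sequences used by the
    edges; ``orientation`` records the strand each input contig was
    assigned relative to its original sequence.
    """

    graph: nx.DiGraph
    contigs: dict[str, RawContig]
    orientation: dict[str, str] = field(default_factory=dict)
    placements: list[Placement] = field(default_factory=list)

    def edge_overlap(self, u: str, v: str) -> Overlap:
        return self.graph.edges[u, v]["overlap"]


def _max_edits(length: int, rate: float) -> int:
    """Largest edit count with edits/length strictly below rate."""
    return math.ceil(length * rate) - 1


def candidate_pairs(contigs: Sequence[RawContig], k0: int,
                    orientation_aware: bool = True) -> set[tuple[str, str]]:
    """Ordered contig pairs sharing at least one exact length-k0 substring.

    With ``orientation_aware`` a shared substring between one contig and
    the reverse complement of the other also qualifies.  This is a
    superset of all pairs admitting a qualifying overlap.
    """
    kmer_sets: dict[str, set[str]] = {}
    for c in contigs:
        seq = c.sequence.upper()
        kmers = {seq[i:i + k0] for i in range(len(seq) - k0 + 1)}
        if orientation_aware:
            rc = revcomp(seq)
            kmers |= {rc[i:i + k0] for i in range(len(rc) - k0 + 1)}
        kmer_sets[c.id] = kmers

    index: dict[str, list[str]] = {}
    for c in contigs:
        seq = c.sequence.upper()
        for i in range(len(seq) - k0 + 1):
            index.setdefault(seq[i:i + k0], []).append(c.id)

    pairs: set[tuple[str, str]] = set()
    for cid, kmers in kmer_sets.items():
        partners: set[str] = set()
        for kmer in kmers:
            partners.update(index.get(kmer, ()))
        partners.discard(cid)
        for other in partners:
            pairs.add((cid, other))
            pairs.add((other, cid))
    return pairs


def compute_overlap(source: RawContig, target: RawContig,
                    config: PipelineConfig,
                    orientation_aware: bool = True) -> Overlap | None:
    """Best qualifying suffix-prefix overlap between two contigs.

    All candidate overlap lengths are evaluated by edit-distance DP over
    the length-L suffix of ``source`` versus the length-L prefix of
    ``target``, from the longest possible L downward; the first
    qualifying length wins (ties between orientations at the same L go
    to fewer mismatches, then forward orientation).
    """
    if source.id == target.id:
        raise ValueError("compute_overlap requires two distinct contigs")
    s = source.sequence.upper()
    t_fwd = target.sequence.upper()
    orientations = [("+", t_fwd)]
    if orientation_aware:
        orientations.append(("-", revcomp(t_fwd)))
    max_len = min(len(s), len(t_fwd))
    for length in range(max_len, config.min_overlap_bp - 1, -1):
        limit = _max_edits(length, config.max_mismatch_rate)
        if limit < 0:
            continue
        best: Overlap | None = None
        for orient, t in orientations:
            aln = edlib.align(s[-length:], t[:length], mode="NW",
                              task="distance", k=limit)
            d = aln["editDistance"]
            if d < 0:
                continue
            if best is None or d < best.mismatches:
                best = Overlap(source.id, target.id, length, d, orient)
        if best is not None:
            return best
    return None


def _find_containments(contigs: Sequence[RawContig],
                       pairs: Iterable[tuple[str, str]],
                       config: PipelineConfig) -> set[str]:
    """Contigs aligning fully inside a longer contig at qualifying edit rate."""
    by_id = {c.id: c for c in contigs}
    dropped: set[str] = set()
    for a_id, b_id in sorted(pairs):
        if a_id >= b_id or a_id in dropped or b_id in dropped:
            continue
        a, b = by_id[a_id], by_id[b_id]
        # candidate containee is the shorter contig (ties: larger id)
        outer, inner = (a, b) if (a.length, b.id) > (b.length, a.id) else (b, a)
        if inner.length > outer.length:
            continue
        limit = _max_edits(inner.length, config.max_mismatch_rate)
        if limit < 0:
            continue
        for query in (inner.sequence, revcomp(inner.sequence)):
            aln = edlib.align(query, outer.sequence, mode="HW",
                              task="distance", k=limit)
            if aln["editDistance"] >= 0:
                dropped.add(inner.id)
                break
    return dropped


def _strand_constraint(a: RawContig, b: RawContig,
                       config: PipelineConfig) -> tuple[bool, int, int] | None:
    """Best relative-strand constraint implied by any qualifying overlap.

    All four junction types are examined: suffix-prefix and prefix-suffix
    overlaps require the two contigs on the same strand (flip False),
    suffix-suffix and prefix-prefix overlaps require opposite strands
    (flip True).  Returns (flip, length, mismatches) of the longest
    qualifying junction, or None.
    """
    rc_a = RawContig(a.id, revcomp(a.sequence), a.source_k)
    candidates: list[tuple[bool, Overlap | None]] = [
        (False, compute_overlap(a, b, config, orientation_aware=False)),
        (False, compute_overlap(b, a, config, orientation_aware=False)),
        (True, _suffix_suffix(a, b, config)),
        (True, compute_overlap(rc_a, b, config, orientation_aware=False)),
    ]
    best: tuple[bool, int, int] | None = None
    for flip, ov in candidates:
        if ov is None:
            continue
        if best is None or (ov.length, -ov.mismatches) > (best[1], -best[2]):
            best = (flip, ov.length, ov.mismatches)
    return best


def _suffix_suffix(a: RawContig, b: RawContig,
                   config: PipelineConfig) -> Overlap | None:
    rc_b = RawContig(b.id, revcomp(b.sequence), b.source_k)
    return compute_overlap(a, rc_b, config, orientation_aware=False)


def _assign_orientations(contigs: Sequence[RawContig],
                         config: PipelineConfig) -> dict[str, str]:
    """One strand per contig per overlap-connected component.

    Strand constraints are merged strongest-overlap-first with a parity
    union-find; constraints conflicting with an already-merged parity
    (odd cycles) are dropped.  Component roots are oriented '+'.
    """
    by_id = {c.id: c for c in contigs}
    pairs = candidate_pairs(contigs, config.prefilter_substring_len, True)
    constraints: list[tuple[int, int, str, str, bool]] = []
    for a_id, b_id in sorted(pairs):
        if a_id >= b_id:
            continue
        found = _strand_constraint(by_id[a_id], by_id[b_id], config)
        if found is not None:
            flip, length, mismatches = found
            constraints.append((-length, mismatches, a_id, b_id, flip))

    parent: dict[str, str] = {c.id: c.id for c in contigs}
    parity: dict[str, int] = {c.id: 0 for c in contigs}  # vs parent chain root

    def find(x: str) -> tuple[str, int]:
        if parent[x] == x:
            return x, 0
        root, p = find(parent[x])
        parent[x] = root
        parity[x] ^= p
        return root, parity[x]

    for _neg_len, _mm, a_id, b_id, flip in sorted(constraints):
        ra, pa = find(a_id)
        rb, pb = find(b_id)
        if ra == rb:
            continue  # already constrained; odd-parity conflicts are dropped
        # attach the lexicographically larger root under the smaller one
        if ra > rb:
            ra, rb = rb, ra
            pa, pb = pb, pa
        parent[rb] = ra
        parity[rb] = pa ^ pb ^ int(flip)

    orientation: dict[str, str] = {}
    for cid in sorted(by_id):
        _root, p = find(cid)
        orientation[cid] = "-" if p else "+"
    return orientation


def pair_support(v1: RawContig, v2: RawContig, overlap: Overlap,
                 placements_v1: Sequence[Placement],
                 placements_v2: Sequence[Placement],
                 config: PipelineConfig) -> tuple[int, bool]:
    """Read pairs straddling the v1->v2 junction, and whether any are expected.

    A straddling pair has one mate on v1 and the other on v2 with
    consistent forward/reverse orientation in the tentative merged layout
    and an implied fragment span within mean +/- (window * sd) of the
    insert size.  ``expected`` is True when the merged layout can
    geometrically host such a fragment at all; edges lacking support are
    only rejected when support was expected.
    """
    len1, len2 = v1.length, v2.length
    ovl = overlap.length
    merged_len = len1 + len2 - ovl
    rl = config.read_length
    lo = config.insert_size_mean - config.insert_sd_window * config.insert_size_sd
    hi = config.insert_size_mean + config.insert_sd_window * config.insert_size_sd
    # feasible fragment spans for a straddling pair are [2*rl - ovl, merged_len]
    expected = (merged_len >= lo) and (2 * rl - ovl <= hi)

    offset = len1 - ovl
    supporting: set[int] = set()
    by_read: dict[int, list[Placement]] = {}
    for p in placements_v2:
        by_read.setdefault(p.read_id, []).append(p)
    for p1 in placements_v1:
        for p2 in by_read.get(p1.read_id, ()):
            if p1.mate == p2.mate:
                continue
            if overlap.orientation == "+":
                start2, end2, strand2 = offset + p2.start, offset + p2.end, p2.strand
            else:
                start2 = offset + (len2 - p2.end)
                end2 = offset + (len2 - p2.start)
                strand2 = "-" if p2.strand == "+" else "+"
            if p1.strand == strand2:
                continue
            if p1.strand == "+":
                left_start, right_end = p1.start, end2
                ordered = p1.start <= start2
            else:
                left_start, right_end = start2, p1.end
                ordered = start2 <= p1.start
            span = right_end - left_start
            if ordered and lo <= span <= hi:
                supporting.add(p1.read_id)
    return len(supporting), expected


def build_graph(contigs: Sequence[RawContig], reads,
                config: PipelineConfig) -> ContigGraph:
    """Construct the contig graph from overlaps plus read-pair evidence.

    Steps: remove divergently contained contigs; assign one strand per
    connected component and flip minus-strand contigs; recompute forward
    overlaps on the re-oriented set; map reads; admit each overlap edge
    through the pair-support rule.
    """
    contigs = list(contigs)
    graph = nx.DiGraph()
    if not contigs:
        return ContigGraph(graph=graph, contigs={})

    pairs = candidate_pairs(contigs, config.prefilter_substring_len, True)
    contained = _find_containments(contigs, pairs, config)
    surviving = [c for c in contigs if c.id not in contained]

    orientation = _assign_orientations(surviving, config)
    oriented = [
        c if orientation.get(c.id, "+") == "+"
        else RawContig(c.id, revcomp(c.sequence), c.source_k, c.source_bin_target)
        for c in surviving
    ]
    by_id = {c.id: c for c in oriented}
    graph.add_nodes_from(sorted(by_id))

    placements: list[Placement] = []
    if reads is not None and len(reads.pairs) > 0:
        placements = map_reads_to_contigs(reads, oriented, config)
    by_contig: dict[str, list[Placement]] = {cid: [] for cid in by_id}
    for p in placements:
        by_contig[p.contig_id].append(p)

    for a_id, b_id in sorted(candidate_pairs(oriented,
                                             config.prefilter_substring_len,
                                             False)):
        a, b = by_id[a_id], by_id[b_id]
        ov = compute_overlap(a, b, config, orientation_aware=False)
        if ov is None:
            continue
        if ov.length >= min(a.length, b.length):
            continue  # full overlap is containment, handled as deduplication
        support, expected = pair_support(a, b, ov, by_contig[a_id],
                                         by_contig[b_id], config)
        if expected and support < config.min_read_pair_support:
            continue
        graph.add_edge(a_id, b_id, overlap=ov, support=support,
                       expected=expected)

    return ContigGraph(graph=graph, contigs=by_id, orientation=orientation,
                       placements=placements)


def write_edge_list(cgraph: ContigGraph, path) -> None:
    """Dump edges as TSV: source, target, overlap length, mismatches, support."""
    with open(path, "w") as handle:
        handle.write("source\ttarget\toverlap_len\tmismatches\tsupport\n")
        for u, v, data in sorted(cgraph.graph.edges(data=True)):
            ov = data["overlap"]
            handle.write(f"{u}\t{v}\t{ov.length}\t{ov.mismatches}\t{data['support']}\n")
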