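"""Raw-contig assembly: frequent k-mers -> unitigs of a de Bruijn graph.

The inputs here are exact k-mers (not error-bearing reads), so a plain
unitig-only de Bruijn assembler suffices: nodes are (k-1)-mers, each
member k-mer is an edge, and every maximal non-branching path is spelled
as one raw contig.  Assembly is run per frequency bin and per k-mer
length, and the resulting lists are merged with substring deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import PipelineConfig
from .dna import canonical, revcomp
from .kmers import KmerCatalog, make_frequency_bins, select_frequent


@dataclass
class RawContig:
    """A conserved repeat fragment assembled from one frequency bin."""

    id: str
    sequence: str
    source_k: int
    source_bin_target: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)


def assemble_bin(members: Iterable[str], k: int, canonical_mode: bool = True,
                 id_prefix: str = "u", bin_target: float = 0.0) -> list[RawContig]:
    """Spell the maximal non-branching paths of the k-mer de Bruijn graph.

    With ``canonical_mode`` each member and its reverse complement are
    both inserted; traversing an edge consumes its reverse-complement
    twin as well, so every member k-mer ends up in exactly one output
    contig (in forward or reverse-complement orientation).  Node
    traversal order is lexicographic, making the output deterministic.
    """
    members = list(members)
    if not members:
        return []
    if any(len(m) != k for m in members):
        raise ValueError(f"all members must have length k={k}")

    edges: set[str] = set()
    for m in members:
        m = m.upper()
        edges.add(m)
        if canonical_mode:
            edges.add(revcomp(m))

    out_edges: dict[str, list[str]] = {}
    indeg: dict[str, int] = {}
    nodes: set[str] = set()
    for e in edges:
        u, v = e[:-1], e[1:]
        out_edges.setdefault(u, []).append(e)
        indeg[v] = indeg.get(v, 0) + 1
        nodes.add(u)
        nodes.add(v)
    for u in out_edges:
        out_edges[u].sort()

    def edge_key(e: str) -> str:
        return canonical(e) if canonical_mode else e

    def is_linear(v: str) -> bool:
        return len(out_edges.get(v, ())) == 1 and indeg.get(v, 0) == 1

    used: set[str] = set()
    sequences: list[str] = []

    def walk(first: str) -> None:
        used.add(edge_key(first))
        chars = [first]
        v = first[1:]
        while is_linear(v):
            nxt = out_edges[v][0]
            if edge_key(nxt) in used:
                break
            used.add(edge_key(nxt))
            chars.append(nxt)
            v = nxt[1:]
        seq = chars[0] + "".join(e[-1] for e in chars[1:])
        if canonical_mode:
            seq = min(seq, revcomp(seq))
        sequences.append(seq)

    # unitigs anchored at branching / terminal nodes
    for u in sorted(nodes):
        if not is_linear(u):
            for e in out_edges.get(u, ()):
                if edge_key(e) not in used:
                    walk(e)
    # leftover edges belong to isolated simple cycles
    for e in sorted(edges):
        if edge_key(e) not in used:
            walk(e)

    return [
        RawContig(id=f"{id_prefix}{i:04d}", sequence=seq, source_k=k,
                  source_bin_target=bin_target)
        for i, seq in enumerate(sequences)
    ]


def deduplicate_contigs(contigs: list[RawContig]) -> list[RawContig]:
    """Drop contigs contained (forward or reverse-complement) in another.

    Among exact duplicates the contig with the smaller id is retained.
    Output order is deterministic: length descending, then sequence.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.sequence, c.id))
    retained: list[RawContig] = []
    for c in ordered:
        seq, rc = c.sequence, revcomp(c.sequence)
        if any(seq in r.sequence or rc in r.sequence for r in retained):
            continue
        retained.append(c)
    return retained


def estimate_kmer_depth(catalog: KmerCatalog) -> float:
    """Per-locus k-mer depth estimate: mode of the count histogram.

    Counts of 1 (dominated by sequencing-error k-mers) are excluded when
    any higher count exists, so the estimate tracks the main single-copy
    coverage peak of the spectrum.
    """
    hist: dict[int, int] = {}
    for c in catalog.counts.values():
        hist[c] = hist.get(c, 0) + 1
    if not hist:
        raise ValueError("empty catalog")
    candidates = {c: n for c, n in hist.items() if c > 1} or hist
    return float(max(candidates, key=lambda c: (candidates[c], -c)))


def assemble_all(catalogs: Mapping[int, KmerCatalog],
                 config: PipelineConfig) -> list[RawContig]:
    """Select, bin and assemble frequent k-mers for every k; merge lists.

    For each k-mer length: select frequent k-mers against the catalog's
    average frequency, build frequency bins, and assemble bins from the
    highest target down.  Contigs from all bins and all k values are
    concatenated and substring-deduplicated into a single raw list.
    """
    if not catalogs:
        raise ValueError("at least one catalog is required")
    contigs: list[RawContig] = []
    for k in sorted(catalogs):
        catalog = catalogs[k]
        baseline = None
        if config.freq_baseline == "depth-estimate":
            baseline = estimate_kmer_depth(catalog)
        frequent = select_frequent(catalog, config.freq_cutoff_factor, baseline)
        if not frequent:
            continue
        for bi, fbin in enumerate(make_frequency_bins(frequent, config)):
            contigs.extend(
                assemble_bin(
                    fbin.members, k, canonical_mode=config.canonical_kmers,
                    id_prefix=f"k{k}b{bi:02d}u", bin_target=fbin.target_frequency,
                )
            )
    return deduplicate_contigs(contigs)
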