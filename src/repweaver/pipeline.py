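"""End-to-end repeat assembly: reads in, repeat consensus FASTA out."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .assembly import RawContig, assemble_all
from .config import PipelineConfig
from .coverage import annotate_repeats, filter_contigs
from .graph import ContigGraph, build_graph
from .kmers import KmerCatalog, count_kmers
from .mapping import map_reads_to_contigs
from .scaffold import AssembledRepeat, assemble_repeats
from .seqio import ReadSet

logger = logging.getLogger("repweaver")


@dataclass
class PipelineResult:
    """Intermediate and final products of one assembly run."""

    catalogs: dict[int, KmerCatalog]
    raw_contigs: list[RawContig]
    filtered_contigs: list[RawContig]
    contig_graph: ContigGraph | None
    repeats: list[AssembledRepeat] = field(default_factory=list)


def run_assembly(reads: ReadSet, config: PipelineConfig) -> PipelineResult:
    """Run every stage of the repeat-assembly pipeline.

    Stages: k-mer counting per k-mer length; frequent-k-mer selection,
    binning and de Bruijn assembly into raw contigs; coverage filtering
    of raw contigs; contig-graph construction with read-pair support;
    SCC condensation / path enumeration / merging; final coverage
    annotation and re-filtering of the merged repeats.
    """
    t0 = time.perf_counter()
    catalogs = {
        k: count_kmers(reads, k, canonical=config.canonical_kmers)
        for k in config.kmer_lengths
    }
    _stage(t0, "k-mer counting (%s catalogs)" % len(catalogs))

    raw = assemble_all(catalogs, config)
    _stage(t0, f"raw-contig assembly ({len(raw)} contigs)")
    if not raw:
        return PipelineResult(catalogs, [], [], None, [])

    placements = map_reads_to_contigs(reads, raw, config)
    filtered = filter_contigs(raw, placements, config)
    _stage(t0, f"coverage filtering ({len(filtered)} contigs kept)")
    if not filtered:
        return PipelineResult(catalogs, raw, [], None, [])

    cgraph = build_graph(filtered, reads, config)
    _stage(t0, f"contig graph ({cgraph.graph.number_of_nodes()} nodes, "
               f"{cgraph.graph.number_of_edges()} edges)")

    merged = assemble_repeats(cgraph)
    _stage(t0, f"path merging ({len(merged)} repeats)")

    final = annotate_repeats(merged, reads, config)
    _stage(t0, f"final annotation ({len(final)} repeats)")
    return PipelineResult(catalogs, raw, filtered, cgraph, final)


def _stage(t0: float, message: str) -> None:
    logger.info("[%8.2fs] %s", time.perf_counter() - t0, message)
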