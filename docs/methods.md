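# Methods

## Model and assumptions

`repweaver` reconstructs the consensus of repeat families that are (a)
present at high copy number and (b) of low within-family divergence.
The per-family k-mer frequency model is simple: a consensus k-mer that
is intact in a fraction q of copies is expected to occur
`copies × q × d_k` times in the reads, where `d_k ≈ depth × (L − k + 1)/L`
is the per-locus k-mer depth for read length L. With per-copy
substitution rate s and per-base read error e, `q ≈ ((1−s)(1−e))^k`.
Unique background sequence sits near `d_k`, so a frequency cutoff at
`f_K ×` (average frequency) separates repeat from background for
sufficiently high copy numbers. Divergent internal regions depress q
exponentially in k, which is why raw contigs fragment there — and why a
second, overlap-graph assembly stage exists at all.

The average k-mer frequency is the mean count over **distinct observed
k-mers** (`freq_baseline="distinct-mean"`). In error-bearing data this
average is pulled well below the single-copy depth by the mass of
singleton error k-mers, making the effective threshold `f_K × avg`
mild. The alternative `depth-estimate` baseline (mode of the count
histogram above 1, tracking the single-copy coverage peak) gives a
stricter reading of "ten times the depth"; it is exposed as a config
switch but is not the default.

K-mers are counted canonically (minimum of k-mer and reverse
complement) because shotgun reads sample both strands; a switch disables
this for strand-aware experiments. Windows containing N are skipped
rather than dropping the read.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `kmer_lengths` | 29, 39, 49 | shorter k tolerates divergence, longer k resolves ambiguity; runs are combined and deduplicated |
| `freq_cutoff_factor` (f_K) | 10 | strict `>` at the cutoff, so boundary behaviour is deterministic |
| `bin_low/high_factor` | 0.2 / 5 | bin admits counts in [0.2f, 5f] around target f |
| `bin_ratio` | 2 | geometric target sequence; consecutive bins overlap since 2 < 5/0.2 |
| `min_overlap_bp` | 15 | minimum contig junction; edits/length strictly < `max_mismatch_rate` (0.05) |
| `prefilter_substring_len` (k0) | 5 | any ≥15 bp overlap at <5% edits contains an exact 5-mer (pigeonhole), so the prefilter is lossless |
| `min_read_pair_support` | 1 | junctions need one straddling pair when geometry makes one possible |
| `min_avg_coverage` | 2 | discard threshold and per-base truncation threshold |
| `insert_sd_window` | 3 | straddling-pair spans accepted within mean ± 3 SD |
| `matching_cutoff` (t_L) | 0.85 | matched span / query length for a library hit |

Frequency-bin targets start at the highest observed frequent count and
halve until a target at or below the lowest frequent count has been
emitted. This stopping rule guarantees every frequent k-mer falls in at
least one bin while not generating bins whose targets lie below
anything observed.

## Numerical and algorithmic choices

**Unitig assembly.** Bin members are exact k-mers, not error-bearing
reads, so a unitig-only de Bruijn assembler suffices: nodes are
(k−1)-mers, members (and their reverse complements, in canonical mode)
are edges, and maximal non-branching paths are spelled. Traversing an
edge consumes its reverse-complement twin, so every member k-mer lands
in exactly one contig up to strand. Node traversal is lexicographic;
output is deterministic. Isolated cycles are spelled from their
smallest k-mer. A hook for an external assembler is intentionally
absent: the in-repo assembler is exact for this input class.

**Overlap detection.** Suffix–prefix overlaps are scanned from the
longest candidate length downward; each length is checked by banded
edit distance (edlib) with the edit ceiling `ceil(L·rate)−1`, which
realises the strict `< rate` contract. Ties between orientations at the
same length go to fewer mismatches, then forward. Full-length overlaps
are containment and resolved by discarding the contained contig, not by
an edge.

**Orientation handling.** The canonical-strand assembler stores each
contig on an arbitrary strand, so adjacent fragments may meet in any of
four end combinations (suffix–prefix, prefix–suffix, suffix–suffix,
prefix–prefix). All four are examined when inferring relative-strand
constraints; constraints are merged strongest-overlap-first with a
parity union-find, odd-parity conflicts are dropped, minus-strand
contigs are flipped, and the final edge set is recomputed forward-only
on the reoriented contigs. The two same-parity cases matter in
practice: a bridge contig stored on the opposite strand from both its
neighbours is otherwise unlinkable.

**Read mapping.** Seed-and-extend: exact 20-mer seeds every 5 bp (plus
the final window) located in a hash index, nearby diagonals clustered,
extension by edit distance with allowance `floor(0.06 × aligned
length)`. Reads may overhang contig ends; only the overlapping segment
(≥ one seed length) is aligned — soft-clip semantics. Without this,
contigs shorter than the read length can never accumulate coverage and
are spuriously discarded. All placements are reported (multi-mapping),
and each placement contributes one unit of depth: every copy of a
family legitimately covers the family contig.

**Pair support.** For a tentative junction of overlap `ovl` between
contigs of lengths l1, l2, a straddling fragment span lies in
`[2·read_length − ovl, l1 + l2 − ovl]`; support is *expected* iff this
interval intersects insert mean ± 3 SD. Unsupported edges are dropped
only when support was expected, so short merges below the insert range
are kept on overlap evidence alone.

**Path finding.** SCCs (networkx) are condensed (acyclic by
construction, asserted); inside each component a Kahn-style order takes
smallest-id zero-in-degree nodes first and, when blocked by a cycle,
clears the incoming edges of the smallest-id remaining node. Greedy
walks start at in-degree-0 nodes (then at any uncovered node, so every
node is emitted), prefer the out-edge to the nearest node ahead in the
global order, never revisit a node, and sub-paths of emitted paths are
removed. Exhaustive path enumeration is explicitly out of scope.

**Junction merging** keeps the predecessor's bases across a
mismatching junction: the successor contributes its suffix beyond the
aligned prefix. Merged length is exactly Σ lengths − Σ overlaps.

**Evaluation.** Local alignment uses Biopython's PairwiseAligner with
match +1, mismatch −2, gap −2.5 (megablast-like), both strands; the
matching ratio is aligned-query-span / query-length. The linear gap
penalty lets one merged repeat bridge an unassembled internal gap at a
proportional cost, which is the intended reading of span-based
matching. Maximum non-overlapping library coverage is computed exactly
by weighted interval scheduling rather than a length-greedy heuristic —
equally simple and never suboptimal. Identity is matches / max(query
span, reference span).

## Synthetic data: what it does and does not emulate

The generator plants mutated family copies (i.i.d. substitutions,
single-base indels, optional region-specific substitution rates, random
strands, non-overlapping insertion points) into a uniform random
background, then draws paired-end reads with normal fragment lengths,
uniform starts, both strands, and i.i.d. base errors. Everything is
recorded: consensus, per-copy placements and edit counts, per-read
positions and errors.

Not emulated: GC bias, quality decay along reads, indel sequencing
errors, nested/truncated/tandem repeat structure, target-site
duplications, poly-A tails. Passing tests therefore demonstrate the
algorithmics under the stated frequency model, not robustness to every
artefact of real libraries.

## Study conditions used by tests and the acceptance script

* `uniform_family`: 200 kb background, one 600 bp family × 60 copies,
  1% substitutions, 0.2% indels; 10× 2×100 bp pairs, insert 300 ± 30,
  0.5% error. Expected outcome: one repeat matching the planted
  consensus at ratio ≥ 0.85 with identity ≥ 0.95.
* `divergent_core_family`: 1.2 kb family whose central 150 bp block has
  8% substitutions (flanks 0.5%), 120 copies, same library. The copy
  number is chosen from the frequency model so the core's consensus
  k-mers sit marginally above the frequent threshold
  (`120 × 7.2 × 0.92^29 × 0.995^29 ≈ 66` against a threshold near 50):
  Poisson dips then fragment the unitigs into pieces overlapping by
  k − (dip run length), which is the regime where merging is necessary
  and possible. By construction this scenario is marginal: for some
  seeds a dip run leaves an overlap below 15 bp and the chain honestly
  breaks, so the merged matching ratio is seed-dependent (≈ 1.0 for
  most seeds); the fixed default seed is part of the condition.
* `decoy filter`: 20 random 150 bp contigs injected into the raw list
  attract no reads and must all be discarded, while every covered true
  contig survives.

Problem sizes (200 kb genomes, ≈12–17 k read pairs) keep a full
pipeline run in single-digit seconds while leaving the k-mer spectrum
regimes (background ≈ 7×, family ≈ 300–650×, threshold ≈ 40–50×)
cleanly separated.

## Known limitations

* The overlap model fixes equal suffix/prefix window lengths; indels
  inside a junction shift the register by at most the edit budget and
  are absorbed, but junction coordinates are nominal.
* Coverage truncation reuses `min_avg_coverage` as the per-base
  threshold; no attempt is made to model coverage statistically.
* Edges require sequence overlap; read-pair evidence alone never links
  contigs, so gaps longer than ~k−15 in the frequent-k-mer spectrum
  cannot be bridged.
* Path enumeration is heuristic; for dense tangles the emitted path set
  depends on the documented tie-breaks, not on global optimality.
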