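import numpy as np
import pytest

import repweaver as rw
from repweaver.assembly import RawContig
from repweaver.dna import revcomp
from repweaver.graph import (_max_edits, build_graph, candidate_pairs,
                             compute_overlap, pair_support)
from repweaver.mapping import map_reads_to_contigs

from conftest import random_dna


def mk(i, seq):
    return RawContig(f"c{i:02d}", seq, 15)


def edit_distance(a: str, b: str) -> int:
    """Plain quadratic Levenshtein DP (independent of edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_overlap(s: str, t: str, config, orientation_aware=True):
    """Exhaustive suffix-prefix scan with full DP, mirroring the contract."""
    orientations = [("+", t)] + ([("-", revcomp(t))] if orientation_aware else [])
    for L in range(min(len(s), len(t)), config.min_overlap_bp - 1, -1):
        best = None
        for orient, tt in orientations:
            d = edit_distance(s[-L:], tt[:L])
            if d / L < config.max_mismatch_rate:
                if best is None or d < best[1]:
                    best = (orient, d)
        if best:
            return L, best[1], best[0]
    return None


# ---------------------------------------------------------------- candidates

def test_candidate_pairs_no_shared_substring(cfg):
    contigs = [mk(0, "A" * 30), mk(1, "C" * 30)]
    assert candidate_pairs(contigs, 5) == set()


def test_candidate_pairs_reports_both_orders(cfg):
    contigs = [mk(0, "AAAAACTG"), mk(1, "CTGAAAAA")]
    pairs = candidate_pairs(contigs, 5)
    assert ("c00", "c01") in pairs and ("c01", "c00") in pairs


def test_candidate_pairs_matches_bruteforce_scan(cfg):
    rng = np.random.default_rng(10)
    contigs = [mk(i, random_dna(rng, 60)) for i in range(30)]
    got = candidate_pairs(contigs, 5)
    expected = set()
    for a in contigs:
        for b in contigs:
            if a.id == b.id:
                continue
            a_kmers = {a.sequence[i:i + 5] for i in range(56)}
            a_kmers |= {revcomp(a.sequence)[i:i + 5] for i in range(56)}
            b_kmers = {b.sequence[i:i + 5] for i in range(56)}
            if a_kmers & b_kmers:
                expected.add((a.id, b.id))
    assert got == expected


# ------------------------------------------------------------------ overlaps

def test_overlap_below_minimum_length_rejected(cfg):
    rng = np.random.default_rng(11)
    junction = random_dna(rng, 14)
    a = mk(0, random_dna(rng, 40) + junction)
    b = mk(1, junction + random_dna(rng, 40))
    assert compute_overlap(a, b, cfg) is None  # 14 < 15 bp minimum


def test_overlap_identical_sequences_full_length(cfg):
    rng = np.random.default_rng(12)
    seq = random_dna(rng, 30)
    ov = compute_overlap(mk(0, seq), mk(1, seq), cfg)
    assert (ov.length, ov.mismatches) == (30, 0)


def test_overlap_mismatch_rate_is_strict(cfg):
    rng = np.random.default_rng(13)
    junction = random_dna(rng, 20)
    mutated = "A" + junction[1:] if junction[0] != "A" else "C" + junction[1:]
    a = mk(0, random_dna(rng, 40) + junction)
    b = mk(1, mutated + random_dna(rng, 40))
    ov = compute_overlap(a, b, cfg)
    # 1/20 = 0.05 is not < 0.05; any qualifying overlap must be clean & shorter
    if ov is not None:
        assert ov.mismatches / ov.length < 0.05
        oracle = oracle_overlap(a.sequence, b.sequence, cfg)
        assert (ov.length, ov.mismatches) == oracle[:2]


@pytest.mark.parametrize("seed", range(6))
def test_overlap_agrees_with_full_dp_oracle(seed, cfg):
    rng = np.random.default_rng(100 + seed)
    for _ in range(8):
        left = random_dna(rng, int(rng.integers(30, 60)))
        right = random_dna(rng, int(rng.integers(30, 60)))
        junction = random_dna(rng, int(rng.integers(10, 35)))
        chars = list(junction)
        for _m in range(int(rng.integers(0, 2))):
            pos = int(rng.integers(0, len(chars)))
            chars[pos] = "ACGT"[int(rng.integers(0, 4))]
        a = mk(0, left + junction)
        b = mk(1, "".join(chars) + right)
        got = compute_overlap(a, b, cfg, orientation_aware=False)
        expected = oracle_overlap(a.sequence, b.sequence, cfg, False)
        if expected is None:
            assert got is None
        else:
            assert (got.length, got.mismatches) == expected[:2]


def test_overlap_antisymmetry_under_reverse_complement(cfg):
    rng = np.random.default_rng(14)
    junction = random_dna(rng, 25)
    a = mk(0, random_dna(rng, 50) + junction)
    b = mk(1, junction + random_dna(rng, 50))
    fwd = compute_overlap(a, b, cfg)
    assert fwd is not None and fwd.mismatches == 0
    rev = compute_overlap(mk(2, revcomp(b.sequence)), mk(3, revcomp(a.sequence)), cfg)
    assert rev is not None and rev.length == fwd.length


def test_prefilter_never_loses_a_qualifying_overlap(cfg):
    """Any >= 15 bp overlap at < 5% edits shares an exact 5-mer."""
    rng = np.random.default_rng(15)
    for _ in range(40):
        junction = random_dna(rng, int(rng.integers(15, 50)))
        chars = list(junction)
        budget = _max_edits(len(junction), cfg.max_mismatch_rate)
        for _m in range(budget):
            pos = int(rng.integers(0, len(chars)))
            chars[pos] = "ACGT"[int(rng.integers(0, 4))]
        a = mk(0, random_dna(rng, 40) + junction)
        b = mk(1, "".join(chars) + random_dna(rng, 40))
        if compute_overlap(a, b, cfg, False) is not None:
            assert (a.id, b.id) in candidate_pairs([a, b], 5)


def test_edge_count_monotone_in_thresholds(cfg):
    rng = np.random.default_rng(16)
    base = random_dna(rng, 400)
    contigs = [mk(i, base[s:s + 80]) for i, s in enumerate(range(0, 320, 60))]

    def n_qualifying(config):
        return sum(
            compute_overlap(a, b, config) is not None
            for a in contigs for b in contigs if a.id != b.id
        )

    counts = [n_qualifying(cfg.replace(min_overlap_bp=m)) for m in (15, 25, 45)]
    assert counts == sorted(counts, reverse=True)


# ------------------------------------------------------------------- mapping

def test_mapper_finds_exact_substring(cfg):
    rng = np.random.default_rng(17)
    contig = mk(0, random_dna(rng, 300))
    read = contig.sequence[57:157]
    reads = rw.ReadSet([(read, "T" * 100)], 100)
    placements = map_reads_to_contigs(reads, [contig], cfg)
    exact = [p for p in placements if p.mate == 0]
    assert any(p.start == 57 and p.end == 157 and p.edits == 0 and
               p.strand == "+" for p in exact)


def test_mapper_no_seed_no_placement(cfg):
    contig = mk(0, "AC" * 150)
    reads = rw.ReadSet([("GT" * 50, "TG" * 50)], 100)
    placements = [p for p in map_reads_to_contigs(reads, [contig], cfg)
                  if p.strand == "+"]
    assert placements == []


def test_mapper_recovers_simulated_truth_positions(cfg):
    rng = np.random.default_rng(18)
    contig = mk(0, random_dna(rng, 500))
    starts = [int(rng.integers(0, 400)) for _ in range(100)]
    pairs = []
    for s in starts:
        fwd = contig.sequence[s:s + 100]
        pairs.append((fwd, revcomp(contig.sequence[s:s + 100])))
    reads = rw.ReadSet(pairs, 100)
    placements = map_reads_to_contigs(reads, [contig], cfg)
    for rid, s in enumerate(starts):
        fwd_hits = [p for p in placements
                    if p.read_id == rid and p.mate == 0 and p.strand == "+"]
        rev_hits = [p for p in placements
                    if p.read_id == rid and p.mate == 1 and p.strand == "-"]
        assert any(p.start == s and p.edits == 0 for p in fwd_hits)
        assert any(p.start == s and p.edits == 0 for p in rev_hits)


# -------------------------------------------------------------- pair support

def _support_fixture(cfg, rng, frag_starts):
    merged = random_dna(rng, 700)
    v1 = mk(0, merged[:400])
    v2 = mk(1, merged[370:])
    ov = rw.Overlap("c00", "c01", 30, 0, "+")
    pairs = []
    for s in frag_starts:
        frag = merged[s:s + 300]
        pairs.append((frag[:100], revcomp(frag[-100:])))
    reads = rw.ReadSet(pairs, 100)
    placements = map_reads_to_contigs(reads, [v1, v2], cfg)
    p1 = [p for p in placements if p.contig_id == "c00"]
    p2 = [p for p in placements if p.contig_id == "c01"]
    return v1, v2, ov, p1, p2


def test_pair_support_counts_straddling_pairs(cfg):
    rng = np.random.default_rng(19)
    # fragments at 200 and 250 straddle the junction cleanly; 0 does not
    v1, v2, ov, p1, p2 = _support_fixture(cfg, rng, [0, 200, 250])
    support, expected = pair_support(v1, v2, ov, p1, p2, cfg)
    assert expected is True
    assert support == 2


def test_pair_support_rejects_unsupported_expected_edge(cfg):
    rng = np.random.default_rng(20)
    v1, v2, ov, _, _ = _support_fixture(cfg, rng, [])
    support, expected = pair_support(v1, v2, ov, [], [], cfg)
    assert (support, expected) == (0, True)


def test_pair_support_not_expected_for_short_merge(cfg):
    rng = np.random.default_rng(21)
    seq = random_dna(rng, 60)
    v1 = mk(0, seq[:45])
    v2 = mk(1, seq[15:])
    ov = rw.Overlap("c00", "c01", 30, 0, "+")
    support, expected = pair_support(v1, v2, ov, [], [], cfg)
    assert expected is False  # merged length 60 < shortest plausible insert


# --------------------------------------------------------------- build_graph

def test_build_graph_no_overlap_no_edges(cfg):
    rng = np.random.default_rng(22)
    contigs = [mk(0, random_dna(rng, 80)), mk(1, random_dna(rng, 80))]
    g = build_graph(contigs, None, cfg)
    assert g.graph.number_of_edges() == 0
    assert set(g.graph.nodes()) == {"c00", "c01"}


def test_build_graph_recovers_tiling_path(cfg):
    rng = np.random.default_rng(23)
    s = random_dna(rng, 500)
    contigs = [mk(0, s[0:200]), mk(1, s[170:370]), mk(2, s[340:500])]
    pairs = []
    for start in range(0, 200, 7):
        frag = s[start:start + 300]
        pairs.append((frag[:100], revcomp(frag[-100:])))
    reads = rw.ReadSet(pairs, 100)
    g = build_graph(contigs, reads, cfg)
    assert set(g.graph.edges()) == {("c00", "c01"), ("c01", "c02")}


def test_build_graph_withheld_reads_drop_expected_edges(cfg):
    rng = np.random.default_rng(23)
    s = random_dna(rng, 500)
    contigs = [mk(0, s[0:200]), mk(1, s[170:370]), mk(2, s[340:500])]
    g = build_graph(contigs, None, cfg)
    assert g.graph.number_of_edges() == 0
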