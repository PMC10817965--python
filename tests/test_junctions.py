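import numpy as np
import pytest

from loxscan.io_core import LOXPSYM_SEQ, PipelineConfig, revcomp
from loxscan.junctions import (
    CountsTable,
    UNCLASSIFIED,
    affine_score,
    build_junction_pool,
    classify_junctions,
    detected_junction_set,
    extract_flanks,
    pool_accounting,
    scan_lox_reads,
)
from loxscan.simulate import (
    LOX_LEN,
    SVEvent,
    ReadSimParams,
    apply_events,
    insert_lox,
    junction_of,
    make_toy_genome,
    simulate_reads,
    sparse_strain_table,
)


def _semiglobal_edit_distance(pattern: str, text: str) -> int:
    """Plain DP oracle: minimum edit distance of pattern against any
    substring of text (free start/end in text)."""
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if pattern[i - 1] == text[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


class TestExtractFlanks:
    def test_flank_coordinates(self):
        g = make_toy_genome(1, [20_000], seed=1)
        parent, sites = insert_lox(g, [("s1", "chr01", 5_000, 1)])
        seq = parent.get("chr01").sequence
        fl = extract_flanks(parent, sites, flank_len=1000)
        f = fl["s1"]
        assert f.up == seq[4_000:5_000]
        assert f.down == seq[5_000 + LOX_LEN: 6_000 + LOX_LEN]
        assert not f.up_truncated and not f.down_truncated

    def test_truncation_near_chromosome_start(self):
        g = make_toy_genome(1, [20_000], seed=1)
        parent, sites = insert_lox(g, [("s1", "chr01", 100, 1)])
        fl = extract_flanks(parent, sites, flank_len=1000)
        f = fl["s1"]
        assert len(f.up) == 100 and f.up_truncated
        assert not f.usable  # below min_flank on one side

    def test_shorter_flank_is_suffix_of_longer(self):
        g = make_toy_genome(1, [20_000], seed=1)
        parent, sites = insert_lox(g, [("s1", "chr01", 5_000, 1)])
        f500 = extract_flanks(parent, sites, 500)["s1"]
        f1000 = extract_flanks(parent, sites, 1000)["s1"]
        assert f1000.up.endswith(f500.up)
        assert f1000.down.startswith(f500.down)


@pytest.fixture(scope="module")
def toy():
    g = make_toy_genome(1, [60_000], seed=2)
    parent, sites = insert_lox(g, [
        ("s1", "chr01", 15_000, 1), ("s2", "chr01", 40_000, 1)])
    return parent, sites


@pytest.fixture(scope="module")
def strain():
    g = make_toy_genome(2, [200_000, 150_000], seed=51)
    parent, sites = insert_lox(g, [
        ("s1", "chr01", 40_000, 1), ("s2", "chr01", 120_000, 1),
        ("t1", "chr02", 50_000, 1), ("t2", "chr02", 100_000, 1)])
    fl = extract_flanks(parent, sites, 1000)
    pool = build_junction_pool(fl)
    return parent, sites, fl, pool


class TestJunctionPool:
    def test_two_loci_give_six_entries(self, toy):
        parent, sites = toy
        pool = build_junction_pool(extract_flanks(parent, sites, 1000))
        assert len(pool) == 6
        classes = [e.cls for e in pool.entries]
        assert classes.count("normal") == 2 and classes.count("novel") == 4
        novel_ends = {e.ends for e in pool.entries if e.cls == "novel"}
        assert novel_ends == {
            junction_of(("s1", "u"), ("s2", "d")),
            junction_of(("s1", "d"), ("s2", "u")),
            junction_of(("s1", "u"), ("s2", "u")),
            junction_of(("s1", "d"), ("s2", "d")),
        }

    def test_each_entry_contains_one_motif(self, toy):
        parent, sites = toy
        pool = build_junction_pool(extract_flanks(parent, sites, 1000))
        for e in pool.entries:
            assert e.seq.count(LOXPSYM_SEQ) == 1

    def test_entry_count_formula(self):
        g = make_toy_genome(1, [200_000], seed=3)
        spec = [(f"s{k}", "chr01", 20_000 * k, 1) for k in range(1, 6)]
        parent, sites = insert_lox(g, spec)
        pool = build_junction_pool(extract_flanks(parent, sites, 1000))
        assert len(pool) == 5 + 4 * 10
        assert pool.n_site_pairs() == 10

    def test_single_locus_rejected(self):
        g = make_toy_genome(1, [20_000], seed=4)
        parent, sites = insert_lox(g, [("s1", "chr01", 10_000, 1)])
        with pytest.raises(ValueError, match="2 usable loci"):
            build_junction_pool(extract_flanks(parent, sites, 1000))

    def test_self_pairs_optional(self, toy):
        parent, sites = toy
        fl = extract_flanks(parent, sites, 1000)
        assert len(build_junction_pool(fl, include_self_pairs=True)) == 6 + 4


class TestPoolAccounting:
    def test_sparse_strain_pair_arithmetic(self):
        acc = pool_accounting(sparse_strain_table())
        assert acc["n_pairs"] == 2775
        assert acc["n_intra_pairs"] == 210
        assert acc["n_inter_pairs"] == 2565
        assert acc["n_pool_entries"] == 75 + 4 * 2775


class TestScanLoxReads:
    def test_exact_occurrence_offset(self):
        read = "A" * 120 + LOXPSYM_SEQ + "C" * 200
        hits = scan_lox_reads([("r1", read)], max_lox_edits=0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].edits) == (120, 0)

    def test_three_substitutions_within_budget(self, rng):
        motif = list(LOXPSYM_SEQ)
        for p in (3, 15, 30):
            motif[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[motif[p]]
        read = "G" * 100 + "".join(motif) + "T" * 100
        hits = scan_lox_reads([("r1", read)], max_lox_edits=4)
        assert len(hits) == 1 and hits[0].edits == 3

    def test_two_distant_occurrences_reported_separately(self):
        read = "A" * 50 + LOXPSYM_SEQ + "C" * 2000 + LOXPSYM_SEQ + "G" * 50
        hits = scan_lox_reads([("r1", read)], max_lox_edits=1)
        assert [h.occurrence for h in hits] == [0, 1]
        assert hits[0].start == 50 and hits[1].start == 50 + LOX_LEN + 2000

    def test_agrees_with_dp_oracle_on_noisy_motifs(self, rng):
        """Best-hit edit distance matches an independent DP computation."""
        for trial in range(15):
            bg = "".join(rng.choice(list("ACGT"), size=400))
            motif = list(LOXPSYM_SEQ)
            n_err = int(rng.integers(0, 4))
            for p in rng.choice(LOX_LEN, size=n_err, replace=False):
                motif[p] = "ACGT"[int(rng.integers(0, 4))]
            read = bg[:200] + "".join(motif) + bg[200:]
            hits = scan_lox_reads([("r", read)], max_lox_edits=4)
            oracle = _semiglobal_edit_distance(LOXPSYM_SEQ, read)
            if oracle <= 4:
                assert hits and min(h.edits for h in hits) == oracle
            else:
                assert not hits


class TestClassification:
    def test_unrearranged_read_called_normal(self, strain):
        parent, sites, fl, pool = strain
        seq = parent.get("chr01").sequence[38_000: 42_100]
        hits = scan_lox_reads([("r1", seq)], max_lox_edits=0)
        calls, counts = classify_junctions(hits, {"r1": seq}, fl, pool)
        assert len(calls) == 1
        assert calls[0].cls == "normal"
        assert counts.nnorm["s1"] == 1 and counts.nre["s1"] == 0

    def test_deletion_reads_hit_only_the_planted_junction(self, strain):
        parent, sites, fl, pool = strain
        out, log = apply_events(parent, sites, [SVEvent("deletion", sites=("s1", "s2"))])
        reads, _ = simulate_reads(out, ReadSimParams(
            coverage=10, sub_rate=0, ins_rate=0, del_rate=0, seed=5))
        hits = scan_lox_reads(reads, max_lox_edits=0)
        calls, counts = classify_junctions(hits, reads, fl, pool)
        novel_pairs = {p for p in counts.nre_pair}
        assert novel_pairs == {frozenset(("s1", "s2"))}
        assert detected_junction_set(counts, calls, 1) == log.novel_pairs()

    def test_short_context_is_unclassified(self, strain):
        parent, sites, fl, pool = strain
        seq = parent.get("chr01").sequence
        read = seq[39_950: 42_000]  # 50 bp of upstream context only
        hits = scan_lox_reads([("r1", read)], max_lox_edits=0)
        calls, _ = classify_junctions(hits, {"r1": read}, fl, pool)
        assert calls[0].junction_id == UNCLASSIFIED
        assert calls[0].reason == "near_read_end"

    def test_indistinguishable_flanks_tie_to_unclassified(self):
        # two loci embedded in an identical 6 kb repeat -> any spanning read
        # matches both normal entries equally; the margin rule must refuse
        g = make_toy_genome(1, [50_000], seed=52)
        repeat = g.get("chr01").sequence[10_000:16_000]
        seq = g.get("chr01").sequence
        seq = seq[:20_000] + repeat + seq[26_000:]  # plant the repeat twice
        from loxscan.io_core import Chromosome, GenomeModel
        g2 = GenomeModel([Chromosome("chr01", seq)])
        parent, sites = insert_lox(g2, [("s1", "chr01", 13_000, 1),
                                        ("s2", "chr01", 23_000, 1)])
        fl = extract_flanks(parent, sites, 1000)
        pool = build_junction_pool(fl)
        read = parent.get("chr01").sequence[11_500: 14_600]
        hits = scan_lox_reads([("r1", read)], max_lox_edits=0)
        calls, _ = classify_junctions(hits, {"r1": read}, fl, pool)
        assert calls[0].junction_id == UNCLASSIFIED
        assert calls[0].reason == "ambiguous"

    def test_count_conservation(self, strain):
        parent, sites, fl, pool = strain
        out, _ = apply_events(parent, sites, [
            SVEvent("inversion", sites=("s1", "s2")),
            SVEvent("deletion", sites=("t1", "t2")),
        ])
        reads, _ = simulate_reads(out, ReadSimParams(
            coverage=8, sub_rate=0.02, ins_rate=0.01, del_rate=0.01, seed=6))
        hits = scan_lox_reads(reads)
        calls, counts = classify_junctions(hits, reads, fl, pool)
        n_norm = sum(counts.nnorm.values())
        n_novel = sum(1 for c in calls if c.cls == "novel")
        n_uncls = sum(1 for c in calls if c.junction_id == UNCLASSIFIED)
        assert n_norm + n_novel + n_uncls == len(hits)
        # Nre_i equals the sum of pair counts over both ends
        for locus in counts.loci:
            from_pairs = sum(n for p, n in counts.nre_pair.items() if locus in p)
            assert counts.nre.get(locus, 0) == from_pairs


class TestAffineScore:
    @pytest.mark.parametrize("cigar,expected", [
        ("10=", 10.0),
        ("5=2X3=", 5 - 2 + 3),
        ("4=1I4=", 8 - 2),       # single-base gap: open only
        ("4=3D4=", 8 - 2 - 2),   # 3-base gap: open + 2 extensions
    ])
    def test_scoring_scheme(self, cigar, expected):
        assert affine_score(cigar) == expected


class TestCountsTable:
    def test_nall_definition(self):
        c = CountsTable.empty(["a", "b"])
        c.add_normal("a")
        c.add_novel("a", "b")
        assert c.nall("a") == 2 * 1 + 1
        assert c.nall("b") == 1
        assert c.nre_pair[frozenset(("a", "b"))] == 1
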