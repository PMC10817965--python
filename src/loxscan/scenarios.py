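"""Reference study designs: fixed simulation scenarios used to validate the
pipeline end to end.

Each function builds a synthetic study (genome, planted events, reads),
runs the relevant pipeline stages and returns the measured quantities
together with the ground truth.  Problem sizes are chosen for desk-scale
verification: genomes of a few megabases, tens of loci, and coverages at
which the per-window depth sampling noise (which scales as 1/sqrt(depth)
for 2 kb windows read by multi-kilobase fragments) leaves integer copy
numbers clearly separated.
"""

from __future__ import annotations

import numpy as np

from . import cnv as cv
from . import deconvolve as dc
from . import junctions as jx
from . import stats as st
from .io_core import CentromereTable, LoxSite, LoxSiteTable, PipelineConfig
from .simulate import (
    ReadSimParams,
    SVEvent,
    apply_events,
    insert_lox,
    make_diploid,
    make_toy_genome,
    random_lox_spec,
    simulate_reads,
)


# ---------------------------------------------------------------------------
# multi-event SCRaMbLE round trip
# ---------------------------------------------------------------------------

#: Ten planted events mixing every junction-forming rearrangement kind, on a
#: 5-chromosome genome with 4 loci per chromosome.
SCRAMBLE_EVENTS = [
    SVEvent("deletion", sites=("01-1", "01-2")),
    SVEvent("inversion", sites=("01-3", "01-4")),
    SVEvent("duplication", sites=("02-1", "02-2")),
    SVEvent("deletion", sites=("02-3", "02-4")),
    SVEvent("translocation_reciprocal", sites=("03-1", "04-1")),
    SVEvent("inversion", sites=("03-2", "03-3")),
    SVEvent("translocation_nonreciprocal", sites=("04-2", "03-4")),
    SVEvent("duplication", sites=("05-1", "05-2")),
    SVEvent("inversion", sites=("05-3", "05-4")),
    SVEvent("circularization", sites=("05-1", "05-4")),
]


def build_scramble_truth(seed: int = 0, chrom_len: int = 500_000):
    """5 x 0.5 Mb genome, 20 loci, the 10-event mixture; returns
    (parent genome, sites, rearranged genome, event log)."""
    genome = make_toy_genome(5, [chrom_len] * 5, seed=seed)
    spec = random_lox_spec(genome, 20, min_per_chrom=4, seed=seed + 1)
    parent, sites = insert_lox(genome, spec)
    scrambled, log = apply_events(parent, sites, SCRAMBLE_EVENTS, seed=seed)
    return parent, sites, scrambled, log


def junction_recovery_study(
    seed: int = 0,
    coverage: float = 20.0,
    error_rate: float = 0.05,
    flank_len: int = 1000,
    min_support: int = 2,
) -> dict:
    """Simulation round trip: planted events -> reads -> junction calls.

    Returns event-level precision/recall of detected novel junctions against
    the simulator truth, plus the observed intra-chromosomal event fraction.
    """
    parent, sites, scrambled, log = build_scramble_truth(seed)
    params = ReadSimParams(
        coverage=coverage,
        sub_rate=error_rate * 0.6, ins_rate=error_rate * 0.2,
        del_rate=error_rate * 0.2, seed=seed + 2,
    )
    reads, _truth = simulate_reads(scrambled, params)
    cfg = PipelineConfig(flank_len=flank_len)
    flanks = jx.extract_flanks(parent, sites, flank_len)
    pool = jx.build_junction_pool(flanks, cfg.lox_seq)
    hits = jx.scan_lox_reads(reads, cfg.lox_seq, cfg.max_lox_edits)
    calls, counts = jx.classify_junctions(hits, reads, flanks, pool, cfg)
    detected = jx.detected_junction_set(counts, calls, min_support=min_support)
    res = jx.junction_recovery(detected, log.novel_pairs())
    res["n_occurrences"] = len(hits)
    res["detected"] = detected
    res["counts"] = counts
    res["calls"] = calls
    res["log"] = log
    return res


def flank_robustness_study(seed: int = 0, coverage: float = 10.0) -> dict:
    """Zero-error classification at flank lengths 500/1000/1500/2500;
    the recovered event sets should be identical."""
    parent, sites, scrambled, log = build_scramble_truth(seed)
    params = ReadSimParams(coverage=coverage, sub_rate=0, ins_rate=0,
                           del_rate=0, seed=seed + 2)
    reads, _ = simulate_reads(scrambled, params)
    hits = jx.scan_lox_reads(reads, max_lox_edits=0)
    detected = {}
    for fl in (500, 1000, 1500, 2500):
        cfg = PipelineConfig(flank_len=fl)
        flanks = jx.extract_flanks(parent, sites, fl)
        pool = jx.build_junction_pool(flanks, cfg.lox_seq)
        calls, counts = jx.classify_junctions(hits, reads, flanks, pool, cfg)
        detected[fl] = jx.detected_junction_set(counts, calls, min_support=1)
    sets = list(detected.values())
    return {
        "detected": detected,
        "identical": all(s == sets[0] for s in sets[1:]),
        "truth": log.novel_pairs(),
    }


def zero_error_oracle_study(seed: int = 0, coverage: float = 10.0) -> dict:
    """Agreement between classification and exhaustive substring search of
    every pool entry in every read, at zero read error (small genome,
    <= 10 loci)."""
    genome = make_toy_genome(3, [300_000, 250_000, 200_000], seed=seed)
    spec = random_lox_spec(genome, 8, min_per_chrom=2, seed=seed + 1)
    parent, sites = insert_lox(genome, spec)
    events = [
        SVEvent("deletion", sites=("01-1", "01-2")),
        SVEvent("inversion", sites=("02-1", "02-2")),
        SVEvent("translocation_reciprocal", sites=("01-3", "03-1")),
    ]
    scrambled, log = apply_events(parent, sites, events)
    params = ReadSimParams(coverage=coverage, sub_rate=0, ins_rate=0,
                           del_rate=0, seed=seed + 2)
    reads, _ = simulate_reads(scrambled, params)
    cfg = PipelineConfig()
    flanks = jx.extract_flanks(parent, sites, cfg.flank_len)
    pool = jx.build_junction_pool(flanks, cfg.lox_seq)
    hits = jx.scan_lox_reads(reads, max_lox_edits=0)
    calls, _counts = jx.classify_junctions(hits, reads, flanks, pool, cfg)

    from .io_core import revcomp

    # brute-force oracle: which entries appear verbatim in which read
    read_seq = {r.read_id: r.sequence for r in reads}
    oracle: dict[tuple[str, int], str] = {}
    for rid, seq in read_seq.items():
        rc = revcomp(seq)
        for e in pool.entries:
            for hay, is_rc in ((seq, False), (rc, True)):
                off = hay.find(e.seq)
                while off >= 0:
                    lox_off = off + (len(e.seq) - 34) // 2
                    pos = lox_off if not is_rc else len(seq) - lox_off - 34
                    oracle[(rid, pos)] = e.junction_id
                    off = hay.find(e.seq, off + 1)

    n_checked = n_agree = 0
    full = cfg.flank_len
    for c, h in zip(calls, (h for h in hits)):
        # compare only occurrences with full flank context in the read
        if h.start >= full and len(read_seq[h.read_id]) - h.end - 1 >= full:
            n_checked += 1
            expect = oracle.get((h.read_id, h.start))
            if expect is not None and c.junction_id == expect:
                n_agree += 1
    return {
        "n_checked": n_checked,
        "n_agree": n_agree,
        "agreement": n_agree / n_checked if n_checked else float("nan"),
        "n_oracle_hits": len(oracle),
    }


# ---------------------------------------------------------------------------
# diploid CNV / LOH study
# ---------------------------------------------------------------------------

#: Planted truth of the diploid study: copy number per flank window and the
#: loci converted to homozygosity.
CNV_EVENTS = [
    SVEvent("loh_conversion", haplotype="A", chrom="chr01",
            interval=(24_000, 26_000), donor_haplotype="B"),
    SVEvent("loh_conversion", haplotype="A", chrom="chr01",
            interval=(54_000, 56_000), donor_haplotype="B"),
    SVEvent("loh_conversion", haplotype="A", chrom="chr05",
            interval=(24_000, 26_000), donor_haplotype="B"),
    SVEvent("chrom_loss", chrom="chr03", haplotype="A"),
    SVEvent("chrom_loss", chrom="chr03", haplotype="B"),
    SVEvent("chrom_gain", chrom="chr04", haplotype="B"),
    SVEvent("deletion", sites=("02-1", "02-2"), haplotype="A"),
]

CNV_TRUTH = {
    **{(f"0{c}-{k}", side): 2 for c in (1, 5) for k in (1, 2)
       for side in ("up", "down")},
    ("02-1", "up"): 2, ("02-1", "down"): 1,
    ("02-2", "up"): 1, ("02-2", "down"): 2,
    **{(f"03-{k}", side): 0 for k in (1, 2) for side in ("up", "down")},
    **{(f"04-{k}", side): 3 for k in (1, 2) for side in ("up", "down")},
}

LOH_TRUTH = {"01-1", "01-2", "05-1"}


def build_cnv_diploid(seed: int = 0, chrom_len: int = 80_000):
    """5 x 80 kb diploid, 2 loci per chromosome (positions 25/55 kb on the
    lox-free base), hapA lox-bearing, hapB wild type; parent = unscrambled
    diploid, sample = diploid after the planted CNV/LOH events."""
    base = make_toy_genome(5, [chrom_len] * 5, seed=seed)
    spec = []
    for c in range(1, 6):
        spec.append((f"0{c}-1", f"chr0{c}", 25_000, 1))
        spec.append((f"0{c}-2", f"chr0{c}", 55_000, 1))
    hapA, sites = insert_lox(base, spec)
    parent, _ = make_diploid(hapA, base, [], sites_a=sites)
    sample, log = make_diploid(hapA, base, CNV_EVENTS, sites_a=sites)
    return hapA, sites, parent, sample, log


def cnv_loh_study(
    seed: int = 0,
    sample_coverage: float = 100.0,
    parent_coverage: float = 200.0,
    error_rate: float = 0.05,
) -> dict:
    """Recovery of planted copy-number segments (CN 0/1/2/3) and LOH
    conversions from flank read depth in a hetero-diploid.

    Coverages are set so 2 kb-window depth noise keeps integer copy numbers
    separated (see module docstring); reads use a ~4.5 kb median length.
    """
    hapA, sites, parent, sample, log = build_cnv_diploid(seed)
    rp = dict(mean_log=8.4, sd_log=0.4, sub_rate=error_rate * 0.6,
              ins_rate=error_rate * 0.2, del_rate=error_rate * 0.2)
    reads_p, _ = simulate_reads(parent, ReadSimParams(
        coverage=parent_coverage, seed=seed + 11, **rp))
    reads_s, _ = simulate_reads(sample, ReadSimParams(
        coverage=sample_coverage, seed=seed + 12, **rp))
    dep_p = cv.compute_flank_depth(reads_p, hapA, sites)
    dep_s = cv.compute_flank_depth(reads_s, hapA, sites)
    cn_calls = cv.iterative_cnv(dep_s, dep_p, ploidy=2)

    cfg = PipelineConfig()
    flanks = jx.extract_flanks(hapA, sites, cfg.flank_len)
    pool = jx.build_junction_pool(flanks, cfg.lox_seq)
    hits = jx.scan_lox_reads(reads_s, cfg.lox_seq, cfg.max_lox_edits)
    jcalls, counts = jx.classify_junctions(hits, reads_s, flanks, pool, cfg)
    status = cv.call_lox_status(cn_calls, dep_s, counts, jcalls)
    hyps = cv.infer_sv_hypotheses(cn_calls, counts, jcalls, sites)

    n_ok = sum(1 for c in cn_calls if CNV_TRUTH[(c.locus, c.side)] == c.cn)
    loh_called = {s.locus for s in status if s.state == "lox_lost"}
    tp = len(loh_called & LOH_TRUTH)
    return {
        "cn_calls": cn_calls,
        "cn_accuracy": n_ok / len(cn_calls),
        "n_windows": len(cn_calls),
        "loh_called": loh_called,
        "loh_precision": tp / len(loh_called) if loh_called else float("nan"),
        "loh_recall": tp / len(LOH_TRUTH),
        "status": status,
        "hypotheses": hyps,
        "log": log,
    }


# ---------------------------------------------------------------------------
# deconvolution exhaustive study
# ---------------------------------------------------------------------------

def deconvolution_exhaustive_study(
    max_segments: int = 6, circular_max: int = 4
) -> dict:
    """For every canonical signed arrangement of up to ``max_segments``
    distinct segments (linear; circular up to ``circular_max``), rebuild the
    arrangement from its error-free junction observations and count exact
    recoveries and circular-topology detections."""
    from itertools import permutations, product

    n_linear = n_linear_ok = 0
    n_circ = n_circ_ok = 0
    for n in range(2, max_segments + 1):
        seen = set()
        for perm in permutations(range(1, n + 1)):
            for orients in product("+-", repeat=n):
                arr = tuple(zip(perm, orients))
                canon = dc.canonical_arrangement(arr, "linear")
                if canon in seen:
                    continue
                seen.add(canon)
                edges = dc.arrangement_edges(canon, "linear")
                obs = [dc.JunctionObservation(e[0], e[1], 5)
                       for e in edges.elements()]
                cns = {k: 1 for k in range(1, n + 1)}
                res = dc.reconstruct(obs, cns, support_threshold=1)
                n_linear += 1
                if (res.topology == "linear" and not res.alternatives
                        and res.arrangement == canon):
                    n_linear_ok += 1
    for n in range(2, circular_max + 1):
        seen = set()
        for perm in permutations(range(1, n + 1)):
            for orients in product("+-", repeat=n):
                arr = tuple(zip(perm, orients))
                canon = dc.canonical_arrangement(arr, "circular")
                if canon in seen:
                    continue
                seen.add(canon)
                edges = dc.arrangement_edges(canon, "circular")
                obs = [dc.JunctionObservation(e[0], e[1], 5)
                       for e in edges.elements()]
                cns = {k: 1 for k in range(1, n + 1)}
                res = dc.reconstruct(obs, cns, support_threshold=1)
                n_circ += 1
                if res.topology == "circular" and res.arrangement == canon:
                    n_circ_ok += 1
    return {
        "n_linear": n_linear, "n_linear_exact": n_linear_ok,
        "n_circular": n_circ, "n_circular_exact": n_circ_ok,
        "linear_recovery": n_linear_ok / n_linear,
        "circular_recovery": n_circ_ok / n_circ,
    }


# ---------------------------------------------------------------------------
# statistics null / calibration studies
# ---------------------------------------------------------------------------

def draw_null_counts(sites: LoxSiteTable, n_events: int, depth_norm: int,
                     seed: int = 0) -> jx.CountsTable:
    """Counts table under uniform recombination: ``n_events`` rearranged
    reads drawn uniformly over all locus pairs, ``depth_norm`` normal reads
    per locus."""
    rng = np.random.default_rng(seed)
    loci = [s.site_id for s in sites]
    pairs = [(a, b) for i, a in enumerate(loci) for b in loci[i + 1:]]
    counts = jx.CountsTable.empty(loci)
    for l in loci:
        counts.nnorm[l] = depth_norm
    draws = rng.multinomial(n_events, np.full(len(pairs), 1.0 / len(pairs)))
    for (a, b), n in zip(pairs, draws):
        if n:
            counts.nre[a] += n
            counts.nre[b] += n
            counts.nre_pair[frozenset((a, b))] = int(n)
    return counts


def null_intra_fraction_study(seed: int = 0, n_events: int = 20_000) -> dict:
    """Uniform-recombination null on the sparse 83-site layout: the observed
    intra-chromosomal event fraction should converge to the analytic pair
    fraction (210/2775)."""
    from .simulate import sparse_strain_table

    sites = sparse_strain_table()
    counts = draw_null_counts(sites, n_events, depth_norm=100, seed=seed)
    return {
        "observed": st.observed_intra_fraction(counts, sites),
        "expected": st.intra_pair_fraction(sites),
        "n_events": n_events,
    }


def arr_null_study(seeds=range(10), n_events: int = 5_700,
                   depth_norm: int = 300) -> dict:
    """Uniform recombination: intra vs inter ARR should be statistically
    indistinguishable (two-sided Mann-Whitney) across seeds.

    Event and normal-read totals mirror the scale observed in a haploid
    SCRaMbLE pool (a few thousand rearranged reads over 75 loci, with
    roughly twice as many normal as rearranged observations per site).
    """
    from scipy import stats as sps

    from .simulate import sparse_strain_table

    sites = sparse_strain_table()
    pvals = []
    means_i, means_e = [], []
    for seed in seeds:
        counts = draw_null_counts(sites, n_events, depth_norm=depth_norm, seed=seed)
        arr_i = st.compute_arr(counts, sites, "intra").dropna()
        arr_e = st.compute_arr(counts, sites, "inter").dropna()
        means_i.append(float(arr_i.mean()))
        means_e.append(float(arr_e.mean()))
        pvals.append(float(sps.mannwhitneyu(
            arr_i, arr_e, alternative="two-sided").pvalue))
    return {"p_values": pvals,
            "n_nonsig": sum(1 for p in pvals if p > 0.05),
            "pooled_mean_intra": float(np.mean(means_i)),
            "pooled_mean_inter": float(np.mean(means_e))}


def rw_distance_calibration_study(slope: float = 5.0) -> dict:
    """Same-arm loci with RW set exactly to ``slope``/distance: the distance
    regression must return R^2 = 1 and recover the slope."""
    sites = LoxSiteTable([
        LoxSite(f"X-{k}", "chrX", pos, 1)
        for k, pos in enumerate([10_000, 25_000, 47_000, 90_000, 160_000], 1)
    ])
    cen = CentromereTable({"chrX": (200_000, 200_120)})
    loci = [s.site_id for s in sites]
    pos = {s.site_id: s.position for s in sites}
    vals = np.zeros((len(loci), len(loci)))
    for i, a in enumerate(loci):
        for j in range(i + 1, len(loci)):
            d = abs(pos[a] - pos[loci[j]])
            vals[i, j] = vals[j, i] = slope / d
    rw = st.RWMatrix(loci, vals)
    res = st.rw_distance_regression(rw, sites, cen)
    return {"r_squared": res.r_squared, "slope": res.slope,
            "n_pairs": res.n_pairs}
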