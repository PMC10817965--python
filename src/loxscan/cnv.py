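"""Flank read-depth, copy-number and loss-of-heterozygosity deduction around
lox loci in (hetero-)diploids, plus rule-based structural-variant hypotheses.

Reads are placed on the parental reference with an internal seed-anchored
matcher (exact k-mer seeds on the 2 kb windows flanking each lox locus,
median-offset placement), so no external aligner is involved.  Depth is mean
aligned bases per window position, split by whether the covering read carries
a lox motif at the locus.  Copy number is estimated per window by iterative
median re-scaling of sample/parent depth ratios, re-anchored each round on
the windows currently assigned the modal ploidy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import GenomeModel, LoxSiteTable, logger, revcomp
from .junctions import CountsTable, JunctionCall, LoxReadHit, scan_lox_reads
from .simulate import LOX_LEN, SimRead

Region = tuple[str, str]  # (locus, 'up' | 'down')


# ---------------------------------------------------------------------------
# windows and read placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Window:
    locus: str
    side: str
    chrom: str
    start: int
    end: int
    lox_pos: int  # motif start on the parental reference
    truncated: bool


def _make_windows(genome: GenomeModel, sites: LoxSiteTable, window: int) -> list[_Window]:
    out = []
    for s in sites:
        L = len(genome.get(s.chrom))
        us, ue = max(0, s.position - window), s.position
        ds, de = s.position + LOX_LEN, min(L, s.position + LOX_LEN + window)
        out.append(_Window(s.site_id, "up", s.chrom, us, ue, s.position,
                           truncated=ue - us < window))
        out.append(_Window(s.site_id, "down", s.chrom, ds, de, s.position,
                           truncated=de - ds < window))
        if ue - us < window or de - ds < window:
            logger.warning("flank window of %s truncated by chromosome end", s.site_id)
    return out


def _index_windows(genome: GenomeModel, windows: Sequence[_Window], k: int
                   ) -> dict[str, tuple[int, int, int]]:
    """kmer -> (window index, ref position of kmer start, orient) with
    ambiguous kmers dropped.  orient +1: kmer on forward strand; -1: the
    kmer is the reverse complement of the reference at that position."""
    index: dict[str, tuple[int, int, int]] = {}
    ambiguous: set[str] = set()

    def add(km: str, val: tuple[int, int, int]) -> None:
        if km in ambiguous:
            return
        if km in index and index[km] != val:
            del index[km]
            ambiguous.add(km)
        else:
            index[km] = val

    for wi, w in enumerate(windows):
        seq = genome.get(w.chrom).sequence[w.start: w.end]
        rc = revcomp(seq)
        n = len(seq)
        for off in range(0, n - k + 1):
            add(seq[off: off + k], (wi, w.start + off, +1))
            add(rc[off: off + k], (wi, w.start + (n - off - k), -1))
    return index


@dataclass
class _Placement:
    window: int
    ref_start: int  # inferred reference start of the read
    votes: int
    orient: int


def _place_read(seq: str, index: Mapping[str, tuple[int, int, int]],
                k: int, step: int, min_votes: int) -> list[_Placement]:
    n = len(seq)
    votes: dict[tuple[int, int], list[int]] = {}
    for p in range(0, n - k + 1, step):
        hit = index.get(seq[p: p + k])
        if hit is None:
            continue
        wi, ref, orient = hit
        if orient > 0:
            r0 = ref - p
        else:
            r0 = ref - n + p + k
        votes.setdefault((wi, orient), []).append(r0)
    out = []
    for (wi, orient), r0s in votes.items():
        if len(r0s) >= min_votes:
            out.append(_Placement(wi, int(np.median(r0s)), len(r0s), orient))
    return out


# ---------------------------------------------------------------------------
# flank depth
# ---------------------------------------------------------------------------

def compute_flank_depth(
    reads: Iterable[SimRead | tuple[str, str]],
    parent_genome: GenomeModel,
    sites: LoxSiteTable,
    window: int = 2000,
    lox_hits: Sequence[LoxReadHit] | None = None,
    k: int = 21,
    step: int = 9,
    min_votes: int = 3,
) -> pd.DataFrame:
    """Mean per-base read depth over the 2 kb windows flanking each locus.

    Returns one row per (locus, side) with total depth split into
    lox-containing and lox-free components, plus counts of reads spanning
    the motif position with/without a lox motif there (the LOH signal).
    ``parent_genome`` must be the haploid lox-bearing reference matching the
    site table's coordinates.
    """
    reads = [(r.read_id, r.sequence) if isinstance(r, SimRead) else tuple(r)
             for r in reads]
    windows = _make_windows(parent_genome, sites, window)
    index = _index_windows(parent_genome, windows, k)
    if lox_hits is None:
        lox_hits = scan_lox_reads(reads)
    hits_by_read: dict[str, list[LoxReadHit]] = {}
    for h in lox_hits:
        hits_by_read.setdefault(h.read_id, []).append(h)

    cover = np.zeros(len(windows))
    cover_lox = np.zeros(len(windows))
    span_lox = np.zeros(len(windows), dtype=int)
    span_nolox = np.zeros(len(windows), dtype=int)

    for rid, seq in reads:
        placements = _place_read(seq, index, k, step, min_votes)
        if not placements:
            continue
        n = len(seq)
        # reference positions of this read's lox occurrences per placement
        rhits = hits_by_read.get(rid, [])
        for pl in placements:
            w = windows[pl.window]
            ov = min(w.end, pl.ref_start + n) - max(w.start, pl.ref_start)
            if ov <= 0:
                continue
            lox_here = False
            for h in rhits:
                if pl.orient > 0:
                    ref_lox = pl.ref_start + h.start
                else:
                    ref_lox = pl.ref_start + n - h.end - 1
                if abs(ref_lox - w.lox_pos) <= 80:
                    lox_here = True
                    break
            cover[pl.window] += ov
            if lox_here:
                cover_lox[pl.window] += ov
            spans = (pl.ref_start <= w.lox_pos - 50
                     and pl.ref_start + n >= w.lox_pos + LOX_LEN + 50)
            if spans:
                if lox_here:
                    span_lox[pl.window] += 1
                else:
                    span_nolox[pl.window] += 1

    rows = []
    for wi, w in enumerate(windows):
        wl = w.end - w.start
        rows.append((w.locus, w.side, w.chrom, w.start + 1, w.end,
                     cover[wi] / wl, cover_lox[wi] / wl,
                     (cover[wi] - cover_lox[wi]) / wl,
                     int(span_lox[wi]), int(span_nolox[wi]), w.truncated))
    df = pd.DataFrame(rows, columns=[
        "locus", "side", "chrom", "start", "end",
        "depth_total", "depth_lox", "depth_nolox",
        "n_span_lox", "n_span_nolox", "truncated"])
    logger.info("compute_flank_depth: %d windows, mean depth %.1f",
                len(df), df["depth_total"].mean())
    return df


# ---------------------------------------------------------------------------
# iterative copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyNumberCall:
    locus: str
    side: str
    cn: int
    rel_depth: float  # ploidy-scaled depth ratio the call was rounded from
    low_confidence: bool


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def iterative_cnv(
    sample: pd.DataFrame,
    parent: pd.DataFrame,
    ploidy: int = 2,
    max_iter: int = 20,
    tol: float = 0.01,
    conf_band: float = 0.35,
) -> list[CopyNumberCall]:
    """Integer copy number per flank window by iterative median re-scaling.

    The sample/parent depth ratio ``r`` of each window is scaled by ``s``
    (initially the median ratio) and rounded to ``CN = round(ploidy*r/s)``;
    ``s`` is then re-estimated as the median ratio over windows currently at
    ``CN == ploidy``, until assignments are stable, ``s`` moves less than
    ``tol``, or ``max_iter`` rounds.  Calls more than ``conf_band`` away from
    their integer are flagged low-confidence.
    """
    key = ["locus", "side"]
    merged = sample.merge(parent, on=key, suffixes=("_s", "_p"))
    usable = merged[merged["depth_total_p"] > 0].copy()
    if usable.empty:
        raise ValueError("no usable windows: parent depth is zero everywhere")
    r = (usable["depth_total_s"] / usable["depth_total_p"]).to_numpy()
    s = float(np.median(r))
    if s <= 0:
        s = max(float(np.mean(r)), 1e-9)
    cn = np.array([_round_half_away(x) for x in ploidy * r / s])
    for _ in range(max_iter):
        anchor = r[cn == ploidy]
        if len(anchor) == 0:
            logger.warning("iterative_cnv: no window at CN=%d; falling back "
                           "to global median scale", ploidy)
            s_new = float(np.median(r))
        else:
            s_new = float(np.median(anchor))
        cn_new = np.array([_round_half_away(x) for x in ploidy * r / s_new])
        stable = np.array_equal(cn_new, cn) and abs(s_new - s) <= tol * max(s, 1e-9)
        s, cn = s_new, cn_new
        if stable:
            break
    rel = ploidy * r / s
    calls = [
        CopyNumberCall(row.locus, row.side, int(c), float(x),
                       bool(abs(x - c) > conf_band))
        for row, c, x in zip(usable.itertuples(index=False), cn, rel)
    ]
    # windows with zero parent depth are uncallable; report CN -1? exclude.
    n_var = sum(1 for c in calls if c.cn != ploidy)
    logger.info("iterative_cnv: %d windows, %d deviate from ploidy %d (scale %.3f)",
                len(calls), n_var, ploidy, s)
    return calls


def cnv_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "locus": [c.locus for c in calls],
        "side": [c.side for c in calls],
        "cn": [c.cn for c in calls],
        "rel_depth": [c.rel_depth for c in calls],
        "low_confidence": [c.low_confidence for c in calls],
    })


# ---------------------------------------------------------------------------
# lox presence / LOH states
# ---------------------------------------------------------------------------

LOX_STATES = ("intact_lox", "wildtype_only", "lox_lost", "rearranged", "absent")


@dataclass(frozen=True)
class LoxStatusCall:
    locus: str
    state: str
    cn_up: int
    cn_down: int
    n_span_lox: int
    junction_ids: tuple[str, ...] = ()
    low_confidence: bool = False


def call_lox_status(
    cn_calls: Sequence[CopyNumberCall],
    depth: pd.DataFrame,
    counts: CountsTable,
    calls: Sequence[JunctionCall],
    parent_lox_loci: set[str] | None = None,
    min_junction_support: int = 2,
) -> list[LoxStatusCall]:
    """Assign each locus a lox presence state.

    Priority: absent (CN 0 on both flanks) > rearranged (supported novel
    junction touches the locus) > lox_lost (parent carried lox, no read
    spans the motif with a lox, flank depth persists — the LOH signal) >
    wildtype_only (parent lox-free here) > intact_lox.
    """
    cn_by_region = {(c.locus, c.side): c.cn for c in cn_calls}
    loci = sorted({c.locus for c in cn_calls})
    if parent_lox_loci is None:
        parent_lox_loci = set(loci)
    span_lox = depth.groupby("locus")["n_span_lox"].sum().to_dict()

    support: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.cls == "novel" and c.ends is not None:
            for end in c.ends:
                support.setdefault(end[0], {})
                support[end[0]][c.junction_id] = \
                    support[end[0]].get(c.junction_id, 0) + 1

    out = []
    for locus in loci:
        cn_up = cn_by_region.get((locus, "up"), 0)
        cn_down = cn_by_region.get((locus, "down"), 0)
        n_lox = int(span_lox.get(locus, 0))
        juncs = tuple(sorted(
            j for j, n in support.get(locus, {}).items()
            if n >= min_junction_support))
        if cn_up == 0 and cn_down == 0 and not juncs:
            state, low = "absent", False
        elif juncs:
            state = "rearranged"
            low = cn_up == 0 and cn_down == 0
        elif locus in parent_lox_loci and n_lox == 0 and (cn_up > 0 or cn_down > 0):
            state, low = "lox_lost", False
        elif locus not in parent_lox_loci:
            state, low = "wildtype_only", False
        else:
            state, low = "intact_lox", False
        out.append(LoxStatusCall(locus, state, cn_up, cn_down, n_lox, juncs, low))
    return out


# ---------------------------------------------------------------------------
# SV hypotheses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVHypothesis:
    kind: str
    loci: tuple[str, ...]
    junction_ids: tuple[str, ...]
    cn_evidence: tuple[str, ...]
    note: str = ""


def infer_sv_hypotheses(
    cn_calls: Sequence[CopyNumberCall],
    counts: CountsTable,
    calls: Sequence[JunctionCall],
    sites: LoxSiteTable,
    ploidy: int = 2,
    min_junction_support: int = 2,
) -> list[SVHypothesis]:
    """Combine junction calls with flank copy-number asymmetries into
    structural-variant hypotheses.

    Rules: a uniform chromosome-wide CN shift is aneuploidy; a supported
    novel junction with balanced CN at all four flank regions (its reciprocal
    partner junction present) is a reciprocal translocation; a junction with
    both a gained and a lost flank region is non-reciprocal; gained only is a
    duplication insertion; an intra-chromosomal up/down junction with reduced
    or lost interior is a deletion.
    """
    cn = {(c.locus, c.side): c.cn for c in cn_calls}
    chrom_of = {s.site_id: s.chrom for s in sites}
    pos_of = {s.site_id: s.position for s in sites}
    out: list[SVHypothesis] = []

    # aneuploidy: every region of a chromosome shifted uniformly
    by_chrom: dict[str, list[int]] = {}
    for c in cn_calls:
        by_chrom.setdefault(chrom_of.get(c.locus, "?"), []).append(c.cn)
    aneuploid = set()
    for chrom, cns in sorted(by_chrom.items()):
        if len(cns) >= 2 and len(set(cns)) == 1 and cns[0] != ploidy:
            kind = "chromosome_gain" if cns[0] > ploidy else "chromosome_loss"
            loci = tuple(sorted(s.site_id for s in sites.on_chrom(chrom)))
            out.append(SVHypothesis(kind, loci, (), (f"{chrom}:CN={cns[0]}",),
                                    note=f"uniform CN {cns[0]} across {chrom}"))
            aneuploid.add(chrom)

    # supported novel junctions grouped by locus pair
    support: dict = {}
    jid_ends: dict = {}
    for c in calls:
        if c.cls == "novel" and c.ends is not None:
            support[c.junction_id] = support.get(c.junction_id, 0) + 1
            jid_ends[c.junction_id] = c.ends
    by_pair: dict[frozenset, list[str]] = {}
    for jid, n in support.items():
        if n < min_junction_support:
            continue
        ends = jid_ends[jid]
        pair = frozenset(e[0] for e in ends)
        if len(pair) == 2:
            by_pair.setdefault(pair, []).append(jid)

    side_region = {"u": "up", "d": "down"}
    for pair, jids in sorted(by_pair.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        if chrom_of.get(a) in aneuploid or chrom_of.get(b) in aneuploid:
            continue
        regions = [(a, "up"), (a, "down"), (b, "up"), (b, "down")]
        cns = {r: cn.get(r, ploidy) for r in regions}
        gained = [r for r, c in cns.items() if c > ploidy]
        lost = [r for r, c in cns.items() if c < ploidy]
        ev = tuple(f"{l}-{s}:CN={c}" for (l, s), c in sorted(cns.items()))
        jids = sorted(jids)
        intra = chrom_of.get(a) == chrom_of.get(b)
        # deletion: intra junction joining the outer flanks across a lost interior
        is_del = False
        if intra:
            left, right = (a, b) if pos_of[a] < pos_of[b] else (b, a)
            del_ends = frozenset(((left, "u"), (right, "d")))
            if any(jid_ends[j] == del_ends for j in jids) and (
                    cns[(left, "down")] < ploidy or cns[(right, "up")] < ploidy):
                is_del = True
        if is_del:
            out.append(SVHypothesis("deletion", (a, b), tuple(jids), ev,
                                    note="interior flank depth reduced"))
        elif gained and lost:
            out.append(SVHypothesis("non_reciprocal_translocation", (a, b),
                                    tuple(jids), ev))
        elif gained:
            out.append(SVHypothesis("duplication_insertion", (a, b),
                                    tuple(jids), ev))
        elif not lost and len(jids) >= 2:
            out.append(SVHypothesis("reciprocal_translocation", (a, b),
                                    tuple(jids), ev))
        elif not intra:
            out.append(SVHypothesis("non_reciprocal_translocation", (a, b),
                                    tuple(jids), ev,
                                    note="single junction, CN balanced"))
    return out


def hypotheses_to_json(hyps: Sequence[SVHypothesis]) -> list[dict]:
    return [
        {"kind": h.kind, "loci": list(h.loci), "junctions": list(h.junction_ids),
         "cn_evidence": list(h.cn_evidence), "note": h.note}
        for h in hyps
    ]
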