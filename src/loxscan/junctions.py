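"""In-silico junction reference pool and classification of loxPsym-bearing
long reads.

Every distinct lox locus ``i`` contributes an upstream flank ``U_i`` (the
``flank_len`` bases ending just before the motif) and a downstream flank
``D_i`` (the bases starting just after it).  The reference pool holds the
parental junction ``U_i + lox + D_i`` for every locus plus, for every locus
pair ``(i, j)``, the four possible recombinant junctions — the end pairs
``{u_i,d_j}``, ``{d_i,u_j}``, ``{u_i,u_j}`` and ``{d_i,d_j}``.  Because the
motif is palindromic, a junction sequence and its reverse complement denote
the same entry, and reads need only be scanned on the forward strand.

Classification scores the context around each motif occurrence in a read
against every pool entry (per-flank anchored alignment, affine scoring) and
emits a call only when the best entry clears the runner-up by a score margin
and both flanks are sufficiently covered.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .io_core import (
    GenomeModel,
    LoxSiteTable,
    PipelineConfig,
    LOXPSYM_SEQ,
    logger,
    revcomp,
)
from .simulate import End, Junction, LOX_LEN, SimRead, junction_of

UNCLASSIFIED = "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# flank library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Flank:
    locus: str
    chrom: str
    position: int
    up: str
    down: str
    up_truncated: bool
    down_truncated: bool
    usable: bool


class FlankLibrary:
    """Per-locus up/down flank sequences at a fixed flank length."""

    def __init__(self, flanks: Sequence[Flank], flank_len: int, min_flank: int):
        self.flank_len = flank_len
        self.min_flank = min_flank
        self._flanks = {f.locus: f for f in flanks}
        self.loci = [f.locus for f in flanks]
        self.usable_loci = [f.locus for f in flanks if f.usable]

    def __getitem__(self, locus: str) -> Flank:
        return self._flanks[locus]

    def __iter__(self):
        return iter(self._flanks.values())

    def left_seq(self, end: End) -> str:
        """Sequence entering the motif when ``end`` is the left side."""
        f = self._flanks[end[0]]
        return f.up if end[1] == "u" else revcomp(f.down)

    def right_seq(self, end: End) -> str:
        """Sequence leaving the motif when ``end`` is the right side."""
        f = self._flanks[end[0]]
        return f.down if end[1] == "d" else revcomp(f.up)


def extract_flanks(
    genome: GenomeModel,
    sites: LoxSiteTable,
    flank_len: int = 1000,
    min_flank: int = 200,
    lox_len: int = LOX_LEN,
) -> FlankLibrary:
    """Extract up/down flanks around every distinct lox locus.

    Co-located multi-copy sites are a single locus (one table row).  Loci
    whose flanks are both shorter than ``min_flank`` (chromosome-end
    truncation) are flagged unusable and excluded from the pool.
    """
    flanks = []
    for s in sites:
        chrom = genome.get(s.chrom)
        up = chrom.sequence[max(0, s.position - flank_len): s.position]
        down = chrom.sequence[s.position + lox_len: s.position + lox_len + flank_len]
        usable = len(up) >= min_flank and len(down) >= min_flank
        if not usable:
            logger.warning("extract_flanks: locus %s unusable (flanks %d/%d bp)",
                           s.site_id, len(up), len(down))
        flanks.append(Flank(
            s.site_id, s.chrom, s.position, up, down,
            up_truncated=len(up) < flank_len,
            down_truncated=len(down) < flank_len,
            usable=usable,
        ))
    return FlankLibrary(flanks, flank_len, min_flank)


# ---------------------------------------------------------------------------
# junction pool
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolEntry:
    junction_id: str
    end_a: End
    end_b: End
    seq: str
    cls: str  # 'normal' | 'novel'

    @property
    def ends(self) -> Junction:
        return junction_of(self.end_a, self.end_b)


class JunctionPool:
    """All parental + pairwise recombinant junction references."""

    def __init__(self, entries: Sequence[PoolEntry], lox_seq: str, flank_len: int):
        self.entries = list(entries)
        self.lox_seq = lox_seq
        self.flank_len = flank_len
        self._by_ends = {e.ends: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def by_ends(self, ends: Junction) -> PoolEntry:
        return self._by_ends[ends]

    def n_site_pairs(self) -> int:
        """Distinct locus pairs represented among novel entries."""
        pairs = {
            frozenset((e.end_a[0], e.end_b[0]))
            for e in self.entries if e.cls == "novel"
        }
        return sum(1 for p in pairs if len(p) == 2)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                hdr = (f"{e.junction_id}|{e.end_a[0]}:{e.end_a[1]}|"
                       f"{e.end_b[0]}:{e.end_b[1]}|{e.cls}")
                fh.write(f">{hdr}\n{e.seq}\n")


def pool_accounting(sites: LoxSiteTable) -> dict:
    """Pool and pair-count arithmetic from a site table alone.

    Returns locus counts, pool entry counts (L normal + 4*C(L,2) novel) and
    the analytic intra/inter-chromosomal pair split used as the null
    expectation when recombination has no intra/inter preference.
    """
    L = sites.n_loci()
    per_chrom = {c: len(sites.on_chrom(c)) for c in sites.chroms}
    n_pairs = L * (L - 1) // 2
    intra = sum(n * (n - 1) // 2 for n in per_chrom.values())
    return {
        "n_sites": sites.n_sites(),
        "n_loci": L,
        "n_pairs": n_pairs,
        "n_intra_pairs": intra,
        "n_inter_pairs": n_pairs - intra,
        "n_pool_entries": L + 4 * n_pairs,
        "intra_fraction": intra / n_pairs if n_pairs else float("nan"),
    }


def build_junction_pool(
    flanks: FlankLibrary,
    lox_seq: str = LOXPSYM_SEQ,
    include_self_pairs: bool = False,
) -> JunctionPool:
    """Assemble the junction reference pool from a flank library.

    For ``L`` usable loci the pool holds ``L`` normal entries and
    ``4*C(L,2)`` novel entries (plus ``2L`` self-pair foldback entries when
    ``include_self_pairs`` is set).  Entry ids are deterministic, sorted by
    end tuple in library locus order.
    """
    loci = flanks.usable_loci
    if len(loci) < 2:
        raise ValueError(f"need >= 2 usable loci, have {len(loci)}")
    order = {loc: k for k, loc in enumerate(loci)}
    entries = []

    def make(end_a: End, end_b: End, cls: str) -> PoolEntry:
        # canonical orientation: lower (locus order, side) end on the left
        key = lambda e: (order[e[0]], e[1])
        a, b = sorted((end_a, end_b), key=key)
        seq = flanks.left_seq(a) + lox_seq + flanks.right_seq(b)
        jid = f"{a[0]}.{a[1]}--{b[0]}.{b[1]}"
        return PoolEntry(jid, a, b, seq, cls)

    for loc in loci:
        entries.append(make((loc, "u"), (loc, "d"), "normal"))
    for i, li in enumerate(loci):
        for lj in loci[i + 1:]:
            entries.append(make((li, "u"), (lj, "d"), "novel"))
            entries.append(make((li, "d"), (lj, "u"), "novel"))
            entries.append(make((li, "u"), (lj, "u"), "novel"))
            entries.append(make((li, "d"), (lj, "d"), "novel"))
    if include_self_pairs:
        for loc in loci:
            entries.append(make((loc, "u"), (loc, "u"), "novel"))
            entries.append(make((loc, "d"), (loc, "d"), "novel"))
    logger.info("build_junction_pool: %d loci -> %d entries", len(loci), len(entries))
    return JunctionPool(entries, lox_seq, flanks.flank_len)


# ---------------------------------------------------------------------------
# lox scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoxReadHit:
    read_id: str
    occurrence: int
    start: int  # 0-based, inclusive
    end: int    # 0-based, inclusive (edlib convention)
    edits: int


def scan_lox_reads(
    reads: Iterable[SimRead | tuple[str, str]],
    lox_seq: str = LOXPSYM_SEQ,
    max_lox_edits: int = 3,
) -> list[LoxReadHit]:
    """Find all non-overlapping approximate lox occurrences in each read.

    Occurrences are reported best-first by iterated infix search with
    masking; the motif's palindromy makes reverse-strand scanning redundant.
    """
    if lox_seq != revcomp(lox_seq):
        raise ValueError("lox_seq must be palindromic")
    hits: list[LoxReadHit] = []
    for read in reads:
        rid, seq = (read.read_id, read.sequence) if isinstance(read, SimRead) else read
        found: list[tuple[int, int, int]] = []
        work = seq
        while True:
            res = edlib.align(lox_seq, work, mode="HW", task="locations",
                              k=max_lox_edits)
            if res["editDistance"] < 0:
                break
            ed = res["editDistance"]
            placed = False
            for s, e in sorted(res["locations"]):
                if any(s <= fe and fs <= e for fs, fe, _ in found):
                    continue
                found.append((s, e, ed))
                work = work[:s] + "#" * (e - s + 1) + work[e + 1:]
                placed = True
            if not placed:
                break
        found.sort()
        for k, (s, e, ed) in enumerate(found):
            hits.append(LoxReadHit(rid, k, s, e, ed))
    logger.info("scan_lox_reads: %d occurrences", len(hits))
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    occurrence: int
    junction_id: str  # pool entry id or UNCLASSIFIED
    ends: Junction | None
    cls: str | None   # 'normal' | 'novel' | None
    score: float
    margin: float
    cov_left: float
    cov_right: float
    reason: str = ""


@dataclass
class CountsTable:
    """Per-locus normal/rearranged counts and per-pair rearranged counts.

    ``Nall_i = 2*Nnorm_i + Nre_i`` is the site's effective junction
    observation depth: a normal read covers both flanks of one locus while a
    rearranged read covers one flank each of two loci.
    """

    loci: list[str]
    nnorm: dict = field(default_factory=dict)
    nre: dict = field(default_factory=dict)
    nre_pair: dict = field(default_factory=dict)  # frozenset{i,j} -> count

    @classmethod
    def empty(cls, loci: Sequence[str]) -> "CountsTable":
        return cls(list(loci), {l: 0 for l in loci}, {l: 0 for l in loci}, {})

    def nall(self, locus: str) -> int:
        return 2 * self.nnorm.get(locus, 0) + self.nre.get(locus, 0)

    def add_normal(self, locus: str) -> None:
        self.nnorm[locus] = self.nnorm.get(locus, 0) + 1

    def add_novel(self, locus_a: str, locus_b: str) -> None:
        self.nre[locus_a] = self.nre.get(locus_a, 0) + 1
        self.nre[locus_b] = self.nre.get(locus_b, 0) + 1
        pair = frozenset((locus_a, locus_b))
        self.nre_pair[pair] = self.nre_pair.get(pair, 0) + 1

    def scaled(self, factor: float) -> "CountsTable":
        return CountsTable(
            list(self.loci),
            {k: v * factor for k, v in self.nnorm.items()},
            {k: v * factor for k, v in self.nre.items()},
            {k: v * factor for k, v in self.nre_pair.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_id": self.loci,
            "n_norm": [self.nnorm.get(l, 0) for l in self.loci],
            "n_re": [self.nre.get(l, 0) for l in self.loci],
            "n_all": [self.nall(l) for l in self.loci],
        })

    def pair_frame(self) -> pd.DataFrame:
        rows = []
        for pair, n in self.nre_pair.items():
            a, b = sorted(pair) if len(pair) == 2 else (min(pair), min(pair))
            rows.append((a, b, n))
        rows.sort()
        return pd.DataFrame(rows, columns=["locus_a", "locus_b", "n_re"])


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def affine_score(cigar: str, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -1.0) -> float:
    """Affine alignment score recomputed from an edlib extended CIGAR."""
    score = 0.0
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op == "=":
            score += match * n
        elif op in ("X", "M"):
            score += mismatch * n
        else:  # I or D: one gap of length n
            score += gap_open + gap_extend * (n - 1)
    return score


def _anchored_side_score(ctx: str, ref: str, flank_len: int) -> tuple[float, float]:
    """Score a read context against a reference flank, both anchored at the
    motif boundary (index 0 side).  Returns (affine score, flank coverage)."""
    if not ctx or not ref:
        return -math.inf, 0.0
    q = ctx[: len(ref)]
    res = edlib.align(q, ref, mode="SHW", task="path")
    span = res["locations"][0][1] + 1
    cov = span / min(flank_len, len(ref))
    return affine_score(res["cigar"]), cov


def classify_junctions(
    hits: Sequence[LoxReadHit],
    reads: Mapping[str, str] | Iterable[SimRead | tuple[str, str]],
    flanks: FlankLibrary,
    pool: JunctionPool,
    config: PipelineConfig | None = None,
) -> tuple[list[JunctionCall], CountsTable]:
    """Classify each lox occurrence against the junction pool.

    For every occurrence the read context on each side (up to ``flank_len``
    bases, motif excluded) is scored against each locus flank in both
    left/right roles; a pool entry's score is the best of its two possible
    orientations.  A call is emitted when the best entry leads the runner-up
    by ``min_score_margin`` and both flank coverages reach ``min_flank_cov``;
    ties and occurrences too close to a read end are UNCLASSIFIED.
    """
    config = config or PipelineConfig(flank_len=flanks.flank_len)
    if not isinstance(reads, Mapping):
        reads = {
            (r.read_id if isinstance(r, SimRead) else r[0]):
            (r.sequence if isinstance(r, SimRead) else r[1])
            for r in reads
        }
    flank_len = flanks.flank_len
    min_ctx = config.min_flank_cov * flank_len
    calls: list[JunctionCall] = []
    counts = CountsTable.empty(flanks.usable_loci)
    loci = flanks.usable_loci

    # anchored reference flanks, oriented so index 0 touches the motif
    left_ref = {}   # end used as left side: reversed sequence
    right_ref = {}  # end used as right side: forward sequence
    for loc in loci:
        f = flanks[loc]
        left_ref[(loc, "u")] = f.up[::-1]
        left_ref[(loc, "d")] = revcomp(f.down)[::-1]
        right_ref[(loc, "d")] = f.down
        right_ref[(loc, "u")] = revcomp(f.up)

    for hit in hits:
        seq = reads[hit.read_id]
        lctx = seq[max(0, hit.start - flank_len): hit.start][::-1]
        rctx = seq[hit.end + 1: hit.end + 1 + flank_len]
        if len(lctx) < min_ctx or len(rctx) < min_ctx:
            calls.append(JunctionCall(hit.read_id, hit.occurrence, UNCLASSIFIED,
                                      None, None, -math.inf, 0.0, 0.0, 0.0,
                                      reason="near_read_end"))
            continue
        ls = {e: _anchored_side_score(lctx, ref, flank_len)
              for e, ref in left_ref.items()}
        rs = {e: _anchored_side_score(rctx, ref, flank_len)
              for e, ref in right_ref.items()}
        best = runner = None
        best_entry = None
        best_cov = (0.0, 0.0)
        for entry in pool.entries:
            s1 = ls[entry.end_a][0] + rs[entry.end_b][0]
            s2 = ls[entry.end_b][0] + rs[entry.end_a][0]
            if s1 >= s2:
                s, covs = s1, (ls[entry.end_a][1], rs[entry.end_b][1])
            else:
                s, covs = s2, (ls[entry.end_b][1], rs[entry.end_a][1])
            if best is None or s > best:
                runner = best
                best, best_entry, best_cov = s, entry, covs
            elif runner is None or s > runner:
                runner = s
        margin = best - runner if runner is not None else math.inf
        cov_l, cov_r = best_cov
        if margin < config.min_score_margin:
            calls.append(JunctionCall(hit.read_id, hit.occurrence, UNCLASSIFIED,
                                      None, None, best, margin, cov_l, cov_r,
                                      reason="ambiguous"))
            continue
        if cov_l < config.min_flank_cov or cov_r < config.min_flank_cov:
            calls.append(JunctionCall(hit.read_id, hit.occurrence, UNCLASSIFIED,
                                      None, None, best, margin, cov_l, cov_r,
                                      reason="low_flank_coverage"))
            continue
        calls.append(JunctionCall(hit.read_id, hit.occurrence,
                                  best_entry.junction_id, best_entry.ends,
                                  best_entry.cls, best, margin, cov_l, cov_r))
        if best_entry.cls == "normal":
            counts.add_normal(best_entry.end_a[0])
        else:
            counts.add_novel(best_entry.end_a[0], best_entry.end_b[0])
    n_called = sum(1 for c in calls if c.junction_id != UNCLASSIFIED)
    logger.info("classify_junctions: %d/%d occurrences called", n_called, len(calls))
    return calls, counts


def calls_to_frame(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "read_id": [c.read_id for c in calls],
        "occurrence": [c.occurrence for c in calls],
        "junction_id": [c.junction_id for c in calls],
        "class": [c.cls or "" for c in calls],
        "score": [c.score for c in calls],
        "margin": [c.margin for c in calls],
        "cov_left": [c.cov_left for c in calls],
        "cov_right": [c.cov_right for c in calls],
        "reason": [c.reason for c in calls],
    })


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

def detected_junction_set(counts: CountsTable, calls: Sequence[JunctionCall],
                          min_support: int = 2) -> set:
    """Novel end-pair junctions supported by at least ``min_support`` calls."""
    support: dict[Junction, int] = {}
    for c in calls:
        if c.cls == "novel" and c.ends is not None:
            support[c.ends] = support.get(c.ends, 0) + 1
    return {j for j, n in support.items() if n >= min_support}


def junction_recovery(detected: set, truth: set) -> dict:
    """Event-level precision/recall of detected novel junctions vs truth."""
    tp = len(detected & truth)
    precision = tp / len(detected) if detected else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {"tp": tp, "n_detected": len(detected), "n_truth": len(truth),
            "precision": precision, "recall": recall}
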