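"""Segment-level deconvolution of a rearranged lox-bearing chromosome.

The parental chromosome is cut at its lox sites into ordered segments
1..N (each with a *head* end, left in parental orientation, and a *tail*
end).  Reads are first partitioned by marker sequences distinguishing the
engineered chromosome from its wild-type homolog; lox junction observations
are then translated into segment-end adjacencies, and an
alternation-constrained Eulerian traversal of the segment-end multigraph
recovers every arrangement (order, orientation, linear/circular topology)
consistent with the observed junctions and the supplied segment copy
numbers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io_core import GenomeModel, LoxSiteTable, PipelineConfig, logger, revcomp
from .junctions import (
    JunctionCall,
    build_junction_pool,
    classify_junctions,
    extract_flanks,
    scan_lox_reads,
    UNCLASSIFIED,
)
from .simulate import LOX_LEN, SimRead

SegEnd = tuple[int, str]  # (segment_id, 'head' | 'tail')
Edge = tuple[SegEnd, SegEnd]  # sorted pair


def edge_of(a: SegEnd, b: SegEnd) -> Edge:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# segment map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    segment_id: int
    start: int  # on the parental chromosome, 0-based half-open, lox excluded
    end: int
    sequence: str


class SegmentMap:
    """Parental segments between adjacent lox sites of one chromosome.

    Segment k runs from the end of lox k-1 (or the left telomere) to the
    start of lox k (or the right telomere); concatenating segments with the
    motif between them reproduces the parental chromosome.
    """

    def __init__(self, segments: Sequence[Segment], chrom: str,
                 site_ids: Sequence[str]):
        self.segments = list(segments)
        self.chrom = chrom
        self.site_ids = list(site_ids)  # site k sits between segment k and k+1

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_parent(cls, genome: GenomeModel, chrom: str,
                    sites: LoxSiteTable) -> "SegmentMap":
        seq = genome.get(chrom).sequence
        ss = sites.on_chrom(chrom)
        segments = []
        prev = 0
        for k, s in enumerate(ss, start=1):
            segments.append(Segment(k, prev, s.position, seq[prev: s.position]))
            prev = s.position + LOX_LEN
        segments.append(Segment(len(ss) + 1, prev, len(seq), seq[prev:]))
        return cls(segments, chrom, [s.site_id for s in ss])

    def end_of_site(self, site_id: str, side: str) -> SegEnd:
        """Map a lox junction end to a segment end: site k's upstream flank
        is segment k's tail; its downstream flank is segment k+1's head."""
        k = self.site_ids.index(site_id) + 1
        return (k, "tail") if side == "u" else (k + 1, "head")

    def parental_edges(self) -> list[Edge]:
        return [edge_of((k, "tail"), (k + 1, "head"))
                for k in range(1, len(self.segments))]


# ---------------------------------------------------------------------------
# marker partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    marker_id: str
    variant: str  # 'synthetic' | 'wildtype'
    sequence: str
    segment_id: int


class MarkerTable:
    def __init__(self, markers: Sequence[Marker]):
        seqs = [m.sequence for m in markers]
        if len(set(seqs)) != len(seqs):
            raise ValueError("marker sequences must be unique")
        for m in markers:
            if len(m.sequence) < 15:
                raise ValueError(f"marker {m.marker_id} shorter than 15 bp")
        self.markers = list(markers)

    def by_variant(self, variant: str) -> list[Marker]:
        return [m for m in self.markers if m.variant == variant]


def make_marker_table(
    segment_map: SegmentMap, genome: GenomeModel, n_per_segment: int = 2,
    length: int = 28, seed: int = 0,
) -> tuple[MarkerTable, str]:
    """Plant marker pairs in each segment and return the marker table plus
    the wild-type homolog sequence (parental chromosome with every marker
    recoded and no lox motifs).

    The synthetic variant of a marker is the parental substring; the
    wild-type variant differs at roughly every third base, far beyond any
    sensible matching edit budget.
    """
    rng = np.random.default_rng(seed)
    markers: list[Marker] = []
    replacements: list[tuple[int, int, str]] = []  # parent coords
    for seg in segment_map.segments:
        if len(seg.sequence) < 3 * length:
            continue
        # markers evenly spaced through the segment, like recoded tags
        offs = np.linspace(length, len(seg.sequence) - 2 * length,
                           n_per_segment).astype(int)
        for i, off in enumerate(sorted(set(int(o) for o in offs))):
            syn = seg.sequence[off: off + length]
            wt = list(syn)
            for p in range(0, length, 3):
                alts = [b for b in "ACGT" if b != wt[p]]
                wt[p] = alts[int(rng.integers(0, 3))]
            wt = "".join(wt)
            mid = f"M{seg.segment_id}.{i + 1}"
            markers.append(Marker(mid, "synthetic", syn, seg.segment_id))
            markers.append(Marker(f"{mid}w", "wildtype", wt, seg.segment_id))
            replacements.append((seg.start + off, seg.start + off + length, wt))
    # wild-type homolog: parent sequence, markers recoded, lox motifs removed
    parent = genome.get(segment_map.chrom).sequence
    out = []
    prev = 0
    cuts = sorted(
        [(s, e, rep) for s, e, rep in replacements]
        + [(seg.end, seg.end + LOX_LEN, "") for seg in segment_map.segments[:-1]]
    )
    for s, e, rep in cuts:
        out.append(parent[prev:s])
        out.append(rep)
        prev = e
    out.append(parent[prev:])
    return MarkerTable(markers), "".join(out)


def partition_reads_by_markers(
    reads: Iterable[SimRead | tuple[str, str]],
    markers: MarkerTable,
    max_edits: int = 2,
) -> dict[str, list]:
    """Assign each read to 'synthetic' or 'wildtype' by majority of marker
    hits (approximate match within ``max_edits`` on either strand); ties and
    zero-hit reads go to 'unassigned'."""
    groups: dict[str, list] = {"synthetic": [], "wildtype": [], "unassigned": []}
    syn = [m.sequence for m in markers.by_variant("synthetic")]
    wt = [m.sequence for m in markers.by_variant("wildtype")]
    for read in reads:
        rid, seq = (read.read_id, read.sequence) if isinstance(read, SimRead) else read

        def n_hits(pats: list[str]) -> int:
            n = 0
            for p in pats:
                for q in (p, revcomp(p)):
                    if edlib.align(q, seq, mode="HW", k=max_edits)["editDistance"] >= 0:
                        n += 1
                        break
            return n

        ns, nw = n_hits(syn), n_hits(wt)
        if ns > nw:
            groups["synthetic"].append(read)
        elif nw > ns:
            groups["wildtype"].append(read)
        else:
            groups["unassigned"].append(read)
    logger.info("partition_reads_by_markers: %d syn / %d wt / %d unassigned",
                len(groups["synthetic"]), len(groups["wildtype"]),
                len(groups["unassigned"]))
    return groups


# ---------------------------------------------------------------------------
# junction observation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionObservation:
    end_a: SegEnd
    end_b: SegEnd
    support: int

    @property
    def edge(self) -> Edge:
        return edge_of(self.end_a, self.end_b)


def observe_junctions(
    reads: Iterable[SimRead | tuple[str, str]],
    segment_map: SegmentMap,
    genome: GenomeModel,
    sites: LoxSiteTable,
    config: PipelineConfig | None = None,
) -> tuple[list[JunctionObservation], list[JunctionCall]]:
    """Match each lox occurrence's two sides to segment ends.

    Returns accumulated segment-end adjacencies with read support, plus an
    unassigned report: occurrences that could not be matched to a junction
    of two segment ends (e.g. one side joined to non-segment sequence by
    homologous recombination).
    """
    config = config or PipelineConfig()
    reads = list(reads)
    chrom_sites = LoxSiteTable(sites.on_chrom(segment_map.chrom))
    flanks = extract_flanks(genome, chrom_sites, config.flank_len)
    pool = build_junction_pool(flanks, config.lox_seq, include_self_pairs=True)
    hits = scan_lox_reads(reads, config.lox_seq, config.max_lox_edits)
    calls, _counts = classify_junctions(hits, reads, flanks, pool, config)
    support: Counter = Counter()
    unassigned: list[JunctionCall] = []
    for c in calls:
        if c.junction_id == UNCLASSIFIED or c.ends is None:
            unassigned.append(c)
            continue
        ends = sorted(c.ends)
        if len(ends) == 1:
            ends = ends * 2
        (la, sa), (lb, sb) = ends
        e1 = segment_map.end_of_site(la, sa)
        e2 = segment_map.end_of_site(lb, sb)
        support[edge_of(e1, e2)] += 1
    obs = [JunctionObservation(e[0], e[1], n) for e, n in sorted(support.items())]
    logger.info("observe_junctions: %d distinct adjacencies, %d unassigned",
                len(obs), len(unassigned))
    return obs, unassigned


# ---------------------------------------------------------------------------
# arrangement reconstruction
# ---------------------------------------------------------------------------

Arrangement = tuple[tuple[int, str], ...]  # ((segment_id, '+'|'-'), ...)


@dataclass
class ArrangementResult:
    arrangement: Arrangement
    topology: str  # 'linear' | 'circular'
    alternatives: list[Arrangement] = field(default_factory=list)
    ambiguous: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "order_index": range(1, len(self.arrangement) + 1),
            "segment_id": [s for s, _ in self.arrangement],
            "orientation": [o for _, o in self.arrangement],
        })


class ReconstructionError(ValueError):
    """No Eulerian traversal consistent with the observations exists."""


def arrangement_edges(arr: Arrangement, topology: str) -> Counter:
    """Junction-edge multiset realised by an arrangement (the exhaustive-
    search oracle uses this too)."""
    edges: Counter = Counter()
    pairs = list(zip(arr, arr[1:]))
    if topology == "circular" and len(arr) > 0:
        pairs.append((arr[-1], arr[0]))
    for (s1, o1), (s2, o2) in pairs:
        exit_end = (s1, "tail" if o1 == "+" else "head")
        enter_end = (s2, "head" if o2 == "+" else "tail")
        edges[edge_of(exit_end, enter_end)] += 1
    return edges


def flip_arrangement(arr: Arrangement) -> Arrangement:
    return tuple((s, "+" if o == "-" else "-") for s, o in reversed(arr))


def canonical_arrangement(arr: Arrangement, topology: str,
                          anchor_segment: int | None = None) -> Arrangement:
    """Canonical form modulo global flip (and rotation when circular)."""
    def variants(a: Arrangement):
        for base in (a, flip_arrangement(a)):
            if topology == "circular":
                for r in range(len(base)):
                    yield base[r:] + base[:r]
            else:
                yield base

    cands = list(variants(arr))
    if anchor_segment is not None:
        anchored = [c for c in cands
                    if any(s == anchor_segment and o == "+" for s, o in c)]
        if anchored:
            cands = anchored
    return min(cands)


def reconstruct(
    observations: Sequence[JunctionObservation],
    copy_numbers: Mapping[int, int],
    support_threshold: int = 2,
    enumerate_cap: int = 16,
    anchor_segment: int | None = None,
) -> ArrangementResult:
    """Recover segment arrangements consistent with junction observations.

    Builds a multigraph whose nodes are segment ends: each of the
    ``copy_numbers[k]`` copies of segment k is an edge head(k)-tail(k) that
    must be traversed, and each accepted junction observation is an edge that
    must be traversed exactly once.  A valid chromosome is an Eulerian
    traversal alternating segment and junction edges — linear when it starts
    and ends with segment edges, circular when a junction edge closes it.
    Distinct traversals are enumerated deterministically up to
    ``enumerate_cap`` (modulo global flip / rotation); multiple solutions are
    flagged ambiguous; no solution raises ``ReconstructionError`` listing the
    end-degree imbalance.
    """
    edges: Counter = Counter()
    for ob in observations:
        if ob.support >= support_threshold:
            edges[ob.edge] += 1
    copies = {k: c for k, c in copy_numbers.items() if c > 0}
    n_copies = sum(copies.values())
    if n_copies == 0:
        raise ReconstructionError("no segment copies to arrange")
    n_edges = sum(edges.values())
    if n_edges not in (n_copies - 1, n_copies):
        raise ReconstructionError(
            f"{n_copies} segment copies cannot be joined by {n_edges} "
            f"junction edges (need {n_copies - 1} for a linear or "
            f"{n_copies} for a circular arrangement); "
            f"end degrees: {dict(_end_degrees(edges))}")
    circular = n_edges == n_copies

    solutions: list[tuple[Arrangement, str]] = []
    seen: set = set()

    def incident(end: SegEnd) -> list[Edge]:
        return sorted(e for e, n in edges.items() if n > 0 and end in e)

    def walk(path: list[tuple[int, str]], current_exit: SegEnd,
             remaining_edges: Counter, remaining_copies: Counter,
             start_enter: SegEnd) -> None:
        if len(seen) >= enumerate_cap:
            return
        if not remaining_copies.total():
            if not remaining_edges.total():
                arr = tuple(path)
                topo = "circular" if circular else "linear"
                canon = canonical_arrangement(arr, topo, anchor_segment)
                if canon not in seen:
                    seen.add(canon)
                    solutions.append((canon, topo))
            return
        for e in sorted(remaining_edges):
            if remaining_edges[e] <= 0 or current_exit not in e:
                continue
            a, b = e
            nxt = b if a == current_exit else a
            if a == b and a != current_exit:
                continue
            seg, enter = nxt
            if remaining_copies[seg] <= 0:
                continue
            orient = "+" if enter == "head" else "-"
            exit_end = (seg, "tail" if orient == "+" else "head")
            remaining_edges[e] -= 1
            remaining_copies[seg] -= 1
            path.append((seg, orient))
            walk(path, exit_end, remaining_edges, remaining_copies, start_enter)
            path.pop()
            remaining_edges[e] += 1
            remaining_copies[seg] += 1

    for seg in sorted(copies):
        for orient in ("+", "-"):
            enter = (seg, "head" if orient == "+" else "tail")
            exit_end = (seg, "tail" if orient == "+" else "head")
            rem_c = Counter(copies)
            rem_c[seg] -= 1
            if circular:
                # the closing edge back to `enter` is consumed last inside walk:
                # handle by requiring the final exit to connect to `enter`
                _walk_circ(path := [(seg, orient)], exit_end, Counter(edges),
                           rem_c, enter, solutions, seen, enumerate_cap,
                           anchor_segment)
            else:
                walk([(seg, orient)], exit_end, Counter(edges), rem_c, enter)

    if not solutions:
        raise ReconstructionError(
            f"no Eulerian traversal found; end degrees: "
            f"{dict(_end_degrees(edges))}, copies: {dict(copies)}")
    primary, topo = solutions[0]
    alts = [a for a, _ in solutions[1:]]
    logger.debug("reconstruct: %d solution(s), topology %s", len(solutions), topo)
    return ArrangementResult(primary, topo, alts, ambiguous=len(solutions) > 1)


def _walk_circ(path, current_exit, remaining_edges, remaining_copies,
               start_enter, solutions, seen, cap, anchor_segment):
    if len(seen) >= cap:
        return
    if not remaining_copies.total():
        # all copies placed: the single remaining edge must close the circle
        if remaining_edges.total() == 1:
            e = next(iter(remaining_edges.elements()))
            if e == edge_of(current_exit, start_enter):
                canon = canonical_arrangement(tuple(path), "circular",
                                              anchor_segment)
                if canon not in seen:
                    seen.add(canon)
                    solutions.append((canon, "circular"))
        return
    for e in sorted(remaining_edges):
        if remaining_edges[e] <= 0 or current_exit not in e:
            continue
        a, b = e
        nxt = b if a == current_exit else a
        if a == b and a != current_exit:
            continue
        seg, enter = nxt
        if remaining_copies[seg] <= 0:
            continue
        orient = "+" if enter == "head" else "-"
        exit_end = (seg, "tail" if orient == "+" else "head")
        remaining_edges[e] -= 1
        remaining_copies[seg] -= 1
        path.append((seg, orient))
        _walk_circ(path, exit_end, remaining_edges, remaining_copies,
                   start_enter, solutions, seen, cap, anchor_segment)
        path.pop()
        remaining_edges[e] += 1
        remaining_copies[seg] += 1


def _end_degrees(edges: Counter) -> Counter:
    deg: Counter = Counter()
    for (a, b), n in edges.items():
        deg[a] += n
        deg[b] += n if a != b else n
    return deg


def exhaustive_arrangements(
    observations: Sequence[JunctionObservation],
    copy_numbers: Mapping[int, int],
    topology: str,
    support_threshold: int = 1,
) -> set:
    """Brute-force oracle: all canonical signed orders of the segment copy
    multiset whose junction-edge multiset equals the observations.  Only
    feasible for small segment counts."""
    from itertools import permutations, product

    edges: Counter = Counter()
    for ob in observations:
        if ob.support >= support_threshold:
            edges[ob.edge] += 1
    pool: list[int] = []
    for k, c in sorted(copy_numbers.items()):
        pool.extend([k] * c)
    out = set()
    for perm in set(permutations(pool)):
        for orients in product("+-", repeat=len(pool)):
            arr = tuple(zip(perm, orients))
            if arrangement_edges(arr, topology) == edges:
                out.add(canonical_arrangement(arr, topology))
    return out
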