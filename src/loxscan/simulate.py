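"""Synthetic loxPsym genomes, Cre-mediated rearrangement events, and
error-bearing long-read simulation.

The generator is the pipeline's ground-truth source: every event it applies
records the novel lox junctions it creates, and the final genome state yields
the exact truth set (`EventLog.expected_junctions`) that detection results
are scored against.

Junction end notation: each parental lox locus ``i`` has an upstream flank
(end ``(i, 'u')``, sequence ending just before the motif on the forward
strand) and a downstream flank (end ``(i, 'd')``).  A junction is an
unordered pair of ends; the parental junction of locus ``i`` is
``{(i,'u'), (i,'d')}``.  Because the motif is palindromic a junction and its
reverse complement are the same object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import (
    Chromosome,
    GenomeModel,
    IntervalSet,
    LoxSite,
    LoxSiteTable,
    LOXPSYM_SEQ,
    logger,
    revcomp,
)

End = tuple[str, str]  # (locus_id, 'u' | 'd')
Junction = frozenset  # frozenset of End (size 1 for self-pairs)

LOX_LEN = len(LOXPSYM_SEQ)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class EventError(ValueError):
    """An event is invalid for the current genome state."""


def junction_of(end_a: End, end_b: End) -> Junction:
    return frozenset((end_a, end_b))


def is_parental(j: Junction) -> bool:
    ends = sorted(j)
    if len(ends) == 1:
        return False
    (la, sa), (lb, sb) = ends
    return la == lb and {sa, sb} == {"u", "d"}


# ---------------------------------------------------------------------------
# event and log types
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "deletion",
    "inversion",
    "duplication",
    "inverted_duplication",
    "translocation_reciprocal",
    "translocation_nonreciprocal",
    "circularization",
    "chrom_gain",
    "chrom_loss",
    "loh_conversion",
)


@dataclass
class SVEvent:
    """One rearrangement event.

    ``sites`` names one or two lox site_ids for Cre-mediated kinds; whole-
    chromosome and LOH kinds use ``chrom``/``interval`` (interval in the
    shared lox-free base coordinate system) instead.
    """

    kind: str
    sites: tuple[str, ...] = ()
    haplotype: str = "0"
    chrom: str | None = None
    interval: tuple[int, int] | None = None
    donor_haplotype: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventLog:
    """Ground truth for a simulated genome.

    ``expected_junctions`` is the set of novel junctions present in the final
    genome; ``per_event_junctions`` records what each event created when it
    was applied (later events may destroy earlier junctions, so the final set
    is the acceptance truth).  ``expected_losses`` lists loci whose lox motif
    was removed from a chromosome copy.
    """

    events: list[SVEvent] = field(default_factory=list)
    per_event_junctions: list[list[Junction]] = field(default_factory=list)
    expected_junctions: set = field(default_factory=set)
    expected_losses: list[tuple[str, str]] = field(default_factory=list)  # (locus, haplotype)

    def novel_pairs(self) -> set:
        """Distinct-locus novel junctions in the final genome (self-pairs and
        parental junctions excluded) as frozensets of ends."""
        out = set()
        for j in self.expected_junctions:
            if len(j) == 2 and not is_parental(j):
                out.add(j)
        return out

    def to_json(self, path: str | Path) -> None:
        def enc_j(j):
            return sorted([list(e) for e in j])

        data = {
            "events": [
                {
                    "kind": e.kind, "sites": list(e.sites), "haplotype": e.haplotype,
                    "chrom": e.chrom, "interval": list(e.interval) if e.interval else None,
                    "donor_haplotype": e.donor_haplotype, "params": e.params,
                }
                for e in self.events
            ],
            "per_event_junctions": [[enc_j(j) for j in js] for js in self.per_event_junctions],
            "expected_junctions": [enc_j(j) for j in sorted(self.expected_junctions, key=enc_j)],
            "expected_losses": [list(x) for x in self.expected_losses],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# toy genome construction
# ---------------------------------------------------------------------------

def make_toy_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc: float = 0.38,
    seed: int = 0,
    names: Sequence[str] | None = None,
    haplotype: str = "0",
) -> GenomeModel:
    """Random multi-chromosome genome with the given GC fraction."""
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if any(L <= 0 for L in lengths):
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if names is None:
        names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    chroms = []
    for name, L in zip(names, lengths):
        codes = rng.choice(4, size=L, p=p)
        seq = _BASES[codes].tobytes().decode()
        chroms.append(Chromosome(name=name, sequence=seq, haplotype=haplotype))
    return GenomeModel(chroms)


# ---------------------------------------------------------------------------
# sparse 83-site strain layout (synthetic stand-in for the engineered strain)
# ---------------------------------------------------------------------------

#: S. cerevisiae R64 chromosome lengths (bp).
YEAST_CHROM_LENGTHS = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 948066, "chrXVI": 924429,
}
# note: XV/XVI magnitudes are close; exact values matter only through the
# ~12 Mb total and the per-chromosome spans used below.
YEAST_CHROM_LENGTHS["chrXV"] = 1091291
YEAST_CHROM_LENGTHS["chrXVI"] = 948066

#: Distinct loxPsym loci per chromosome for the sparse 83-site layout
#: (synthetic layout: the deposited per-site coordinates are not shipped).
#: Chosen so that loci sum to 75, every site id named in published analyses
#: of the strain exists (II-8, IV-9, X-5, XII-8, XIII-7, ...), and the
#: intra-chromosomal pair count is sum_c C(n_c, 2) = 210 of C(75, 2) = 2775.
SPARSE_LOCI_PER_CHROM = {
    "chrI": 2, "chrII": 8, "chrIII": 2, "chrIV": 12, "chrV": 2, "chrVI": 2,
    "chrVII": 5, "chrVIII": 3, "chrIX": 2, "chrX": 5, "chrXI": 2,
    "chrXII": 9, "chrXIII": 8, "chrXIV": 3, "chrXV": 5, "chrXVI": 5,
}

#: Chromosomes whose first locus carries a second co-located lox copy
#: (8 extra copies bring 75 loci to 83 sites).
SPARSE_DOUBLE_COPY_CHROMS = (
    "chrI", "chrIII", "chrV", "chrVI", "chrVII", "chrIX", "chrXI", "chrXIV",
)

_SPARSE_MARGIN = 74_000  # bp kept lox-free at each chromosome end


def sparse_site_spec() -> list[tuple[str, str, int, int]]:
    """(site_id, chrom, base_position, copies) rows of the sparse layout.

    Positions are pre-insertion (lox-free base genome) coordinates, 0-based.
    Loci are evenly spaced between ~74 kb margins, which reproduces the
    strain's ~145 kb mean adjacent-site spacing.
    """
    rows = []
    for chrom, n in SPARSE_LOCI_PER_CHROM.items():
        L = YEAST_CHROM_LENGTHS[chrom]
        span = L - 2 * _SPARSE_MARGIN
        roman = chrom[3:]
        for k in range(n):
            pos = _SPARSE_MARGIN + round(k * span / (n - 1)) if n > 1 else L // 2
            copies = 2 if (k == 0 and chrom in SPARSE_DOUBLE_COPY_CHROMS) else 1
            rows.append((f"{roman}-{k + 1}", chrom, pos, copies))
    return rows


def sparse_strain_table() -> LoxSiteTable:
    """Site table of the sparse 83-site layout in post-insertion coordinates
    (one 34-bp motif spliced per locus), without building sequences."""
    sites = []
    for chrom in SPARSE_LOCI_PER_CHROM:
        rows = [r for r in sparse_site_spec() if r[1] == chrom]
        rows.sort(key=lambda r: r[2])
        for k, (sid, ch, pos, copies) in enumerate(rows):
            sites.append(LoxSite(sid, ch, pos + LOX_LEN * k, copies))
    return LoxSiteTable(sites)


def sparse_centromeres() -> dict[str, tuple[int, int]]:
    """Nominal mid-chromosome centromere intervals (0-based half-open) for
    the sparse layout; synthetic placement used for arm assignment only."""
    out = {}
    for chrom, L in YEAST_CHROM_LENGTHS.items():
        mid = L // 2
        out[chrom] = (mid - 60, mid + 60)
    return out


def make_sparse_strain(seed: int = 0, gc: float = 0.38) -> tuple[GenomeModel, LoxSiteTable]:
    """Build a random ~12 Mb genome carrying the sparse 83-site layout."""
    names = list(YEAST_CHROM_LENGTHS)
    genome = make_toy_genome(
        len(names), [YEAST_CHROM_LENGTHS[n] for n in names], gc=gc, seed=seed,
        names=names,
    )
    return insert_lox(genome, sparse_site_spec())


# ---------------------------------------------------------------------------
# lox insertion
# ---------------------------------------------------------------------------

def random_lox_spec(
    genome: GenomeModel,
    n_loci: int,
    min_per_chrom: int = 2,
    seed: int = 0,
    margin: int = 5000,
    min_gap: int = 20000,
) -> list[tuple[str, str, int, int]]:
    """Random insertion spec: ``n_loci`` loci, at least ``min_per_chrom`` per
    chromosome, pairwise gaps >= ``min_gap``."""
    rng = np.random.default_rng(seed)
    names = genome.names
    if n_loci < min_per_chrom * len(names):
        raise ValueError("n_loci too small for min_per_chrom")
    lens = np.array([len(genome.get(n)) for n in names], dtype=float)
    counts = {n: min_per_chrom for n in names}
    extra = n_loci - min_per_chrom * len(names)
    for _ in range(extra):
        counts[names[rng.choice(len(names), p=lens / lens.sum())]] += 1
    rows = []
    for name in names:
        L = len(genome.get(name))
        n = counts[name]
        lo, hi = margin, L - margin
        for attempt in range(1000):
            pos = np.sort(rng.integers(lo, hi, size=n))
            if n == 1 or np.diff(pos).min() >= min_gap:
                break
        else:
            raise ValueError(f"cannot place {n} loci on {name} with gap {min_gap}")
        roman = name.removeprefix("chr")
        for k, p in enumerate(pos):
            rows.append((f"{roman}-{k + 1}", name, int(p), 1))
    return rows


def insert_lox(
    genome: GenomeModel,
    spec: Iterable[tuple[str, str, int, int]],
    lox_seq: str = LOXPSYM_SEQ,
) -> tuple[GenomeModel, LoxSiteTable]:
    """Splice the lox motif at the given pre-insertion positions.

    Returns the modified genome and a site table whose coordinates refer to
    the post-insertion genome.  ``copies`` is carried through as locus
    multiplicity metadata (one motif is spliced per locus).
    """
    rows = sorted(spec, key=lambda r: (r[1], r[2]))
    by_chrom: dict[str, list] = {}
    for row in rows:
        by_chrom.setdefault(row[1], []).append(row)
    new_chroms = []
    sites = []
    for chrom in genome.chromosomes:
        todo = by_chrom.get(chrom.name, [])
        if not todo:
            new_chroms.append(chrom)
            continue
        parts = []
        prev = 0
        for k, (sid, _, pos, copies) in enumerate(todo):
            if not (0 <= pos <= len(chrom)):
                raise ValueError(f"site {sid}: position {pos} outside {chrom.name}")
            parts.append(chrom.sequence[prev:pos])
            parts.append(lox_seq)
            sites.append(LoxSite(sid, chrom.name, pos + LOX_LEN * k, copies))
            prev = pos
        parts.append(chrom.sequence[prev:])
        new_chroms.append(Chromosome(chrom.name, "".join(parts),
                                     chrom.topology, chrom.haplotype))
    table = LoxSiteTable(sites)
    logger.info("insert_lox: %d loci (%d sites) inserted", table.n_loci(), table.n_sites())
    return GenomeModel(new_chroms), table


# ---------------------------------------------------------------------------
# event engine
# ---------------------------------------------------------------------------

@dataclass
class _Occ:
    """A lox motif occurrence in a mutable chromosome state."""
    pos: int  # 0-based motif start in the current sequence
    left: End
    right: End
    base_pos: int | None = None  # pre-insertion coordinate; None once rearranged


@dataclass
class _ChromState:
    name: str
    haplotype: str
    seq: str
    occs: list  # of _Occ, sorted by pos
    topology: str = "linear"
    colinear: bool = True  # still colinear with the base coordinate system

    def sorted_occs(self) -> None:
        self.occs.sort(key=lambda o: o.pos)


class _SimGenome:
    """Mutable genome state used while applying events."""

    def __init__(self, genome: GenomeModel,
                 sites: LoxSiteTable | Mapping[str, LoxSiteTable] | None):
        self.states: list[_ChromState] = []
        for chrom in genome.chromosomes:
            if isinstance(sites, Mapping):
                table = sites.get(chrom.haplotype)
            else:
                table = sites
            occs = []
            if table is not None:
                for k, s in enumerate(table.on_chrom(chrom.name)):
                    occs.append(_Occ(
                        pos=s.position,
                        left=(s.site_id, "u"), right=(s.site_id, "d"),
                        base_pos=s.position - LOX_LEN * k,
                    ))
            self.states.append(_ChromState(
                chrom.name, chrom.haplotype, chrom.sequence, occs, chrom.topology))
        self.losses: list[tuple[str, str]] = []

    # -- lookup helpers ---------------------------------------------------
    def find_site(self, site_id: str, haplotype: str) -> tuple[_ChromState, _Occ]:
        for st in self.states:
            if st.haplotype != haplotype:
                continue
            for occ in st.occs:
                if site_id in (occ.left[0], occ.right[0]) and (
                    occ.left == (site_id, "u") or occ.right == (site_id, "d")
                ):
                    return st, occ
        raise EventError(f"site {site_id} not found on haplotype {haplotype}")

    def state_of(self, name: str, haplotype: str) -> _ChromState:
        for st in self.states:
            if st.name == name and st.haplotype == haplotype:
                return st
        raise EventError(f"no chromosome {name} on haplotype {haplotype}")

    def record_losses(self, occs: Iterable[_Occ], haplotype: str) -> None:
        for o in occs:
            for locus in {o.left[0], o.right[0]}:
                self.losses.append((locus, haplotype))

    # -- event application ------------------------------------------------
    def apply(self, ev: SVEvent, essential: IntervalSet | None = None) -> list[Junction]:
        handler = getattr(self, f"_ev_{ev.kind}")
        return handler(ev, essential)

    def _pair_on_one_chrom(self, ev: SVEvent):
        sa, sb = ev.sites
        st_a, occ_a = self.find_site(sa, ev.haplotype)
        st_b, occ_b = self.find_site(sb, ev.haplotype)
        if st_a is not st_b:
            raise EventError(f"{ev.kind} sites {sa},{sb} lie on different chromosomes")
        if occ_a.pos > occ_b.pos:
            occ_a, occ_b = occ_b, occ_a
        return st_a, occ_a, occ_b

    def _ev_deletion(self, ev: SVEvent, essential) -> list[Junction]:
        st, a, b = self._pair_on_one_chrom(ev)
        if essential is not None:
            n_copies = sum(1 for s in self.states if s.name == st.name)
            if n_copies <= 1 and essential.overlaps(st.name, a.pos, b.pos):
                raise EventError(
                    f"deletion {ev.sites} removes an essential interval on the "
                    f"last copy of {st.name}")
        removed = [o for o in st.occs if a.pos < o.pos < b.pos]
        self.record_losses(removed, st.haplotype)
        shift = b.pos - a.pos
        st.seq = st.seq[: a.pos] + st.seq[b.pos:]
        fused = _Occ(a.pos, a.left, b.right)
        kept = [o for o in st.occs if o.pos < a.pos]
        tail = [o for o in st.occs if o.pos > b.pos]
        for o in tail:
            o.pos -= shift
            o.base_pos = None
        st.occs = kept + [fused] + tail
        st.colinear = False
        return [junction_of(a.left, b.right)]

    def _ev_inversion(self, ev: SVEvent, essential) -> list[Junction]:
        st, a, b = self._pair_on_one_chrom(ev)
        lo, hi = a.pos + LOX_LEN, b.pos
        st.seq = st.seq[:lo] + revcomp(st.seq[lo:hi]) + st.seq[hi:]
        inner = [o for o in st.occs if lo <= o.pos < hi]
        for o in inner:
            o.pos = lo + (hi - (o.pos + LOX_LEN))
            o.left, o.right = o.right, o.left
            o.base_pos = None
        a_right_old, b_left_old = a.right, b.left
        # occurrence a now reads U_a .. lox .. revcomp(pre-b sequence): its
        # pair becomes {a.left, old b.left}; occurrence b pairs
        # {old a.right, b.right}
        a.right = b_left_old
        b.left = a_right_old
        a.base_pos = b.base_pos = None
        st.colinear = False
        st.sorted_occs()
        return [junction_of(a.left, a.right), junction_of(b.left, b.right)]

    def _ev_duplication(self, ev: SVEvent, essential) -> list[Junction]:
        st, a, b = self._pair_on_one_chrom(ev)
        pa, pb = a.pos, b.pos
        seg = st.seq[pa:pb]
        st.seq = st.seq[:pb] + seg + st.seq[pb:]
        shift = pb - pa
        copies = []
        for o in st.occs:
            if pa <= o.pos < pb:
                if o.pos == pa:
                    copies.append(_Occ(o.pos + shift, b.left, a.right))
                else:
                    copies.append(_Occ(o.pos + shift, o.left, o.right))
        for o in st.occs:
            if o.pos >= pb:
                o.pos += shift
                o.base_pos = None
        st.occs.extend(copies)
        st.sorted_occs()
        st.colinear = False
        return [junction_of(b.left, a.right)]

    def _ev_inverted_duplication(self, ev: SVEvent, essential) -> list[Junction]:
        # foldback: inverted copy of [lox_a, lox_b) inserted right after
        # lox_b.  Creates a self-pair junction {b.left, b.left} at lox_b and
        # {a.right, old b.right} at the inverted copy of lox_a.
        st, a, b = self._pair_on_one_chrom(ev)
        pa, pb = a.pos, b.pos
        b_right_old = b.right
        seg = revcomp(st.seq[pa:pb])
        ins_at = pb + LOX_LEN
        st.seq = st.seq[:ins_at] + seg + st.seq[ins_at:]
        shift = len(seg)
        new_occs = []
        for o in st.occs:
            if pa <= o.pos < pb:
                new_pos = ins_at + (pb - (o.pos + LOX_LEN))
                if o.pos == pa:
                    new_occs.append(_Occ(new_pos, o.right, b_right_old))
                else:
                    new_occs.append(_Occ(new_pos, o.right, o.left))
        for o in st.occs:
            if o.pos >= ins_at:
                o.pos += shift
                o.base_pos = None
        st.occs.extend(new_occs)
        b.right = b.left  # sequence after lox_b is now revcomp of pre-lox_b
        b.base_pos = None
        st.sorted_occs()
        st.colinear = False
        return [junction_of(b.left, b.left), junction_of(a.right, b_right_old)]

    def _ev_translocation_reciprocal(self, ev: SVEvent, essential) -> list[Junction]:
        sa, sb = ev.sites
        st_a, a = self.find_site(sa, ev.haplotype)
        st_b, b = self.find_site(sb, ev.haplotype)
        if st_a is st_b:
            raise EventError(f"translocation sites {sa},{sb} lie on one chromosome")
        pa, pb = a.pos, b.pos
        seq_a, seq_b = st_a.seq, st_b.seq
        st_a.seq = seq_a[:pa] + seq_b[pb:]
        st_b.seq = seq_b[:pb] + seq_a[pa:]
        head_a = [o for o in st_a.occs if o.pos < pa]
        tail_a = [o for o in st_a.occs if o.pos > pa]
        head_b = [o for o in st_b.occs if o.pos < pb]
        tail_b = [o for o in st_b.occs if o.pos > pb]
        for o in tail_b:
            o.pos += pa - pb
            o.base_pos = None
        for o in tail_a:
            o.pos += pb - pa
            o.base_pos = None
        st_a.occs = head_a + [_Occ(pa, a.left, b.right)] + tail_b
        st_b.occs = head_b + [_Occ(pb, b.left, a.right)] + tail_a
        st_a.colinear = st_b.colinear = False
        st_a.sorted_occs(); st_b.sorted_occs()
        return [junction_of(a.left, b.right), junction_of(b.left, a.right)]

    def _ev_translocation_nonreciprocal(self, ev: SVEvent, essential) -> list[Junction]:
        # the tail of chromosome A beyond site a is replaced by the tail of
        # chromosome B beyond site b; B itself is left intact (its tail is
        # now present twice, A's tail is lost)
        sa, sb = ev.sites
        st_a, a = self.find_site(sa, ev.haplotype)
        st_b, b = self.find_site(sb, ev.haplotype)
        if st_a is st_b:
            raise EventError(f"translocation sites {sa},{sb} lie on one chromosome")
        pa, pb = a.pos, b.pos
        lost = [o for o in st_a.occs if o.pos > pa]
        self.record_losses(lost, st_a.haplotype)
        tail_b = [
            _Occ(o.pos + pa - pb, o.left, o.right)
            for o in st_b.occs if o.pos > pb
        ]
        st_a.seq = st_a.seq[:pa] + st_b.seq[pb:]
        st_a.occs = [o for o in st_a.occs if o.pos < pa] + \
            [_Occ(pa, a.left, b.right)] + tail_b
        st_a.colinear = False
        st_a.sorted_occs()
        return [junction_of(a.left, b.right)]

    def _ev_circularization(self, ev: SVEvent, essential) -> list[Junction]:
        # the chromosome circularizes between its two named sites; the arms
        # outside them are lost (excision-style circle kept as the chromosome)
        st, a, b = self._pair_on_one_chrom(ev)
        pa, pb = a.pos, b.pos
        lost = [o for o in st.occs if o.pos < pa or o.pos > pb]
        self.record_losses(lost, st.haplotype)
        self.record_losses([b], st.haplotype)  # b's motif merges into a's
        st.seq = st.seq[pa:pb]
        kept = []
        for o in st.occs:
            if pa <= o.pos < pb:
                o.pos -= pa
                kept.append(o)
        st.occs = kept
        a2 = st.occs[0]
        a2.left = b.left  # around the circle, lox_a is preceded by U_b
        st.topology = "circular"
        st.colinear = False
        return [junction_of(b.left, a2.right)]

    def _ev_chrom_gain(self, ev: SVEvent, essential) -> list[Junction]:
        st = self.state_of(ev.chrom, ev.haplotype)
        existing = {s.haplotype for s in self.states if s.name == st.name}
        k = 2
        while f"{st.haplotype}.gain{k}" in existing:
            k += 1
        copy = _ChromState(
            st.name, f"{st.haplotype}.gain{k}", st.seq,
            [_Occ(o.pos, o.left, o.right, o.base_pos) for o in st.occs],
            st.topology, st.colinear,
        )
        self.states.append(copy)
        return []

    def _ev_chrom_loss(self, ev: SVEvent, essential) -> list[Junction]:
        st = self.state_of(ev.chrom, ev.haplotype)
        self.record_losses(st.occs, st.haplotype)
        self.states.remove(st)
        return []

    def _ev_loh_conversion(self, ev: SVEvent, essential) -> list[Junction]:
        haps = {s.haplotype for s in self.states}
        if len(haps) < 2:
            raise EventError("loh_conversion requires a diploid genome")
        if ev.interval is None or ev.chrom is None or ev.donor_haplotype is None:
            raise EventError("loh_conversion needs chrom, interval, donor_haplotype")
        recip = self.state_of(ev.chrom, ev.haplotype)
        donor = self.state_of(ev.chrom, ev.donor_haplotype)
        if not (recip.colinear and donor.colinear):
            raise EventError(
                "loh_conversion requires both copies colinear with the base "
                "coordinate system (apply LOH before structural events)")
        s, e = ev.interval  # base coordinates
        if s >= e:
            raise EventError("empty loh interval")

        def to_cur(st: _ChromState, x: int) -> int:
            off = sum(LOX_LEN for o in st.occs if o.base_pos is not None and o.base_pos < x)
            return x + off

        rs, re_ = to_cur(recip, s), to_cur(recip, e)
        ds, de = to_cur(donor, s), to_cur(donor, e)
        if re_ > len(recip.seq) or de > len(donor.seq):
            raise EventError("loh interval outside chromosome bounds")
        removed = [o for o in recip.occs if rs <= o.pos < re_]
        self.record_losses(removed, recip.haplotype)
        gained = [
            _Occ(o.pos - ds + rs, o.left, o.right, o.base_pos)
            for o in donor.occs if ds <= o.pos < de
        ]
        shift = (de - ds) - (re_ - rs)
        recip.seq = recip.seq[:rs] + donor.seq[ds:de] + recip.seq[re_:]
        kept_head = [o for o in recip.occs if o.pos < rs]
        kept_tail = [o for o in recip.occs if o.pos >= re_]
        for o in kept_tail:
            o.pos += shift
            # base_pos stays valid: donor segment restores base colinearity
        recip.occs = kept_head + gained + kept_tail
        recip.sorted_occs()
        return []

    # -- export -----------------------------------------------------------
    def to_genome(self) -> GenomeModel:
        return GenomeModel([
            Chromosome(st.name, st.seq, st.topology, st.haplotype)
            for st in self.states
        ])

    def all_junctions(self) -> set:
        out = set()
        for st in self.states:
            for o in st.occs:
                out.add(junction_of(o.left, o.right))
        return out

    def occurrence_pairs(self) -> list[tuple[str, str, int, Junction]]:
        """(chrom, haplotype, pos, junction) for every lox occurrence."""
        out = []
        for st in self.states:
            for o in st.occs:
                out.append((st.name, st.haplotype, o.pos, junction_of(o.left, o.right)))
        return out


def apply_events(
    genome: GenomeModel,
    sites: LoxSiteTable | Mapping[str, LoxSiteTable] | None,
    events: Sequence[SVEvent],
    seed: int = 0,
    essential: IntervalSet | None = None,
) -> tuple[GenomeModel, EventLog]:
    """Apply rearrangement events sequentially and return the rearranged
    genome plus its ground-truth log.

    Events re-resolve site positions against the current state via site ids,
    so multi-event simulations compose.  ``seed`` is accepted for interface
    symmetry; the engine itself is deterministic.
    """
    sim = _SimGenome(genome, sites)
    log = EventLog()
    for ev in events:
        created = sim.apply(ev, essential)
        log.events.append(ev)
        log.per_event_junctions.append(created)
    log.expected_junctions = {j for j in sim.all_junctions() if not is_parental(j)}
    log.expected_losses = sorted(set(sim.losses))
    logger.info("apply_events: %d events, %d novel junctions in final genome",
                len(events), len(log.expected_junctions))
    out = sim.to_genome()
    out._sim_state = sim  # internal hook for truth-checking tests
    return out, log


def make_diploid(
    hapA: GenomeModel,
    hapB: GenomeModel,
    events: Sequence[SVEvent] = (),
    seed: int = 0,
    sites_a: LoxSiteTable | None = None,
    sites_b: LoxSiteTable | None = None,
) -> tuple[GenomeModel, EventLog]:
    """Merge two haplotypes into a diploid and apply LOH/aneuploidy events.

    Haplotypes must share chromosome names.  Chromosomes are relabelled with
    haplotype 'A' and 'B'; LOH conversion intervals are given in the shared
    lox-free base coordinate system.
    """
    names_a, names_b = set(hapA.names), set(hapB.names)
    if names_a != names_b:
        raise ValueError(f"haplotypes do not share chromosome names: "
                         f"{sorted(names_a ^ names_b)}")
    chroms = [Chromosome(c.name, c.sequence, c.topology, "A") for c in hapA.chromosomes]
    chroms += [Chromosome(c.name, c.sequence, c.topology, "B") for c in hapB.chromosomes]
    diploid = GenomeModel(chroms)
    tables: dict[str, LoxSiteTable] = {}
    if sites_a is not None:
        tables["A"] = sites_a
    if sites_b is not None:
        tables["B"] = sites_b
    return apply_events(diploid, tables, events, seed=seed)


# ---------------------------------------------------------------------------
# long-read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    """ONT-like read simulation parameters.

    Lengths are lognormal (defaults give a ~10 kb median); errors are i.i.d.
    per base with the given substitution/insertion/deletion fractions.
    """

    coverage: float = 20.0
    mean_log: float = 9.2
    sd_log: float = 0.5
    min_len: int = 500
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be >= 0 and sum < 0.5")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def error_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    chrom: str
    haplotype: str
    start: int  # source interval on the emitted chromosome, 0-based half-open
    end: int
    strand: str  # '+' or '-'


def _mutate(codes: np.ndarray, params: ReadSimParams, rng) -> np.ndarray:
    """Apply i.i.d. substitution/insertion/deletion errors to base codes."""
    n = codes.size
    if n == 0 or params.error_rate == 0:
        return codes
    u = rng.random(n)
    ps, pi, pd = params.sub_rate, params.ins_rate, params.del_rate
    sub = u < ps
    ins = (u >= ps) & (u < ps + pi)
    dele = (u >= ps + pi) & (u < ps + pi + pd)
    out = codes.copy()
    if sub.any():
        out[sub] = (out[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] += 1
    rep = np.repeat(np.arange(n), counts)
    res = out[rep]
    dup = np.empty(rep.size, dtype=bool)
    dup[0] = False
    dup[1:] = rep[1:] == rep[:-1]
    if dup.any():
        res[dup] = rng.integers(0, 4, size=int(dup.sum()))
    return res


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 0


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_reads(
    genome: GenomeModel, params: ReadSimParams
) -> tuple[list[SimRead], "pd.DataFrame"]:
    """Simulate long reads from every chromosome copy of ``genome``.

    Reads are drawn until total bases reach ``coverage x genome size``;
    source chromosome copies are chosen proportional to length, start
    positions uniformly (wrapping on circular chromosomes), strand uniformly.
    Returns the reads and a truth map (read -> source copy and interval).
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    chroms = genome.chromosomes
    lens = np.array([len(c) for c in chroms], dtype=float)
    target = params.coverage * lens.sum()
    total = 0
    reads: list[SimRead] = []
    rows = []
    i = 0
    codes_cache = {id(c): _encode(c.sequence) for c in chroms}
    while total < target:
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        chrom = chroms[ci]
        L = len(chrom)
        rl = int(rng.lognormal(params.mean_log, params.sd_log))
        rl = max(params.min_len, min(rl, L))
        if chrom.topology == "circular":
            start = int(rng.integers(0, L))
            end = start + rl
            src = codes_cache[id(chrom)]
            codes = src[start:min(end, L)]
            if end > L:
                codes = np.concatenate([codes, src[: end - L]])
            end_rec = end  # may exceed L to signal wrap
        else:
            start = int(rng.integers(0, L - rl + 1))
            end = end_rec = start + rl
            codes = codes_cache[id(chrom)][start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            codes = (3 - codes)[::-1]
        codes = _mutate(codes, params, rng)
        rid = f"read{i:07d}"
        reads.append(SimRead(rid, _decode(codes), chrom.name, chrom.haplotype,
                             start, end_rec, strand))
        rows.append((rid, chrom.name, chrom.haplotype, start, end_rec, strand,
                     codes.size))
        total += codes.size
        i += 1
    truth = pd.DataFrame(rows, columns=[
        "read_id", "chrom", "haplotype", "start", "end", "strand", "length"])
    logger.info("simulate_reads: %d reads, %.1f Mb (%.1fx)",
                len(reads), total / 1e6, total / lens.sum())
    return reads, truth


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTQ reader returning (read_id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
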