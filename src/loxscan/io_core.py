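"""Readers/writers and shared domain types for the rearrangement pipeline.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open and every point coordinate is
0-based.  All user-facing TSV output uses 1-based inclusive coordinates; BED
input stays 0-based half-open as the format requires.  Site tables on disk
give the 1-based position of the first base of the loxPsym motif.
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("loxscan")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Canonical 34-bp loxPsym motif: two 13-bp Cre-binding arms around an
#: 8-bp symmetric spacer; the whole motif equals its own reverse complement,
#: which is what lets Cre join two sites in either relative orientation.
LOXPSYM_SEQ = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

VALID_FLANK_LENS = (500, 1000, 1500, 2500)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file; message names the offending record/line."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    sequence: str
    topology: str = "linear"  # or "circular"
    haplotype: str = "0"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeModel:
    """A (possibly multi-haplotype) genome as a list of chromosomes.

    ``(name, haplotype)`` pairs are unique; a diploid carries each chromosome
    name once per haplotype label.
    """

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        keys = [(c.name, c.haplotype) for c in self.chromosomes]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (name, haplotype) pairs: {dup}")
        for c in self.chromosomes:
            if not c.sequence:
                raise ValueError(f"chromosome {c.name} has empty sequence")
            if c.topology not in ("linear", "circular"):
                raise ValueError(f"chromosome {c.name}: bad topology {c.topology!r}")

    def get(self, name: str, haplotype: str | None = None) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name and (haplotype is None or c.haplotype == haplotype):
                return c
        raise KeyError((name, haplotype))

    @property
    def names(self) -> list[str]:
        seen: list[str] = []
        for c in self.chromosomes:
            if c.name not in seen:
                seen.append(c.name)
        return seen

    def total_length(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def haplotypes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chromosomes:
            if c.haplotype not in seen:
                seen.append(c.haplotype)
        return seen


@dataclass(frozen=True)
class LoxSite:
    site_id: str
    chrom: str
    position: int  # 0-based offset of the first base of the motif
    copies: int = 1


class LoxSiteTable:
    """loxPsym loci of an engineered genome, sorted per chromosome.

    ``copies`` encodes co-located tandem insertions at one locus; collapsing
    them yields the distinct-locus count used by all pairwise statistics.
    """

    def __init__(self, sites: Iterable[LoxSite]):
        sites = list(sites)
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate site_id values: {dup}")
        by_chrom: dict[str, list[LoxSite]] = {}
        for s in sites:
            if s.copies < 1:
                raise ValueError(f"site {s.site_id}: copies must be >= 1")
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, ss in by_chrom.items():
            ss.sort(key=lambda s: s.position)
            for a, b in zip(ss, ss[1:]):
                if a.position == b.position:
                    raise ValueError(
                        f"duplicate locus rows at {chrom}:{a.position + 1} "
                        f"({a.site_id}, {b.site_id}); use the copies field"
                    )
        self._by_chrom = {k: by_chrom[k] for k in sorted(by_chrom)}
        self._sites = [s for ss in self._by_chrom.values() for s in ss]

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites)

    def __getitem__(self, site_id: str) -> LoxSite:
        for s in self._sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def on_chrom(self, chrom: str) -> list[LoxSite]:
        return list(self._by_chrom.get(chrom, []))

    def n_sites(self) -> int:
        """Total site count including co-located copies."""
        return sum(s.copies for s in self._sites)

    def n_loci(self) -> int:
        """Distinct loci (co-located copies collapsed)."""
        return len(self._sites)

    def adjacent_spacings(self) -> list[int]:
        """Distances between adjacent sites on each chromosome.

        Co-located copies contribute zero-length spacings, matching how the
        mean adjacent-site distance of an engineered strain is quoted.
        """
        out: list[int] = []
        for ss in self._by_chrom.values():
            expanded: list[int] = []
            for s in ss:
                expanded.extend([s.position] * s.copies)
            out.extend(b - a for a, b in zip(expanded, expanded[1:]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self._sites],
                "chrom": [s.chrom for s in self._sites],
                "position": [s.position + 1 for s in self._sites],  # 1-based out
                "copies": [s.copies for s in self._sites],
            }
        )


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based half-open
    end: int


class IntervalSet:
    """Sorted genomic intervals (0-based half-open); overlaps are kept as-is
    because membership tests use any-overlap."""

    def __init__(self, intervals: Iterable[Interval]):
        intervals = list(intervals)
        for iv in intervals:
            if iv.start >= iv.end:
                raise ValueError(f"empty interval {iv.chrom}:{iv.start}-{iv.end}")
        self._by_chrom: dict[str, list[Interval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in self._by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def contains_point(self, chrom: str, pos: int) -> bool:
        return any(iv.start <= pos < iv.end for iv in self._by_chrom.get(chrom, []))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            iv.start < end and start < iv.end
            for iv in self._by_chrom.get(chrom, [])
        )


class CentromereTable:
    """chrom -> centromere interval, used to resolve chromosome arms.

    Stored 0-based half-open internally; constructed from 1-based inclusive
    rows as written in centromere TSVs.
    """

    def __init__(self, entries: Mapping[str, tuple[int, int]]):
        # entries already 0-based half-open
        for chrom, (s, e) in entries.items():
            if s >= e or s < 0:
                raise ValueError(f"bad centromere interval for {chrom}: {s}-{e}")
        self._entries = dict(entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._entries

    def interval(self, chrom: str) -> tuple[int, int]:
        return self._entries[chrom]

    def arm(self, chrom: str, pos: int) -> str | None:
        """'L' left of the centromere, 'R' right of it, None if inside."""
        s, e = self._entries[chrom]
        if pos < s:
            return "L"
        if pos >= e:
            return "R"
        return None


@dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    flank_len
        Flank length (bp) used for junction references. 500/1000/1500/2500
        are the lengths over which results are expected to be stable; other
        values are accepted with a warning.
    lox_seq
        The recombination motif; must equal its own reverse complement.
    max_lox_edits
        Edit-distance budget when scanning reads for the motif.
    min_flank_cov
        Minimum fraction of a flank a read must cover for classification.
    min_score_margin
        Required gap (affine score units) between best and runner-up pool
        entry before a call is emitted.
    """

    flank_len: int = 1000
    lox_seq: str = LOXPSYM_SEQ
    max_lox_edits: int = 3
    min_flank_cov: float = 0.5
    min_score_margin: float = 20.0
    cnv_window: int = 2000
    cnv_max_iter: int = 20
    cnv_tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lox_seq != revcomp(self.lox_seq):
            raise ValueError("lox_seq must equal its own reverse complement")
        if self.flank_len not in VALID_FLANK_LENS:
            warnings.warn(
                f"flank_len={self.flank_len} is outside the standard set "
                f"{VALID_FLANK_LENS}", stacklevel=2,
            )
        if not 0 < self.min_flank_cov <= 1:
            raise ValueError("min_flank_cov must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeModel:
    """Read a FASTA genome; sequences are uppercased and validated."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chroms: list[Chromosome] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(
                f"record {rec.id}: invalid characters {sorted(bad)}"
            )
        if not seq:
            raise ParseError(f"record {rec.id}: empty sequence")
        chroms.append(Chromosome(name=rec.id, sequence=seq))
    if not chroms:
        raise ParseError(f"{path}: no FASTA records found")
    logger.info("read_genome: %d chromosomes, %d bp total",
                len(chroms), sum(len(c) for c in chroms))
    return GenomeModel(chroms)


def read_site_table(path: str | Path, genome: GenomeModel) -> LoxSiteTable:
    """Read a loxPsym site TSV (site_id, chrom, position [1-based], copies)
    and validate it against the genome."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str})
    required = {"site_id", "chrom", "position", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        try:
            chrom = genome.get(row.chrom)
        except KeyError:
            raise ParseError(f"site {row.site_id}: unknown chromosome {row.chrom}")
        pos0 = int(row.position) - 1
        if pos0 < 0 or pos0 >= len(chrom):
            raise ParseError(
                f"site {row.site_id}: position {row.position} outside "
                f"{row.chrom} (length {len(chrom)})"
            )
        sites.append(LoxSite(row.site_id, row.chrom, pos0, int(row.copies)))
    table = LoxSiteTable(sites)
    logger.info("read_site_table: %d sites, %d distinct loci",
                table.n_sites(), table.n_loci())
    return table


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3+ column BED file (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append(Interval(chrom, start, end))
    return IntervalSet(intervals)


def read_centromeres(path: str | Path, genome: GenomeModel | None = None) -> CentromereTable:
    """Read a centromere TSV (chrom, cen_start, cen_end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    entries: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        s0, e0 = int(row.cen_start) - 1, int(row.cen_end)  # to half-open
        if genome is not None:
            L = len(genome.get(row.chrom))
            if not (0 <= s0 < e0 <= L):
                raise ParseError(f"centromere of {row.chrom} outside chromosome")
        if row.chrom in entries:
            raise ParseError(f"duplicate centromere entry for {row.chrom}")
        entries[row.chrom] = (s0, e0)
    return CentromereTable(entries)


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(table: pd.DataFrame, path: str | Path,
                 sort_by: Sequence[str] | None = None) -> None:
    """Write a tabular result as TSV.

    Floats are rendered at 6 significant digits and rows are sorted by
    ``sort_by`` (default: all columns, left to right) so identical inputs
    produce byte-identical files.  Position columns are expected to already
    be 1-based in user-facing tables.
    """
    if table is None:
        raise ValueError("table is None")
    df = table.copy()
    if len(df):
        keys = list(sort_by) if sort_by else list(df.columns)
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    logger.info("write_report: %d rows -> %s", len(df), path)
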