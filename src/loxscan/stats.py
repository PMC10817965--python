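"""Rearrangement-rate statistics: RR, ARR, RW, outliers, regressions,
group tests and network export.

Definitions (counts from `loxscan.junctions.CountsTable`):

* ``RR_i = Nre_i / (2*Nnorm_i + Nre_i)`` — per-site fraction of rearranged
  junction observations; the denominator ``Nall_i`` counts flank
  observations (a normal read covers both flanks of a site).
* ``ARR_{i,class} = (Nre_{i,class} / Nall_i) / P_{i,class}`` — the
  class-restricted rate divided by the number of possible partner loci of
  that class, making intra- and inter-chromosomal activity comparable per
  partner opportunity.  The alternative global normalisation (divide by the
  total number of rearranged sites) is available via ``normalization``.
* ``RW_ij = Nre_ij / sqrt(Nall_i * Nall_j)`` — pairwise rearrangement weight
  normalised by the geometric mean of the two sites' observation depths, so
  uniform changes of sequencing depth cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import CentromereTable, IntervalSet, LoxSiteTable, logger
from .junctions import CountsTable


# ---------------------------------------------------------------------------
# core rates
# ---------------------------------------------------------------------------

def compute_rr(counts: CountsTable) -> pd.Series:
    """Per-locus rearrangement rate; NaN where a locus has no observations."""
    out = {}
    for locus in counts.loci:
        nall = counts.nall(locus)
        out[locus] = counts.nre.get(locus, 0) / nall if nall > 0 else float("nan")
    return pd.Series(out, name="rr")


def _partner_counts(sites: LoxSiteTable, cls: str) -> dict[str, int]:
    per_chrom = {c: len(sites.on_chrom(c)) for c in sites.chroms}
    L = sites.n_loci()
    out = {}
    for s in sites:
        n_c = per_chrom[s.chrom]
        out[s.site_id] = (n_c - 1) if cls == "intra" else (L - n_c)
    return out


def _class_nre(counts: CountsTable, sites: LoxSiteTable, cls: str) -> dict[str, float]:
    chrom_of = {s.site_id: s.chrom for s in sites}
    out = {l: 0.0 for l in counts.loci}
    for pair, n in counts.nre_pair.items():
        if len(pair) != 2:
            continue
        a, b = sorted(pair)
        intra = chrom_of[a] == chrom_of[b]
        if (cls == "intra") == intra:
            out[a] = out.get(a, 0.0) + n
            out[b] = out.get(b, 0.0) + n
    return out


def compute_arr(
    counts: CountsTable,
    sites: LoxSiteTable,
    cls: str,
    normalization: str = "partners",
) -> pd.Series:
    """Average rearrangement rate per locus for one pair class.

    ``normalization='partners'`` divides the class-restricted rate by the
    number of possible partner loci of that class for the locus (default);
    ``'global'`` divides by the total number of loci with any rearrangement.
    Loci with no possible partner of the class (e.g. intra on a two-locus
    chromosome's lone partner being itself) yield NaN.
    """
    if cls not in ("intra", "inter"):
        raise ValueError("cls must be 'intra' or 'inter'")
    class_nre = _class_nre(counts, sites, cls)
    if normalization == "partners":
        denom = _partner_counts(sites, cls)
    elif normalization == "global":
        n_rearranged = sum(1 for l in counts.loci if counts.nre.get(l, 0) > 0)
        denom = {l: n_rearranged for l in counts.loci}
    else:
        raise ValueError("normalization must be 'partners' or 'global'")
    out = {}
    for locus in counts.loci:
        nall = counts.nall(locus)
        p = denom.get(locus, 0)
        if nall == 0 or p == 0:
            out[locus] = float("nan")
        else:
            out[locus] = (class_nre.get(locus, 0.0) / nall) / p
    return pd.Series(out, name=f"arr_{cls}")


@dataclass
class RWMatrix:
    """Symmetric per-pair rearrangement weights with pair metadata."""

    loci: list[str]
    values: np.ndarray  # L x L, diagonal 0

    def __post_init__(self) -> None:
        self._index = {l: i for i, l in enumerate(self.loci)}

    def rw(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i, a in enumerate(self.loci):
            for j in range(i + 1, len(self.loci)):
                out.append((a, self.loci[j], float(self.values[i, j])))
        return out

    def to_long_frame(self, sites: LoxSiteTable,
                      centromeres: CentromereTable | None = None) -> pd.DataFrame:
        chrom_of = {s.site_id: s.chrom for s in sites}
        pos_of = {s.site_id: s.position for s in sites}
        rows = []
        for a, b, v in self.pairs():
            intra = chrom_of[a] == chrom_of[b]
            dist = abs(pos_of[a] - pos_of[b]) if intra else np.nan
            same_arm = False
            if intra and centromeres is not None and chrom_of[a] in centromeres:
                arm_a = centromeres.arm(chrom_of[a], pos_of[a])
                arm_b = centromeres.arm(chrom_of[b], pos_of[b])
                same_arm = arm_a is not None and arm_a == arm_b
            rows.append((a, b, v, "intra" if intra else "inter", dist, same_arm))
        return pd.DataFrame(rows, columns=[
            "locus_a", "locus_b", "rw", "class", "distance", "same_arm"])


def compute_rw(counts: CountsTable) -> RWMatrix:
    """Pairwise rearrangement weight matrix (zero where either depth is 0)."""
    loci = list(counts.loci)
    idx = {l: i for i, l in enumerate(loci)}
    vals = np.zeros((len(loci), len(loci)))
    nall = {l: counts.nall(l) for l in loci}
    for pair, n in counts.nre_pair.items():
        if len(pair) != 2:
            continue
        a, b = sorted(pair)
        if nall[a] > 0 and nall[b] > 0:
            v = n / math.sqrt(nall[a] * nall[b])
            vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return RWMatrix(loci, vals)


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

def find_outliers(values: Mapping[str, float] | pd.Series) -> set[str]:
    """Upper-tail Tukey outliers: value > Q3 + 1.5*IQR.

    Quartiles use linear interpolation.  NaNs are ignored; at least five
    finite values are required.
    """
    s = pd.Series(values).dropna()
    if len(s) < 5:
        raise ValueError(f"need >= 5 values, have {len(s)}")
    q1, q3 = np.percentile(s.to_numpy(), [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return set(s.index[s > fence])


# ---------------------------------------------------------------------------
# regressions and group tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def rw_distance_regression(
    rw: RWMatrix, sites: LoxSiteTable, centromeres: CentromereTable
) -> RegressionResult:
    """OLS of RW on 1/genomic distance over same-arm intra-chromosomal pairs.

    Pairs spanning (or inside) the centromere interval are excluded.
    """
    df = rw.to_long_frame(sites, centromeres)
    sel = df[(df["class"] == "intra") & df["same_arm"] & (df["distance"] > 0)]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 same-arm pairs, have {len(sel)}")
    x = 1.0 / sel["distance"].to_numpy()
    y = sel["rw"].to_numpy()
    res = sps.linregress(x, y)
    return RegressionResult(res.slope, res.intercept, res.rvalue ** 2,
                            res.pvalue, len(sel))


def group_tests(
    arr_intra: pd.Series,
    arr_inter: pd.Series,
    sites: LoxSiteTable | None = None,
    open_regions: IntervalSet | None = None,
) -> list[GroupTestResult]:
    """Standard group comparisons of per-locus rates.

    Always returns the two-sided Mann-Whitney comparison of intra vs inter
    ARR; when ``sites`` and ``open_regions`` are given, also the unpaired
    two-tailed t-test of inter-chromosomal ARR between loci inside vs
    outside open-chromatin intervals (a locus is "open" when its motif
    position overlaps any interval).
    """
    out = []
    a = arr_intra.dropna().to_numpy()
    b = arr_inter.dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        which = "intra" if len(a) == 0 else "inter"
        raise ValueError(f"group '{which}' is empty")
    mw = sps.mannwhitneyu(a, b, alternative="two-sided")
    out.append(GroupTestResult("mann_whitney", float(mw.statistic),
                               float(mw.pvalue), len(a), len(b)))
    if sites is not None and open_regions is not None:
        open_loci = {
            s.site_id for s in sites
            if open_regions.overlaps(s.chrom, s.position, s.position + 1)
        }
        vals = arr_inter.dropna()
        g_open = vals[[l in open_loci for l in vals.index]].to_numpy()
        g_closed = vals[[l not in open_loci for l in vals.index]].to_numpy()
        if len(g_open) == 0 or len(g_closed) == 0:
            which = "open" if len(g_open) == 0 else "closed"
            raise ValueError(f"group '{which}' is empty")
        tt = sps.ttest_ind(g_open, g_closed, equal_var=True)
        out.append(GroupTestResult("t_test_two_tailed", float(tt.statistic),
                                   float(tt.pvalue), len(g_open), len(g_closed)))
    return out


def contact_correlation(
    rw: RWMatrix, contact: np.ndarray, sites: LoxSiteTable
) -> GroupTestResult:
    """Spearman correlation of RW with contact counts over inter-chromosomal
    locus pairs; NaN statistic when the contact values are constant."""
    contact = np.asarray(contact, dtype=float)
    if contact.shape != rw.values.shape:
        raise ValueError(f"contact matrix shape {contact.shape} does not match "
                         f"RW matrix {rw.values.shape}")
    chrom_of = {s.site_id: s.chrom for s in sites}
    idx = {l: i for i, l in enumerate(rw.loci)}
    xs, ys = [], []
    for i, a in enumerate(rw.loci):
        for j in range(i + 1, len(rw.loci)):
            b = rw.loci[j]
            if chrom_of[a] != chrom_of[b]:
                xs.append(rw.values[i, j])
                ys.append(contact[idx[a], idx[b]])
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.allclose(ys, ys[0]) or np.allclose(xs, xs[0]):
        return GroupTestResult("spearman", float("nan"), float("nan"),
                               len(xs), len(ys))
    r, p = sps.spearmanr(xs, ys)
    return GroupTestResult("spearman", float(r), float(p), len(xs), len(ys))


def contact_ratio_map(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Median-normalised log2 ratio of two binned contact maps.

    Cells where either map is non-positive are masked (NaN) and ignored by
    the median.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    out = np.full(a.shape, np.nan)
    mask = (a > 0) & (b > 0)
    out[mask] = np.log2(a[mask] / b[mask])
    med = np.nanmedian(out) if mask.any() else 0.0
    out[mask] -= med
    return out


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def export_network(
    rw: RWMatrix,
    sites: LoxSiteTable,
    threshold: float,
    intra_path: str | Path,
    inter_path: str | Path,
) -> tuple[int, int]:
    """Write SIF-style weighted edge lists of pairs with RW >= threshold,
    split into intra- and inter-chromosomal files.  Returns edge counts."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    chrom_of = {s.site_id: s.chrom for s in sites}
    intra_rows, inter_rows = [], []
    for a, b, v in rw.pairs():
        if v >= threshold and v > 0:
            row = (a, b, v)
            (intra_rows if chrom_of[a] == chrom_of[b] else inter_rows).append(row)
    for rows, path in ((intra_rows, intra_path), (inter_rows, inter_path)):
        with open(path, "w") as fh:
            fh.write("locus_a\trearranges_with\tlocus_b\trw\n")
            for a, b, v in sorted(rows):
                fh.write(f"{a}\trearranges_with\t{b}\t{v:.6g}\n")
    logger.info("export_network: %d intra / %d inter edges (threshold %g)",
                len(intra_rows), len(inter_rows), threshold)
    return len(intra_rows), len(inter_rows)


def read_network(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["locus_a", "locus_b", "rw"]]


# ---------------------------------------------------------------------------
# null expectations
# ---------------------------------------------------------------------------

def intra_pair_fraction(sites: LoxSiteTable) -> float:
    """Analytic fraction of locus pairs that are intra-chromosomal — the
    expected intra-event proportion when recombination has no intra/inter
    preference."""
    per_chrom = [len(sites.on_chrom(c)) for c in sites.chroms]
    L = sites.n_loci()
    total = L * (L - 1) / 2
    intra = sum(n * (n - 1) / 2 for n in per_chrom)
    return intra / total if total else float("nan")


def observed_intra_fraction(counts: CountsTable, sites: LoxSiteTable) -> float:
    """Fraction of counted rearrangement events joining same-chromosome loci."""
    chrom_of = {s.site_id: s.chrom for s in sites}
    intra = total = 0
    for pair, n in counts.nre_pair.items():
        if len(pair) != 2:
            continue
        a, b = sorted(pair)
        total += n
        if chrom_of[a] == chrom_of[b]:
            intra += n
    return intra / total if total else float("nan")
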