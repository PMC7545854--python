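"""Per-SNP pairwise F_ST and the stock-specific SNP logic.

F_ST is the classical per-site form

    F_ST = (pi_total - pi_within) / pi_total

with pi_within the average of the two stocks' per-site heterozygosities and
pi_total the heterozygosity of the summed counts.  Negative values (when
pi_within exceeds pi_total) are retained, not clamped; sites monomorphic in
the combined sample are undefined and skipped.

Stock-specific SNPs: within the top-q F_ST sets of all pairwise comparisons,
a SNP is a candidate for stock s when it appears in the top set of *every*
comparison involving s, and stock-specific when it is a candidate for
exactly one stock (the "intersection" rule; a looser "union" rule — top in
at least one comparison involving s — is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SiteCounts
from .sites import FilterConfig, classify_sites, heterozygosity_per_site

__all__ = [
    "FstTable",
    "TopSnpSet",
    "site_fst",
    "fst_per_site",
    "pairwise_scan",
    "fixed_differentiation",
    "top_quantile",
    "stock_specific_snps",
]

logger = logging.getLogger(__name__)

Snp = tuple[str, int]


@dataclass
class FstTable:
    """Per-SNP F_ST records for one stock pair.

    ``table`` has columns chrom, pos, fst, pi_within, pi_total; rows are
    restricted to sites classified as SNPs for the pair with pi_total > 0.
    """

    stock_a: str
    stock_b: str
    table: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def genome_mean(self) -> float:
        """Unweighted mean of per-SNP F_ST (NaN when the table is empty)."""
        return self.mean()

    def mean(self, method: str = "unweighted") -> float:
        if self.table.empty:
            return float("nan")
        if method == "unweighted":
            return float(self.table["fst"].mean())
        if method == "ratio_of_sums":
            pit = self.table["pi_total"].sum()
            piw = self.table["pi_within"].sum()
            return float((pit - piw) / pit)
        raise ValueError(f"unknown mean method {method!r}")

    def snps(self) -> set[Snp]:
        return set(zip(self.table["chrom"], self.table["pos"]))


@dataclass
class TopSnpSet:
    """SNPs at or above the (1-q) empirical F_ST quantile for one pair."""

    stock_a: str
    stock_b: str
    q: float
    cutoff: float
    snps: set[Snp]

    @property
    def pair(self) -> frozenset:
        return frozenset((self.stock_a, self.stock_b))


def fst_per_site(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Vectorised classical F_ST from (n_sites, 4) count arrays.

    NaN where the combined site is monomorphic (pi_total = 0) or where
    either stock's coverage is below 2.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    pi_a = heterozygosity_per_site(counts_a)
    pi_b = heterozygosity_per_site(counts_b)
    pi_total = heterozygosity_per_site(counts_a + counts_b)
    pi_within = 0.5 * (pi_a + pi_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (pi_total - pi_within) / pi_total
    return np.where(pi_total > 0, fst, np.nan)


def site_fst(site_a: SiteCounts | np.ndarray, site_b: SiteCounts | np.ndarray) -> float:
    """Classical per-site F_ST between two pools' counts.

    Accepts :class:`SiteCounts` (counts summed across its pools) or a plain
    4-vector of base counts.  NaN when the combined site is monomorphic.
    """

    def to4(x) -> np.ndarray:
        if isinstance(x, SiteCounts):
            return x.counts[:, :4].sum(axis=0)
        arr = np.asarray(x, dtype=float).ravel()
        if arr.size == 6:
            arr = arr[:4]
        if arr.size != 4:
            raise ValueError("expected a 4-base count vector")
        return arr

    a, b = to4(site_a), to4(site_b)
    val = float(fst_per_site(a[None, :], b[None, :])[0])
    if np.isnan(val):
        logger.info("combined-monomorphic or low-coverage site skipped in F_ST")
    return val


def pairwise_scan(
    matrix: CountMatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    filters: FilterConfig | None = None,
    caps: np.ndarray | None = None,
) -> dict[frozenset, FstTable]:
    """Per-SNP F_ST tables for every stock pair.

    ``matrix`` must be stock-level (one column per stock; see
    :func:`poolscan.sites.merge_by_stock`).  For each pair, sites are
    classified with the pair's two columns as scope; per-SNP F_ST is
    computed at SNP sites with pi_total > 0.
    """
    filters = filters or FilterConfig()
    if matrix.panel is None:
        raise ValueError("pairwise_scan needs a stock-level panel")
    stocks = matrix.panel.labels
    if pairs is None:
        pairs = list(combinations(stocks, 2))
    col = {s: i for i, s in enumerate(stocks)}

    out: dict[frozenset, FstTable] = {}
    for a, b in pairs:
        ia, ib = col[a], col[b]
        cls = classify_sites(matrix, filters, scope=[ia, ib], caps=caps)
        ca = matrix.counts[:, ia, :4]
        cb = matrix.counts[:, ib, :4]
        fst = fst_per_site(ca, cb)
        keep = cls.snp & ~np.isnan(fst)
        pi_a = heterozygosity_per_site(ca[keep])
        pi_b = heterozygosity_per_site(cb[keep])
        pi_t = heterozygosity_per_site(ca[keep] + cb[keep])
        table = pd.DataFrame(
            {
                "chrom": matrix.chrom[keep],
                "pos": matrix.pos[keep],
                "fst": fst[keep],
                "pi_within": 0.5 * (pi_a + pi_b),
                "pi_total": pi_t,
            }
        ).reset_index(drop=True)
        if table.empty:
            logger.warning("pair (%s, %s): no SNPs passed the filters", a, b)
        out[frozenset((a, b))] = FstTable(stock_a=a, stock_b=b, table=table)
    return out


def fixed_differentiation(
    ftable: FstTable, threshold: float = 0.65
) -> tuple[int, pd.DataFrame]:
    """SNPs with F_ST strictly greater than ``threshold`` (default 0.65)."""
    hits = ftable.table[ftable.table["fst"] > threshold]
    return len(hits), hits.reset_index(drop=True)


def top_quantile(ftable: FstTable, q: float) -> TopSnpSet:
    """SNPs at or above the empirical (1-q) F_ST quantile, ties included."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    values = ftable.table["fst"].to_numpy()
    if values.size == 0:
        return TopSnpSet(ftable.stock_a, ftable.stock_b, q, float("nan"), set())
    cutoff = float(np.quantile(values, 1.0 - q))
    sel = ftable.table[ftable.table["fst"] >= cutoff]
    return TopSnpSet(
        stock_a=ftable.stock_a,
        stock_b=ftable.stock_b,
        q=q,
        cutoff=cutoff,
        snps=set(zip(sel["chrom"], sel["pos"])),
    )


def stock_specific_snps(
    top_sets: Mapping[frozenset, TopSnpSet] | Sequence[TopSnpSet],
    stocks: Sequence[str],
    rule: str = "intersection",
) -> dict[str, list[Snp]]:
    """Per-stock unique SNPs among the top-q candidates of all comparisons.

    Under the default "intersection" rule a SNP is a candidate for stock s
    iff it lies in the top set of *every* pairwise comparison involving s;
    under "union" it suffices to be top in at least one.  Either way, the
    SNP is stock-specific to s iff it is a candidate for exactly one stock.

    All ``len(stocks) choose 2`` comparisons must be present.
    """
    if rule not in ("intersection", "union"):
        raise ValueError(f"unknown rule {rule!r}")
    if not isinstance(top_sets, Mapping):
        top_sets = {t.pair: t for t in top_sets}
    missing = [
        (a, b)
        for a, b in combinations(stocks, 2)
        if frozenset((a, b)) not in top_sets
    ]
    if missing:
        raise ValueError(f"missing pairwise comparisons: {missing}")

    candidates: dict[str, set[Snp]] = {}
    for s in stocks:
        sets = [top_sets[frozenset((s, t))].snps for t in stocks if t != s]
        if rule == "intersection":
            cand = set.intersection(*sets) if sets else set()
        else:
            cand = set.union(*sets) if sets else set()
        candidates[s] = cand

    membership: dict[Snp, int] = {}
    for cand in candidates.values():
        for snp in cand:
            membership[snp] = membership.get(snp, 0) + 1
    return {
        s: sorted(snp for snp in cand if membership[snp] == 1)
        for s, cand in candidates.items()
    }


def summary_matrix(
    tables: Mapping[frozenset, FstTable],
    stocks: Sequence[str],
    fixed_threshold: float = 0.65,
) -> pd.DataFrame:
    """Square summary: mean F_ST below the diagonal, fixed-difference counts
    (F_ST > threshold) above it."""
    mat = pd.DataFrame(np.nan, index=list(stocks), columns=list(stocks))
    for i, a in enumerate(stocks):
        for j, b in enumerate(stocks):
            if i == j:
                continue
            t = tables.get(frozenset((a, b)))
            if t is None:
                continue
            if i > j:
                mat.loc[a, b] = t.genome_mean
            else:
                mat.loc[a, b] = fixed_differentiation(t, fixed_threshold)[0]
    return mat
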