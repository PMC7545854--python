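"""Composite Selection Signal (CSS) scan and haplotype-block localization.

For each of m population contrasts (here: each resistance-bred stock versus
the generalized Italian background), per-SNP F_ST values are converted to
fractional ranks r = rank/(N+1) (average ranks for ties, so r stays strictly
inside (0,1)), then to Z-scores via the standard normal quantile function.
The per-SNP mean Z over contrasts, z_bar, has null distribution
Normal(0, 1/m), so the one-sided (high-differentiation) p-value is

    p = 1 - Phi(z_bar * sqrt(m)),        CSS = -log10(p).

Being rank-based, CSS is invariant under any strictly monotone transform of
each contrast's F_ST values.  Outliers are the top 0.1% of the CSS
distribution; they are localized to haplotype blocks (0-based half-open),
and a block is reported when it holds more than ``min_snps`` member SNPs and
at least one outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HaplotypeBlock

__all__ = [
    "CssResult",
    "EnrichedBlock",
    "fractional_ranks",
    "rank_to_z",
    "css_score",
    "compute_css",
    "top_css",
    "map_to_blocks",
]

logger = logging.getLogger(__name__)

Snp = tuple[str, int]


@dataclass
class EnrichedBlock:
    """A haplotype block annotated with member-SNP and CSS-outlier counts."""

    block: HaplotypeBlock
    snp_count: int
    outlier_count: int
    reported: bool


@dataclass
class CssResult:
    """Per-SNP CSS table.

    ``table`` is indexed by (chrom, pos) with columns z_<comparison>...,
    z_mean, m, p, css.
    """

    table: pd.DataFrame
    comparisons: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.table)


def fractional_ranks(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """r_i = rank_i / (N+1), with average ranks for ties.

    All ranks fall strictly inside (0, 1): the maximum maps to N/(N+1).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value to rank")
    if not np.isfinite(values).all():
        raise ValueError("ranks require finite values")
    ranks = stats.rankdata(values, method="average")
    return ranks / (values.size + 1.0)


def rank_to_z(r: float | np.ndarray) -> float | np.ndarray:
    """Standard normal quantile of a fractional rank in the open interval."""
    arr = np.asarray(r, dtype=float)
    if ((arr <= 0) | (arr >= 1)).any():
        raise ValueError("fractional ranks must lie strictly inside (0, 1)")
    z = stats.norm.ppf(arr)
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def css_score(
    z: pd.DataFrame,
    policy: str = "complete",
) -> CssResult:
    """CSS from a SNPs x comparisons matrix of Z-scores.

    Under "complete" (default), SNPs missing a Z in any comparison are
    dropped (and logged).  Under "available", each SNP uses its own m_i
    observed comparisons, with the null variance 1/m_i.
    """
    if z.shape[1] < 1:
        raise ValueError("need at least one comparison")
    if policy not in ("complete", "available"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    if policy == "complete":
        kept = z.dropna(axis=0, how="any")
        dropped = len(z) - len(kept)
        if dropped:
            logger.info("css: dropped %d SNPs missing a comparison", dropped)
        z = kept
    m = z.notna().sum(axis=1).to_numpy(dtype=float)
    z_mean = z.mean(axis=1, skipna=True).to_numpy(dtype=float)
    p = stats.norm.sf(z_mean * np.sqrt(m))
    # sf of a finite argument is strictly inside (0,1); -log10 stays finite
    css = -np.log10(p)
    table = pd.DataFrame(
        {f"z_{c}": z[c] for c in z.columns}
        | {"z_mean": z_mean, "m": m.astype(int), "p": p, "css": css},
        index=z.index,
    )
    return CssResult(table=table, comparisons=list(z.columns))


def compute_css(
    fst_by_comparison: Mapping[str, pd.DataFrame],
    policy: str = "complete",
) -> CssResult:
    """Full CSS path from per-comparison F_ST tables.

    Each table needs columns chrom, pos, fst.  Fractional ranks are taken
    within each comparison over *its own* SNP set before the per-SNP join.
    """
    z_cols = {}
    for name, table in fst_by_comparison.items():
        r = fractional_ranks(table["fst"].to_numpy())
        idx = pd.MultiIndex.from_arrays(
            [table["chrom"], table["pos"]], names=["chrom", "pos"]
        )
        z_cols[name] = pd.Series(rank_to_z(r), index=idx)
    z = pd.DataFrame(z_cols)
    return css_score(z, policy=policy)


def top_css(result: CssResult, q: float = 0.001) -> set[Snp]:
    """SNPs at or above the (1-q) empirical CSS quantile, ties included."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if result.table.empty:
        raise ValueError("empty CSS table")
    css = result.table["css"].to_numpy()
    cutoff = np.quantile(css, 1.0 - q)
    sel = result.table.index[css >= cutoff]
    return set(sel)


def map_to_blocks(
    outliers: Iterable[Snp],
    all_snps: Iterable[Snp],
    blocks: Sequence[HaplotypeBlock],
    min_snps: int = 5,
) -> list[EnrichedBlock]:
    """Assign SNPs to haplotype blocks and flag the reportable ones.

    Block membership of a SNP position P is ``start <= P < end`` (a SNP at
    the half-open block end is excluded).  A SNP landing in several
    overlapping blocks counts in each.  A block is reported when its member
    SNP count strictly exceeds ``min_snps`` and it holds at least one
    outlier.  Output sorted by (chrom, start).
    """
    by_chrom_all: dict[str, np.ndarray] = {}
    by_chrom_out: dict[str, np.ndarray] = {}
    for target, snps in ((by_chrom_all, all_snps), (by_chrom_out, outliers)):
        tmp: dict[str, list[int]] = {}
        for chrom, pos in snps:
            tmp.setdefault(chrom, []).append(pos)
        for chrom, positions in tmp.items():
            target[chrom] = np.sort(np.asarray(positions))

    empty = np.array([], dtype=int)
    out: list[EnrichedBlock] = []
    for block in sorted(blocks, key=lambda b: (b.chrom, b.start, b.end)):
        pos_all = by_chrom_all.get(block.chrom, empty)
        pos_out = by_chrom_out.get(block.chrom, empty)
        n_all = int(
            np.searchsorted(pos_all, block.end, side="left")
            - np.searchsorted(pos_all, block.start, side="left")
        )
        n_out = int(
            np.searchsorted(pos_out, block.end, side="left")
            - np.searchsorted(pos_out, block.start, side="left")
        )
        out.append(
            EnrichedBlock(
                block=HaplotypeBlock(
                    chrom=block.chrom,
                    start=block.start,
                    end=block.end,
                    block_id=block.block_id,
                    snp_count=n_all,
                ),
                snp_count=n_all,
                outlier_count=n_out,
                reported=(n_all > min_snps and n_out >= 1),
            )
        )
    return out
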