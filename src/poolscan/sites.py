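"""Site filters, allele classification and per-site heterozygosity.

These are the atoms of every downstream statistic.  A site is *eligible* when
every in-scope pool's coverage sits inside the [min_coverage, max-coverage
cap] window, and a *SNP* when it is eligible and the combined minor-allele
read count across the in-scope pools reaches min_count.  Per-site diversity
is the sample-size-corrected expected heterozygosity

    pi_hat = C/(C-1) * (1 - sum_a f_a^2)

over the four nucleotides with counts summed across the scope, C being the
combined coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import BASES, CountMatrix, PoolPanel, SiteCounts

__all__ = [
    "FilterConfig",
    "SiteClass",
    "SiteClassTable",
    "classify_site",
    "classify_sites",
    "site_heterozygosity",
    "heterozygosity_per_site",
    "merge_pools",
    "merge_by_stock",
    "max_coverage_caps",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Site-filter thresholds.

    Defaults are the conservative settings used throughout the analysis:
    minimum coverage 20 reads, minimum (combined) minor-allele count 10
    reads, minimum base quality Q20, and a per-pool maximum-coverage cap at
    the 98th coverage percentile (excluding the top 2% highest-coverage
    sites, which are enriched for repeats and copy-number artefacts).

    ``min_quality`` is recorded for provenance only: sync count tables carry
    no per-base qualities, so the Q filter is applied upstream of the counts.
    """

    min_coverage: int = 20
    min_count: int = 10
    min_quality: int = 20
    max_cov_percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0 < self.max_cov_percentile <= 100:
            raise ValueError("max_cov_percentile must be in (0, 100]")


@dataclass
class SiteClass:
    """Classification of one site within a pool scope."""

    eligible: bool
    snp: bool
    major: str
    minor: str
    minor_freq: np.ndarray  # per in-scope pool frequency of the minor allele

    def __post_init__(self) -> None:
        if self.snp and not self.eligible:
            raise ValueError("snp implies eligible")


@dataclass
class SiteClassTable:
    """Vectorised classification of all sites in a :class:`CountMatrix`."""

    eligible: np.ndarray  # (n_sites,) bool
    snp: np.ndarray  # (n_sites,) bool
    major_idx: np.ndarray  # (n_sites,) int, index into BASES
    minor_idx: np.ndarray  # (n_sites,) int
    minor_count: np.ndarray  # (n_sites,) combined minor-allele count
    minor_freq: np.ndarray = field(default=None)  # (n_sites, n_scope) or None

    @property
    def major(self) -> np.ndarray:
        return np.array(list(BASES))[self.major_idx]

    @property
    def minor(self) -> np.ndarray:
        return np.array(list(BASES))[self.minor_idx]


def max_coverage_caps(
    matrix: CountMatrix | np.ndarray, filters: FilterConfig
) -> np.ndarray:
    """Per-pool maximum-coverage cap at the configured percentile.

    With fewer than 100 sites the percentile is not meaningfully estimable;
    the cap falls back to +inf with a warning (nothing excluded).
    """
    cov = matrix.coverage if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    if cov.ndim == 1:
        cov = cov[:, None]
    n_sites, n_pools = cov.shape
    if n_sites < 100:
        warnings.warn(
            f"only {n_sites} sites: too few to estimate a coverage percentile; "
            "max-coverage cap disabled (+inf)",
            stacklevel=2,
        )
        return np.full(n_pools, np.inf)
    return np.percentile(cov, filters.max_cov_percentile, axis=0)


def classify_sites(
    matrix: CountMatrix,
    filters: FilterConfig,
    scope: Sequence[int] | None = None,
    caps: np.ndarray | None = None,
) -> SiteClassTable:
    """Classify every site of ``matrix`` within the pool ``scope``.

    ``caps`` are per-pool maximum-coverage caps *for the scope pools* (in
    scope order); by default they are estimated from the scope pools' own
    coverage distributions via :func:`max_coverage_caps`.
    """
    scope = list(range(matrix.n_pools)) if scope is None else list(scope)
    if not scope:
        raise ValueError("scope must be non-empty")
    counts4 = matrix.counts[:, scope, :4]
    cov = counts4.sum(axis=2)  # (n_sites, n_scope)
    if caps is None:
        caps = max_coverage_caps(cov, filters)
    caps = np.asarray(caps, dtype=float)
    eligible = ((cov >= filters.min_coverage) & (cov <= caps[None, :])).all(axis=1)

    combined = counts4.sum(axis=1)  # (n_sites, 4)
    order = np.argsort(combined, axis=1, kind="stable")
    major_idx = order[:, -1]
    minor_idx = order[:, -2]
    rows = np.arange(matrix.n_sites)
    minor_count = combined[rows, minor_idx]
    snp = eligible & (minor_count >= filters.min_count)

    with np.errstate(invalid="ignore", divide="ignore"):
        minor_freq = counts4[rows, :, minor_idx] / np.where(cov > 0, cov, np.nan)
    return SiteClassTable(
        eligible=eligible,
        snp=snp,
        major_idx=major_idx,
        minor_idx=minor_idx,
        minor_count=minor_count,
        minor_freq=minor_freq,
    )


def classify_site(
    site: SiteCounts, filters: FilterConfig, scope: Sequence[int] | None = None,
    caps: np.ndarray | None = None,
) -> SiteClass:
    """Classify a single site (scalar convenience over :func:`classify_sites`).

    Without precomputed ``caps`` the max-coverage cap cannot be estimated
    from one site and is disabled.
    """
    scope = list(range(site.n_pools)) if scope is None else list(scope)
    if not scope:
        raise ValueError("scope must be non-empty")
    if caps is None:
        caps = np.full(len(scope), np.inf)
    matrix = CountMatrix(
        chrom=np.array([site.chrom], dtype=object),
        pos=np.array([site.pos]),
        ref=np.array([site.ref], dtype=object),
        counts=site.counts[None, :, :],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = classify_sites(matrix, filters, scope=scope, caps=caps)
    return SiteClass(
        eligible=bool(table.eligible[0]),
        snp=bool(table.snp[0]),
        major=str(table.major[0]),
        minor=str(table.minor[0]),
        minor_freq=table.minor_freq[0],
    )


def heterozygosity_per_site(combined_counts: np.ndarray) -> np.ndarray:
    """pi_hat per site from combined 4-base counts of shape (n_sites, 4).

    Sites with combined coverage C < 2 are undefined and come back NaN.
    Monomorphic sites give exactly 0.
    """
    counts = np.asarray(combined_counts, dtype=float)
    C = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / C[:, None]
        het = (C / (C - 1.0)) * (1.0 - (freqs**2).sum(axis=1))
    het = np.where(C >= 2, het, np.nan)
    # guard tiny negative round-off on monomorphic sites
    return np.where(np.isnan(het), np.nan, np.maximum(het, 0.0))


def site_heterozygosity(
    site: SiteCounts, scope: Sequence[int] | None = None
) -> float:
    """Per-site pi_hat = C/(C-1) * (1 - sum f_a^2) over the pool scope.

    Counts are summed across the scope pools before the frequencies are
    formed.  Returns NaN (and logs) when combined coverage < 2.
    """
    scope = list(range(site.n_pools)) if scope is None else list(scope)
    combined = site.counts[scope, :4].sum(axis=0)
    val = float(heterozygosity_per_site(combined[None, :])[0])
    if np.isnan(val):
        logger.info(
            "site %s:%d skipped: combined coverage < 2", site.chrom, site.pos
        )
    return val


def merge_pools(
    matrix: CountMatrix,
    pools: Sequence[int],
    label: str = "merged",
    stock: str | None = None,
) -> CountMatrix:
    """Sum counts element-wise across a pool subset into one virtual pool.

    Count conservation is exact; pool chromosome numbers add.  This is how
    the generalized Italian background is formed from the commercial
    Italian-derived stocks.
    """
    pools = list(pools)
    if not pools:
        raise ValueError("cannot merge an empty pool subset")
    merged = matrix.counts[:, pools, :].sum(axis=1, keepdims=True)
    panel = None
    if matrix.panel is not None:
        chroms = sum(matrix.panel.chromosomes[i] for i in pools)
        panel = PoolPanel(
            labels=[label], stocks=[stock or label], chromosomes=[chroms]
        )
    return CountMatrix(
        chrom=matrix.chrom, pos=matrix.pos, ref=matrix.ref, counts=merged, panel=panel
    )


def merge_site(site: SiteCounts, pools: Sequence[int]) -> SiteCounts:
    """Single-site counterpart of :func:`merge_pools`."""
    pools = list(pools)
    if not pools:
        raise ValueError("cannot merge an empty pool subset")
    return SiteCounts(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        counts=site.counts[pools, :].sum(axis=0, keepdims=True),
    )


def merge_by_stock(
    matrix: CountMatrix,
    merge_groups: dict[str, list[str]] | None = None,
) -> CountMatrix:
    """Collapse a pool-level matrix to one virtual pool per stock.

    ``merge_groups`` optionally maps a new stock label to a list of existing
    stock names merged under it (e.g. the generalized Italian group); stocks
    not covered by any group keep their own name.
    """
    if matrix.panel is None:
        raise ValueError("merge_by_stock requires a panel")
    panel = matrix.panel
    group_of: dict[str, str] = {}
    if merge_groups:
        for new, members in merge_groups.items():
            for m in members:
                group_of[m] = new
    targets: dict[str, list[int]] = {}
    for i, stock in enumerate(panel.stocks):
        targets.setdefault(group_of.get(stock, stock), []).append(i)
    labels = list(targets)
    merged = np.stack(
        [matrix.counts[:, idx, :].sum(axis=1) for idx in targets.values()], axis=1
    )
    new_panel = PoolPanel(
        labels=labels,
        stocks=labels,
        chromosomes=[
            sum(panel.chromosomes[i] for i in idx) for idx in targets.values()
        ],
    )
    return CountMatrix(
        chrom=matrix.chrom,
        pos=matrix.pos,
        ref=matrix.ref,
        counts=merged,
        panel=new_panel,
    )
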