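"""Windowed nucleotide diversity (pi) and Watterson's theta.

Window pi is the mean per-site heterozygosity over the window's *eligible*
sites (monomorphic eligible sites contribute 0 to the numerator and 1 to the
denominator).  Watterson's theta per site is

    theta = S / (a_{n-1} * n_eligible),    a_{n-1} = sum_{i=1}^{n-1} 1/i

with S the number of SNP sites in the window and n the number of chromosomes
in the pool (the sampled lineages).  The locus profile partitions a locus
into a fixed number of equal-width nonoverlapping windows (used for the
*csd* sex-determination locus) and smooths per-window pi by local linear
regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CountMatrix
from .sites import FilterConfig, classify_sites, heterozygosity_per_site

__all__ = [
    "WindowStat",
    "LocusProfile",
    "harmonic_number",
    "window_stats",
    "window_pi",
    "window_theta",
    "make_windows",
    "locus_profile",
]


@dataclass
class WindowStat:
    """pi and theta aggregated over one genomic window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_eligible: int
    n_snps: int
    pi: float
    theta: float

    def __post_init__(self) -> None:
        if self.n_snps > self.n_eligible:
            raise ValueError("n_snps cannot exceed n_eligible")


@dataclass
class LocusProfile:
    """Fixed-count equal-width window profile of pi across one locus."""

    chrom: str
    start: int
    end: int
    windows: list[WindowStat]
    midpoints: np.ndarray
    pi: np.ndarray
    smoothed: np.ndarray


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i by direct summation."""
    if n < 1:
        raise ValueError("harmonic number needs n >= 1")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def make_windows(
    chrom: str, start: int, end: int, size: int
) -> list[tuple[str, int, int]]:
    """Tile [start, end) with nonoverlapping windows of ``size`` bp."""
    if size < 1 or start >= end:
        raise ValueError("bad window size or bounds")
    return [
        (chrom, s, min(s + size, end)) for s in range(start, end, size)
    ]


def window_stats(
    matrix: CountMatrix,
    windows: Sequence[tuple[str, int, int]],
    filters: FilterConfig,
    scope: Sequence[int] | None = None,
    n_chromosomes: int | None = None,
    caps: np.ndarray | None = None,
) -> list[WindowStat]:
    """Per-window pi and theta for one stock (pool scope).

    ``windows`` are (chrom, start, end), 0-based half-open, sorted and
    nonoverlapping per chromosome.  ``n_chromosomes`` is the number of
    sampled lineages behind the scope (summed pool chromosomes); required
    for theta and must be >= 2.  Empty windows yield NaN, not zero.
    """
    scope = list(range(matrix.n_pools)) if scope is None else list(scope)
    if n_chromosomes is None:
        if matrix.panel is None:
            raise ValueError("n_chromosomes required when matrix has no panel")
        n_chromosomes = sum(matrix.panel.chromosomes[i] for i in scope)
    if n_chromosomes < 2:
        raise ValueError("theta needs at least 2 chromosomes")
    a_n1 = harmonic_number(n_chromosomes - 1)

    table = classify_sites(matrix, filters, scope=scope, caps=caps)
    combined = matrix.counts[:, scope, :4].sum(axis=1)
    het = heterozygosity_per_site(combined)
    coord = matrix.pos - 1  # site coordinate, 0-based

    out: list[WindowStat] = []
    for chrom, start, end in windows:
        if start >= end:
            raise ValueError(f"bad window {chrom}:{start}-{end}")
        in_win = (matrix.chrom == chrom) & (coord >= start) & (coord < end)
        elig = in_win & table.eligible & ~np.isnan(het)
        n_elig = int(elig.sum())
        n_snps = int((elig & table.snp).sum())
        if n_elig == 0:
            pi = theta = float("nan")
        else:
            pi = float(het[elig].sum() / n_elig)
            theta = float(n_snps / (a_n1 * n_elig))
        out.append(
            WindowStat(
                chrom=chrom,
                start=start,
                end=end,
                n_eligible=n_elig,
                n_snps=n_snps,
                pi=pi,
                theta=theta,
            )
        )
    return out


def window_pi(
    matrix: CountMatrix,
    windows: Sequence[tuple[str, int, int]],
    filters: FilterConfig,
    scope: Sequence[int] | None = None,
    caps: np.ndarray | None = None,
    n_chromosomes: int | None = None,
) -> list[WindowStat]:
    """Windowed pi (theta comes along for free; see :func:`window_stats`)."""
    if n_chromosomes is None and matrix.panel is None:
        n_chromosomes = 2  # pi does not use it; satisfy the theta guard
    return window_stats(
        matrix, windows, filters, scope=scope, n_chromosomes=n_chromosomes, caps=caps
    )


def window_theta(
    matrix: CountMatrix,
    windows: Sequence[tuple[str, int, int]],
    filters: FilterConfig,
    n_chromosomes: int,
    scope: Sequence[int] | None = None,
    caps: np.ndarray | None = None,
) -> list[WindowStat]:
    """Windowed Watterson theta with an explicit lineage count."""
    return window_stats(
        matrix, windows, filters, scope=scope, n_chromosomes=n_chromosomes, caps=caps
    )


def locus_profile(
    matrix: CountMatrix,
    locus: tuple[str, int, int],
    n_windows: int = 250,
    filters: FilterConfig | None = None,
    scope: Sequence[int] | None = None,
    span: float = 0.3,
    caps: np.ndarray | None = None,
) -> LocusProfile:
    """Equal-width nonoverlapping window profile of pi across a locus.

    The locus is split into ``n_windows`` windows of equal width (the last
    absorbs the remainder).  Smoothing is local linear regression (lowess,
    degree 1) over window midpoints with fraction ``span``; windows with no
    eligible sites are left out of the fit and interpolated.
    """
    chrom, start, end = locus
    length = end - start
    if length < n_windows:
        raise ValueError(
            f"locus length {length} < n_windows {n_windows}; "
            "reduce n_windows or widen the locus"
        )
    filters = filters or FilterConfig()
    width = length // n_windows
    bounds = [start + i * width for i in range(n_windows)] + [end]
    windows = [(chrom, bounds[i], bounds[i + 1]) for i in range(n_windows)]
    stats = window_stats(
        matrix, windows, filters, scope=scope, n_chromosomes=2, caps=caps
    )
    mids = np.array([(w.start + w.end) / 2.0 for w in stats])
    pi = np.array([w.pi for w in stats])

    ok = ~np.isnan(pi)
    if ok.sum() >= 2 and np.nanstd(pi) > 0:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(
            pi[ok], mids[ok], frac=span, it=0, return_sorted=False
        )
        smoothed = np.interp(mids, mids[ok], fitted)
    else:
        # constant or degenerate input: the smooth equals the raw values
        smoothed = np.where(ok, pi, np.nan)
        if ok.any():
            smoothed = np.nan_to_num(smoothed, nan=float(pi[ok].mean()))
    return LocusProfile(
        chrom=chrom,
        start=start,
        end=end,
        windows=stats,
        midpoints=mids,
        pi=pi,
        smoothed=smoothed,
    )
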