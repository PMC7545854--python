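"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit Python loops, sort-based
ranks, and a bisection-based normal quantile, so the oracles share no code
path with the vectorised estimators they verify.
"""

from __future__ import annotations

import math


def naive_pi(counts4) -> float:
    """Per-site heterozygosity by direct formula evaluation."""
    counts = [float(c) for c in counts4]
    C = sum(counts)
    if C < 2:
        return float("nan")
    sq = sum((c / C) ** 2 for c in counts)
    return (C / (C - 1.0)) * (1.0 - sq)


def naive_fst(a4, b4) -> float:
    """Classical per-site F_ST: (pi_total - pi_within) / pi_total."""
    pit = naive_pi([x + y for x, y in zip(a4, b4)])
    if not pit > 0:
        return float("nan")
    piw = 0.5 * (naive_pi(a4) + naive_pi(b4))
    return (pit - piw) / pit


def naive_window_pi_theta(site_rows, n_chromosomes: int):
    """(pi, theta, n_eligible, n_snps) from per-site tuples.

    ``site_rows`` is a list of (eligible, snp, counts4) tuples for the sites
    of one window.
    """
    elig = [(s, c) for e, s, c in site_rows if e]
    n_elig = len(elig)
    if n_elig == 0:
        return float("nan"), float("nan"), 0, 0
    total = sum(naive_pi(c) for _, c in elig)
    S = sum(1 for s, _ in elig if s)
    a = sum(1.0 / i for i in range(1, n_chromosomes))
    return total / n_elig, S / (a * n_elig), n_elig, S


def naive_fractional_ranks(values):
    """rank/(N+1) with average ranks for ties, computed by sorting."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # average of 1-based ranks i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return [r / (n + 1.0) for r in ranks]


def norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def norm_quantile(p: float, tol: float = 1e-13) -> float:
    """Standard normal quantile by bisection on the erf-based CDF."""
    lo, hi = -40.0, 40.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if norm_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def naive_css(fst_by_comparison: dict[str, dict]):
    """CSS per SNP from {comparison: {snp: fst}} via the naive primitives.

    Returns {snp: (z_mean, p, css)} over SNPs present in every comparison.
    """
    z: dict[str, dict] = {}
    for name, table in fst_by_comparison.items():
        snps = list(table)
        ranks = naive_fractional_ranks([table[s] for s in snps])
        z[name] = {s: norm_quantile(r) for s, r in zip(snps, ranks)}
    common = set.intersection(*(set(v) for v in z.values()))
    m = len(fst_by_comparison)
    out = {}
    for snp in common:
        zbar = sum(z[name][snp] for name in z) / m
        p = 1.0 - norm_cdf(zbar * math.sqrt(m))
        out[snp] = (zbar, p, -math.log10(p))
    return out
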