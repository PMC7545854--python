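"""Synthetic pooled-sequencing data with known truth.

The generator emulates the statistical structure the analysis assumes:

* an ancestral allele frequency per site drawn from a Beta distribution,
* per-stock frequencies drifted around the ancestral value under the
  Balding–Nichols model, ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with drift
  coefficient ``F``,
* planted "selected" regions in which a designated subset of stocks has its
  frequency shifted (the shared mite-resistance signal),
* two-stage pool-seq read sampling: chromosomes into the pool binomially,
  read depth Poisson, reads binomially at the realized pool frequency, and a
  symmetric per-read sequencing error.

Sites are independent (no linkage); recombination, indels and alignment
artefacts are out of scope.  Every generator is deterministic under a fixed
seed, and :func:`emit_fixtures` writes byte-identical files across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    BASES,
    CountMatrix,
    HaplotypeBlock,
    PoolPanel,
    write_blocks_bed,
    write_sync,
)

__all__ = [
    "SelectedRegion",
    "SimulationConfig",
    "TruthTable",
    "default_study_config",
    "simulate_stock_frequencies",
    "inject_selection",
    "simulate_pool_reads",
    "simulate_blocks",
    "panel_from_config",
    "emit_fixtures",
]

#: Observed haplotype-block length range (bp) the block generator samples from.
BLOCK_LENGTH_RANGE = (287, 17663)

#: Stock labels used when an 8-stock panel is simulated without explicit names.
DEFAULT_STOCK_NAMES = (
    "Italian1",
    "Italian2",
    "Italian3",
    "Carniolan",
    "MinnesotaHygienic",
    "PolLine",
    "Hilo",
    "Russian",
)

#: The four stocks bred for mite/disease resistance (share planted selection).
RESISTANT_STOCKS = ("MinnesotaHygienic", "PolLine", "Hilo", "Russian")
ITALIAN_STOCKS = ("Italian1", "Italian2", "Italian3")


@dataclass(frozen=True)
class SelectedRegion:
    """A genomic interval (0-based half-open, bp) under planted selection."""

    chrom: str
    start: int
    end: int
    freq_shift: float
    stocks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad region bounds {self.start}-{self.end}")
        if not -1.0 <= self.freq_shift <= 1.0:
            raise ValueError("freq_shift must be in [-1, 1]")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic pool-seq genome.

    Defaults mirror the sequencing design of the real study: 8 stocks, 12
    pools per stock (96 pools), pools of 12 diploid workers (24 chromosomes),
    ~30x mean depth per pool.
    """

    n_stocks: int = 8
    pools_per_stock: int = 12
    pool_chromosomes: int = 24
    n_sites: int = 10_000
    depth_mean: float = 30.0
    seq_error: float = 0.001
    drift_F: float = 0.05
    selected_regions: list[SelectedRegion] = field(default_factory=list)
    ancestral_freq_dist: tuple[float, float] = (0.8, 0.8)
    seed: int = 0
    chrom_name: str = "LG1"
    site_spacing: int = 50
    stock_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_stocks < 1 or self.pools_per_stock < 1 or self.n_sites < 1:
            raise ValueError("counts must be positive")
        if self.pool_chromosomes < 2:
            raise ValueError("pool_chromosomes must be >= 2")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.seq_error <= 1.0:
            raise ValueError("seq_error must be a probability")
        if not 0.0 <= self.drift_F < 1.0:
            raise ValueError("drift_F must be in [0, 1)")
        if any(a <= 0 for a in self.ancestral_freq_dist):
            raise ValueError("ancestral Beta shapes must be positive")
        if self.site_spacing < 1:
            raise ValueError("site_spacing must be >= 1")
        if self.stock_names is None:
            if self.n_stocks == len(DEFAULT_STOCK_NAMES):
                self.stock_names = DEFAULT_STOCK_NAMES
            else:
                self.stock_names = tuple(
                    f"stock{i + 1}" for i in range(self.n_stocks)
                )
        if len(self.stock_names) != self.n_stocks:
            raise ValueError("stock_names length must equal n_stocks")
        self._check_regions()

    def _check_regions(self) -> None:
        by_chrom: dict[str, list[SelectedRegion]] = {}
        for r in self.selected_regions:
            unknown = set(r.stocks) - set(self.stock_names)
            if unknown:
                raise ValueError(f"region names unknown stocks {sorted(unknown)}")
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regions in by_chrom.items():
            regions = sorted(regions, key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping selected regions on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    @property
    def span(self) -> int:
        """Total simulated chromosome span in bp (0-based coordinates)."""
        return self.n_sites * self.site_spacing

    def positions(self) -> np.ndarray:
        """1-based site positions, evenly spaced ``site_spacing`` bp apart."""
        return 1 + np.arange(self.n_sites, dtype=np.int64) * self.site_spacing


@dataclass
class TruthTable:
    """Ground truth per simulated site, for parameter-recovery tests."""

    chrom: np.ndarray  # (n_sites,)
    pos: np.ndarray  # 1-based
    ref: np.ndarray  # reference (ancestral-major) base per site
    alt: np.ndarray  # alternate base per site
    ancestral_freq: np.ndarray  # (n_sites,) alt-allele frequency
    stock_freq: np.ndarray  # (n_sites, n_stocks) alt-allele frequency
    selected: np.ndarray  # (n_sites,) bool
    stock_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.stock_freq.shape != (len(self.pos), len(self.stock_names)):
            raise ValueError("stock_freq shape mismatch")
        for arr in (self.ancestral_freq, self.stock_freq):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("frequencies must be in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def copy(self) -> "TruthTable":
        return TruthTable(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            ancestral_freq=self.ancestral_freq.copy(),
            stock_freq=self.stock_freq.copy(),
            selected=self.selected.copy(),
            stock_names=self.stock_names,
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "ancestral_freq": self.ancestral_freq,
                "selected": self.selected.astype(int),
            }
        )
        for j, name in enumerate(self.stock_names):
            df[f"freq_{name}"] = self.stock_freq[:, j]
        return df


def default_study_config(
    seed: int = 0,
    n_sites: int = 50_000,
    selected_fraction: float = 0.01,
    n_regions: int = 5,
    freq_shift: float = 0.4,
    drift_F: float = 0.05,
) -> SimulationConfig:
    """The default synthetic study: 8 stocks, planted selection shared by the
    four resistance-bred stocks covering ``selected_fraction`` of sites."""
    spacing = 50
    sites_per_region = max(1, int(round(n_sites * selected_fraction / n_regions)))
    region_len = sites_per_region * spacing
    stride = n_sites * spacing // n_regions
    regions = [
        SelectedRegion(
            chrom="LG1",
            start=i * stride + stride // 3,
            end=i * stride + stride // 3 + region_len,
            freq_shift=freq_shift,
            stocks=RESISTANT_STOCKS,
        )
        for i in range(n_regions)
    ]
    return SimulationConfig(
        n_sites=n_sites,
        drift_F=drift_F,
        selected_regions=regions,
        seed=seed,
        site_spacing=spacing,
    )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage, all rooted at config.seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_stock_frequencies(config: SimulationConfig) -> TruthTable:
    """Draw ancestral and per-stock allele frequencies.

    Ancestral frequency p ~ Beta(ancestral_freq_dist); each stock's frequency
    is a Balding–Nichols draw Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p
    and variance F p (1-p).  F = 0 short-circuits to the ancestral value
    exactly (no division by zero).
    """
    rng = _rng(config, 0)
    n, k = config.n_sites, config.n_stocks
    p = rng.beta(*config.ancestral_freq_dist, size=n)
    F = config.drift_F
    if F == 0.0:
        stock = np.tile(p[:, None], (1, k))
    else:
        scale = (1.0 - F) / F
        a = np.clip(p * scale, 1e-12, None)
        b = np.clip((1.0 - p) * scale, 1e-12, None)
        stock = rng.beta(a[:, None], b[:, None], size=(n, k))
    # ref/alt base identities per site (ref is the ancestral-major base)
    ref_idx = rng.integers(0, 4, size=n)
    alt_offset = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_offset) % 4
    bases = np.array(list(BASES), dtype=object)
    return TruthTable(
        chrom=np.array([config.chrom_name] * n, dtype=object),
        pos=config.positions(),
        ref=bases[ref_idx],
        alt=bases[alt_idx],
        ancestral_freq=p,
        stock_freq=stock,
        selected=np.zeros(n, dtype=bool),
        stock_names=tuple(config.stock_names),
    )


def inject_selection(truth: TruthTable, config: SimulationConfig) -> TruthTable:
    """Shift affected stocks' frequencies inside each selected region.

    Shifts are clipped to [0, 1]; unaffected stocks are untouched; the
    per-site selected flag is set.  A region with ``freq_shift == 0`` is a
    no-op.  Regions must lie within the simulated coordinates.
    """
    out = truth.copy()
    name_to_col = {s: j for j, s in enumerate(truth.stock_names)}
    for region in config.selected_regions:
        chrom_mask = out.chrom == region.chrom
        if not chrom_mask.any():
            raise ValueError(
                f"selected region on {region.chrom!r} outside simulated chromosomes"
            )
        if region.end > config.span:
            raise ValueError(
                f"selected region [{region.start},{region.end}) extends beyond "
                f"the simulated span ({config.span} bp)"
            )
        if region.freq_shift == 0.0:
            continue
        coord = out.pos - 1  # 1-based position -> 0-based coordinate
        mask = chrom_mask & (coord >= region.start) & (coord < region.end)
        cols = [name_to_col[s] for s in region.stocks]
        shifted = out.stock_freq[np.ix_(mask, cols)] + region.freq_shift
        out.stock_freq[np.ix_(mask, cols)] = np.clip(shifted, 0.0, 1.0)
        out.selected |= mask
    return out


def _split_three_ways(rng: np.random.Generator, n: np.ndarray) -> tuple[np.ndarray, ...]:
    """Multinomial(n; 1/3,1/3,1/3) via successive binomials (vectorised)."""
    n1 = rng.binomial(n, 1.0 / 3.0)
    n2 = rng.binomial(n - n1, 0.5)
    return n1, n2, n - n1 - n2


def simulate_pool_reads(
    truth: TruthTable, config: SimulationConfig
) -> CountMatrix:
    """Sample sync-compatible read counts for every pool at every site.

    Per pool and site: the pool's alternate-allele count is Binomial
    (pool_chromosomes, stock frequency); depth is Poisson(depth_mean); read
    alternate counts are Binomial(depth, realized pool frequency); finally
    each read is flipped to a uniformly chosen other base with probability
    seq_error.
    """
    rng = _rng(config, 1)
    n = truth.n_sites
    n_pools = config.n_stocks * config.pools_per_stock
    stock_of_pool = np.repeat(np.arange(config.n_stocks), config.pools_per_stock)

    f = truth.stock_freq[:, stock_of_pool]  # (n_sites, n_pools)
    pool_alt = rng.binomial(config.pool_chromosomes, f)
    pool_freq = pool_alt / config.pool_chromosomes
    depth = rng.poisson(config.depth_mean, size=(n, n_pools))
    alt_reads = rng.binomial(depth, pool_freq)
    ref_reads = depth - alt_reads

    e = config.seq_error
    if e > 0:
        kept_ref = rng.binomial(ref_reads, 1.0 - e)
        kept_alt = rng.binomial(alt_reads, 1.0 - e)
        err_ref = _split_three_ways(rng, ref_reads - kept_ref)
        err_alt = _split_three_ways(rng, alt_reads - kept_alt)
    else:
        kept_ref, kept_alt = ref_reads, alt_reads
        zeros = np.zeros_like(ref_reads)
        err_ref = err_alt = (zeros, zeros, zeros)

    base_index = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.array([base_index[b] for b in truth.ref])
    alt_idx = np.array([base_index[b] for b in truth.alt])

    counts = np.zeros((n, n_pools, 6), dtype=np.int64)
    for b in range(4):
        others = [x for x in range(4) if x != b]
        m = ref_idx == b
        if m.any():
            counts[m, :, b] += kept_ref[m]
            for j, ob in enumerate(others):
                counts[m, :, ob] += err_ref[j][m]
        m = alt_idx == b
        if m.any():
            counts[m, :, b] += kept_alt[m]
            for j, ob in enumerate(others):
                counts[m, :, ob] += err_alt[j][m]

    panel = panel_from_config(config)
    return CountMatrix(
        chrom=truth.chrom.copy(),
        pos=truth.pos.copy(),
        ref=truth.ref.copy(),
        counts=counts,
        panel=panel,
    )


def panel_from_config(config: SimulationConfig) -> PoolPanel:
    """The pool panel implied by a simulation config."""
    labels, stocks = [], []
    for name in config.stock_names:
        for p in range(config.pools_per_stock):
            labels.append(f"{name}_p{p + 1:02d}")
            stocks.append(name)
    return PoolPanel(
        labels=labels,
        stocks=stocks,
        chromosomes=[config.pool_chromosomes] * len(labels),
    )


def simulate_blocks(
    config: SimulationConfig,
    min_gap: int = 0,
    max_gap: int = 1000,
) -> list[HaplotypeBlock]:
    """Tile the simulated chromosome with haplotype blocks.

    Block lengths are sampled uniformly from the observed real-data range
    (287–17,663 bp); gaps between consecutive blocks are uniform in
    [min_gap, max_gap].
    """
    rng = _rng(config, 2)
    lo, hi = BLOCK_LENGTH_RANGE
    blocks: list[HaplotypeBlock] = []
    pos = 0
    i = 0
    while pos + lo <= config.span:
        length = int(rng.integers(lo, hi + 1))
        end = min(pos + length, config.span)
        if end - pos >= lo:
            i += 1
            blocks.append(
                HaplotypeBlock(
                    chrom=config.chrom_name,
                    start=pos,
                    end=end,
                    block_id=f"HB{i:05d}",
                )
            )
        pos = end + int(rng.integers(min_gap, max_gap + 1))
    return blocks


def simulate_dataset(config: SimulationConfig) -> tuple[TruthTable, CountMatrix]:
    """Frequencies -> planted selection -> pool reads, in one call."""
    truth = inject_selection(simulate_stock_frequencies(config), config)
    return truth, simulate_pool_reads(truth, config)


def emit_fixtures(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full generator and write the four fixture files.

    Writes ``counts.sync``, ``blocks.bed``, ``truth.tsv`` and ``config.json``
    (which embeds the derived pool panel).  Byte-identical across runs at a
    fixed seed.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc

    truth, matrix = simulate_dataset(config)
    blocks = simulate_blocks(config)
    panel = matrix.panel

    paths = {
        "sync": out_dir / "counts.sync",
        "blocks": out_dir / "blocks.bed",
        "truth": out_dir / "truth.tsv",
        "config": out_dir / "config.json",
    }
    write_sync(matrix.to_records(), paths["sync"])
    write_blocks_bed(blocks, paths["blocks"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")

    cfg = dataclasses.asdict(config)
    cfg["selected_regions"] = [dataclasses.asdict(r) for r in config.selected_regions]
    for r in cfg["selected_regions"]:
        r["stocks"] = list(r["stocks"])
    cfg["stock_names"] = list(config.stock_names)
    cfg["panel"] = {
        "pool": panel.labels,
        "stock": panel.stocks,
        "chromosomes": panel.chromosomes,
    }
    try:
        with open(paths["config"], "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed writing {paths['config']}: {exc}") from exc
    return paths
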