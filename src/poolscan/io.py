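"""Readers and writers for the formats the pipeline touches.

The canonical count format is the Popoolation2 "sync" dialect: one line per
genomic site, tab-separated ``chrom  pos  ref`` followed by one
``A:T:C:G:N:del`` count column per pool.  Haplotype blocks come in as BED
(0-based, half-open); per-pool allele frequencies may optionally be pulled
from a VCF with per-sample ``AD`` or ``AF`` fields.

Coordinates are 1-based in sync/VCF and 0-based half-open in BED.  Conversion
happens only at module boundaries and is property-tested.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "BASE_INDEX",
    "SYNC_FIELD_ORDER",
    "SiteCounts",
    "PoolPanel",
    "HaplotypeBlock",
    "CountMatrix",
    "SyncFormatError",
    "BedFormatError",
    "UnsupportedVcfError",
    "read_sync",
    "write_sync",
    "read_blocks_bed",
    "write_blocks_bed",
    "read_vcf_frequencies",
    "read_panel",
    "write_panel",
]

#: The four nucleotides in sync column order.
BASES = "ATCG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: Full sync count-field order (Popoolation2 convention).
SYNC_FIELD_ORDER = ("A", "T", "C", "G", "N", "del")


class SyncFormatError(ValueError):
    """Raised on a malformed sync line; message carries path and line number."""


class BedFormatError(ValueError):
    """Raised on a malformed BED line."""


class UnsupportedVcfError(ValueError):
    """Raised when a VCF carries neither per-sample AD nor AF."""


@dataclass
class SiteCounts:
    """Per-pool nucleotide read counts at one genomic site (one sync row).

    ``counts`` has shape ``(n_pools, 6)`` in A:T:C:G:N:del order.  Coverage is
    the sum of the four nucleotide counts only — N and deletion calls do not
    contribute to the estimators downstream.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6)")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-pool coverage: A+T+C+G (N/del excluded)."""
        return self.counts[:, :4].sum(axis=1)

    def pool_frequency(self, base: str, pool: int) -> float:
        """Frequency of ``base`` among the four nucleotides in one pool."""
        cov = int(self.coverage[pool])
        if cov == 0:
            return float("nan")
        return float(self.counts[pool, BASE_INDEX[base]]) / cov


@dataclass
class PoolPanel:
    """Ordered pool labels with stock membership and pool haploid sizes.

    Each sync column maps positionally to one panel entry.  ``chromosomes``
    is the number of chromosomes per pool (2 x pooled diploid individuals;
    the study design is pools of 12 workers, i.e. 24 chromosomes).
    """

    labels: list[str]
    stocks: list[str]
    chromosomes: list[int]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.stocks) == len(self.chromosomes)):
            raise ValueError("labels, stocks and chromosomes must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("pool labels must be unique")
        if any(c < 2 for c in self.chromosomes):
            raise ValueError("each pool must carry at least 2 chromosomes")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def stock_names(self) -> list[str]:
        """Unique stock names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.stocks:
            seen.setdefault(s)
        return list(seen)

    def pools_of(self, stock: str) -> list[int]:
        idx = [i for i, s in enumerate(self.stocks) if s == stock]
        if not idx:
            raise KeyError(f"no pools for stock {stock!r}")
        return idx


@dataclass(order=True)
class HaplotypeBlock:
    """A genomic interval (0-based, half-open) grouping SNPs for annotation."""

    chrom: str
    start: int
    end: int
    block_id: str = field(default="", compare=False)
    snp_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"block {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.start < 0:
            raise ValueError("block start must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Membership of a SNP position: ``start <= pos < end``.

        Positions at the half-open block end are excluded.
        """
        return self.start <= pos < self.end


@dataclass
class CountMatrix:
    """Dense in-memory container for a whole sync table.

    ``counts`` has shape ``(n_sites, n_pools, 6)``; rows follow file order.
    The streaming :func:`read_sync` contract stays record-at-a-time; this
    container exists for the vectorised estimators.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int64, 1-based
    ref: np.ndarray  # (n_sites,) str
    counts: np.ndarray  # (n_sites, n_pools, 6)
    panel: PoolPanel | None = None

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        """(n_sites, n_pools) coverage matrix (A+T+C+G)."""
        return self.counts[:, :, :4].sum(axis=2)

    @classmethod
    def from_records(
        cls, records: Iterable[SiteCounts], panel: PoolPanel | None = None
    ) -> "CountMatrix":
        chroms, poss, refs, counts = [], [], [], []
        for rec in records:
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            counts.append(rec.counts)
        if counts:
            arr = np.stack(counts).astype(np.int64)
        else:
            n_pools = len(panel) if panel is not None else 0
            arr = np.zeros((0, n_pools, 6), dtype=np.int64)
        return cls(
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            counts=arr,
            panel=panel,
        )

    @classmethod
    def from_sync(cls, path: str | Path, panel: PoolPanel | None = None) -> "CountMatrix":
        return cls.from_records(read_sync(path, panel), panel)

    def to_records(self) -> Iterator[SiteCounts]:
        for i in range(self.n_sites):
            yield SiteCounts(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=self.counts[i],
            )

    def subset_pools(self, pools: Sequence[int], panel: PoolPanel | None = None) -> "CountMatrix":
        return replace(self, counts=self.counts[:, list(pools), :], panel=panel)


def _parse_count_field(field_str: str) -> list[int]:
    parts = field_str.split(":")
    if len(parts) != 6:
        raise ValueError(f"expected 6 ':'-separated counts, got {field_str!r}")
    return [int(p) for p in parts]


def read_sync(
    path: str | Path, panel: PoolPanel | None = None
) -> Iterator[SiteCounts]:
    """Stream a sync file as :class:`SiteCounts` records in file order.

    If ``panel`` is given, the number of count columns must equal the panel
    size on every line.  Malformed lines raise :class:`SyncFormatError` with
    the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncFormatError(
                    f"{path}:{lineno}: expected >= 4 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            if panel is not None and len(fields) - 3 != len(panel):
                raise SyncFormatError(
                    f"{path}:{lineno}: {len(fields) - 3} count columns "
                    f"but panel has {len(panel)} pools"
                )
            try:
                pos = int(pos_s)
                counts = np.array(
                    [_parse_count_field(f) for f in fields[3:]], dtype=np.int64
                )
                rec = SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)
            except ValueError as exc:
                raise SyncFormatError(f"{path}:{lineno}: {exc}") from exc
            yield rec


def write_sync(records: Iterable[SiteCounts], path: str | Path) -> Path:
    """Write records as a sync file; exact inverse of :func:`read_sync`."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            for rec in records:
                cols = "\t".join(
                    ":".join(str(int(c)) for c in pool) for pool in rec.counts
                )
                fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{cols}\n")
    except OSError as exc:
        raise OSError(f"failed writing sync file {path}: {exc}") from exc
    return path


def read_blocks_bed(path: str | Path) -> list[HaplotypeBlock]:
    """Read haplotype blocks from a BED3+ file, sorted by (chrom, start).

    Overlapping blocks are accepted and passed through unmerged.  A fourth
    column, if present, becomes the block id.
    """
    path = Path(path)
    blocks: list[HaplotypeBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                block = HaplotypeBlock(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    block_id=fields[3] if len(fields) > 3 else f"block{lineno}",
                )
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
            blocks.append(block)
    blocks.sort(key=lambda b: (b.chrom, b.start, b.end))
    return blocks


def write_blocks_bed(blocks: Iterable[HaplotypeBlock], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\n")
    return path


def read_panel(path: str | Path) -> PoolPanel:
    """Read a pool panel TSV with header columns pool/stock/chromosomes."""
    df = pd.read_csv(path, sep="\t")
    required = {"pool", "stock", "chromosomes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns: {sorted(missing)}")
    return PoolPanel(
        labels=[str(x) for x in df["pool"]],
        stocks=[str(x) for x in df["stock"]],
        chromosomes=[int(x) for x in df["chromosomes"]],
    )


def write_panel(panel: PoolPanel, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"pool": panel.labels, "stock": panel.stocks, "chromosomes": panel.chromosomes}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_vcf_frequencies(path: str | Path, panel: PoolPanel | None = None) -> pd.DataFrame:
    """Extract per-pool alternate-allele frequencies from a VCF 4.x file.

    Per-sample ``AD`` (allelic depths, ref first) is preferred; ``AF`` is
    passed through when ``AD`` is absent.  Missing sample fields become NaN —
    never fabricated.  Returns a DataFrame indexed by (chrom, pos) with one
    column per sample.

    Raises :class:`UnsupportedVcfError` when the VCF defines neither field.
    """
    import pysam

    path = Path(path)
    vcf = pysam.VariantFile(str(path))
    fmts = set(vcf.header.formats.keys())
    if "AD" not in fmts and "AF" not in fmts:
        raise UnsupportedVcfError(
            f"{path}: VCF defines neither FORMAT/AD nor FORMAT/AF"
        )
    samples = list(vcf.header.samples)
    if panel is not None and samples != list(panel.labels):
        raise ValueError(
            f"{path}: VCF samples {samples} do not match panel pools {panel.labels}"
        )
    index, rows = [], []
    for rec in vcf:
        freqs = []
        for s in samples:
            sample = rec.samples[s]
            ad = sample.get("AD")
            if ad is not None and ad[0] is not None:
                total = sum(ad)
                freqs.append(float(ad[1]) / total if total > 0 else np.nan)
                continue
            af = sample.get("AF")
            if af is not None:
                af_val = af[0] if isinstance(af, tuple) else af
                if af_val is not None:
                    freqs.append(float(af_val))
                    continue
            freqs.append(np.nan)
        index.append((rec.chrom, rec.pos))
        rows.append(freqs)
    vcf.close()
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"]),
        columns=samples,
        dtype=float,
    )
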