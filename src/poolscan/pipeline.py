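"""End-to-end orchestration: simulate/load -> diversity -> F_ST -> structure -> CSS.

Stages run in dependency order; every output TSV is listed in a JSON
manifest together with its SHA-256 hash, the stage that produced it and the
resolved parameters, so a rerun with the same config and seed reproduces
identical files.  Outputs are written to a ``.partial`` path first and
renamed on completion; a failing stage aborts the run with its name, leaving
any in-progress file with the ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from itertools import combinations
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import css as css_mod
from . import diversity as div_mod
from . import fst as fst_mod
from . import structure as struct_mod
from .config import ConfigError, RunConfig
from .io import CountMatrix, read_blocks_bed, read_panel, write_panel
from .sites import FilterConfig, classify_sites, merge_by_stock
from .simulate import (
    SimulationConfig,
    default_study_config,
    simulate_blocks,
    simulate_dataset,
)

__all__ = ["run_pipeline", "StageError", "pool_frequency_matrix"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    partial = path.with_suffix(path.suffix + ".partial")
    df.to_csv(partial, sep="\t", index=index, float_format="%.10g")
    partial.replace(path)
    return path


def pool_frequency_matrix(
    matrix: CountMatrix, stock_matrix: CountMatrix, filters: FilterConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minor-allele frequency matrices at SNP sites.

    SNPs and the minor allele are defined on the stock-level matrix (all
    stocks in scope); returns (pools x SNPs, stocks x SNPs) frequency
    frames.  Zero-coverage entries are missing (NaN), never fabricated.
    """
    cls = classify_sites(stock_matrix, filters)
    snp = cls.snp
    rows = np.flatnonzero(snp)
    minor = cls.minor_idx[snp]
    cols = pd.MultiIndex.from_arrays(
        [stock_matrix.chrom[snp], stock_matrix.pos[snp]], names=["chrom", "pos"]
    )

    def freqs(m: CountMatrix) -> pd.DataFrame:
        counts4 = m.counts[rows][:, :, :4]
        cov = counts4.sum(axis=2).astype(float)
        minor_counts = counts4[np.arange(len(rows)), :, minor[: len(rows)]]
        # advanced indexing puts the site axis first: (n_snps, n_pools)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = minor_counts / np.where(cov > 0, cov, np.nan)
        labels = m.panel.labels if m.panel is not None else list(range(m.n_pools))
        return pd.DataFrame(f.T, index=labels, columns=cols)

    return freqs(matrix), freqs(stock_matrix)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written
    to ``out_dir/manifest.json``)."""
    config.validate_inputs()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filters = FilterConfig(
        min_coverage=config.filters.min_coverage,
        min_count=config.filters.min_count,
        min_quality=config.filters.min_quality,
        max_cov_percentile=config.filters.max_cov_percentile,
    )
    manifest: dict = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": [],
        "outputs": [],
    }
    outputs: list[tuple[str, Path]] = []

    def run_stage(name: str, fn: Callable[[], list[Path]]) -> None:
        t0 = time.monotonic()
        logger.info("stage %s: start", name)
        try:
            paths = fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "seconds": round(time.monotonic() - t0, 3)}
        )
        outputs.extend((name, p) for p in paths)
        logger.info("stage %s: done (%d outputs)", name, len(paths))

    # ---- input stage: simulate or load --------------------------------
    blocks = None
    if config.simulate is not None:
        sim_cfg = default_study_config(
            seed=config.seed,
            n_sites=config.simulate.n_sites,
            selected_fraction=config.simulate.selected_fraction,
            n_regions=config.simulate.n_regions,
            freq_shift=config.simulate.freq_shift,
            drift_F=config.simulate.drift_F,
        )
        sim_cfg.depth_mean = config.simulate.depth_mean
        sim_cfg.seq_error = config.simulate.seq_error
        holder: dict = {}

        def _simulate() -> list[Path]:
            truth, matrix = simulate_dataset(sim_cfg)
            holder["truth"], holder["matrix"] = truth, matrix
            holder["blocks"] = (
                read_blocks_bed(config.blocks)
                if config.blocks is not None
                else simulate_blocks(sim_cfg)
            )
            p_panel = out_dir / "panel.tsv"
            write_panel(matrix.panel, p_panel)
            p_truth = out_dir / "truth.tsv"
            _write_tsv(truth.to_frame(), p_truth)
            return [p_panel, p_truth]

        run_stage("simulate", _simulate)
        truth, matrix = holder["truth"], holder["matrix"]
        blocks = holder["blocks"]
    else:
        panel = read_panel(config.panel)
        matrix = CountMatrix.from_sync(config.sync, panel)
        truth = None
        if config.blocks is not None:
            blocks = read_blocks_bed(config.blocks)

    # ---- stock-level matrices -----------------------------------------
    panel_stocks = matrix.panel.stock_names
    italians = [s for s in config.italian_stocks if s in panel_stocks]
    stock_matrix = merge_by_stock(matrix)
    merged_matrix = (
        merge_by_stock(matrix, {config.italian_label: italians})
        if italians
        else stock_matrix
    )
    analysis_stocks = merged_matrix.panel.labels

    results: dict = {"matrix": matrix, "stock_matrix": stock_matrix,
                     "merged_matrix": merged_matrix, "truth": truth}

    # ---- diversity -----------------------------------------------------
    if "diversity" in config.stages:

        def _diversity() -> list[Path]:
            span = int(matrix.pos.max())
            rows = []
            for stock in stock_matrix.panel.labels:
                i = stock_matrix.panel.labels.index(stock)
                windows = div_mod.make_windows(
                    str(matrix.chrom[0]), 0, span, config.window_size
                )
                stats = div_mod.window_stats(
                    stock_matrix, windows, filters, scope=[i],
                    n_chromosomes=stock_matrix.panel.chromosomes[i],
                )
                for w in stats:
                    rows.append(
                        {
                            "stock": stock, "chrom": w.chrom, "start": w.start,
                            "end": w.end, "n_eligible": w.n_eligible,
                            "n_snps": w.n_snps, "pi": w.pi, "theta": w.theta,
                        }
                    )
            df = pd.DataFrame(rows)
            results["diversity"] = df
            return [_write_tsv(df, out_dir / "diversity.tsv")]

        run_stage("diversity", _diversity)

    # ---- pairwise F_ST -------------------------------------------------
    if "fst" in config.stages or "css" in config.stages:

        def _fst() -> list[Path]:
            tables = fst_mod.pairwise_scan(merged_matrix, filters=filters)
            results["fst_tables"] = tables
            paths = []
            for key, t in tables.items():
                p = out_dir / f"fst_{t.stock_a}_{t.stock_b}.tsv"
                paths.append(_write_tsv(t.table, p))
            mat = fst_mod.summary_matrix(
                tables, analysis_stocks, config.fixed_threshold
            )
            results["fst_summary"] = mat
            paths.append(_write_tsv(mat, out_dir / "fst_summary.tsv", index=True))

            specific_rows = []
            for q in config.top_q:
                tops = {k: fst_mod.top_quantile(t, q) for k, t in tables.items()}
                specific = fst_mod.stock_specific_snps(tops, analysis_stocks)
                results[f"stock_specific_q{q}"] = specific
                for stock, snps in specific.items():
                    for chrom, pos in snps:
                        specific_rows.append(
                            {"q": q, "stock": stock, "chrom": chrom, "pos": pos}
                        )
            df = pd.DataFrame(
                specific_rows, columns=["q", "stock", "chrom", "pos"]
            )
            paths.append(_write_tsv(df, out_dir / "stock_specific_snps.tsv"))
            return paths

        run_stage("fst", _fst)

    # ---- structure -----------------------------------------------------
    if "structure" in config.stages:

        def _structure() -> list[Path]:
            pool_freq, stock_freq = pool_frequency_matrix(
                matrix, stock_matrix, filters
            )
            res = struct_mod.cluster_stocks(
                pool_freq,
                stock_freq=stock_freq,
                min_freq=config.min_freq,
                k_range=range(config.k_min, config.k_max + 1),
                restarts=config.restarts,
                seed=config.seed,
                n_pcs=config.n_pcs,
            )
            results["structure"] = res
            coords = res.coords.copy()
            coords.insert(0, "pool", coords.index)
            coords["cluster"] = res.labels
            paths = [
                _write_tsv(coords, out_dir / "pca_coordinates.tsv"),
                _write_tsv(
                    pd.DataFrame(
                        {
                            "pc": np.arange(1, len(res.explained_variance_ratio) + 1),
                            "explained_variance_fraction": res.explained_variance_ratio,
                        }
                    ),
                    out_dir / "pca_variance.tsv",
                ),
                _write_tsv(
                    pd.DataFrame(
                        {"k": list(res.aic), "aic": list(res.aic.values())}
                    ),
                    out_dir / "kmeans_aic.tsv",
                ),
            ]
            return paths

        run_stage("structure", _structure)

    # ---- CSS -----------------------------------------------------------
    if "css" in config.stages:

        def _css() -> list[Path]:
            tables = results["fst_tables"]
            comparisons = {}
            for s in config.resistant_stocks:
                key = frozenset((s, config.italian_label))
                if key not in tables:
                    raise ValueError(
                        f"comparison {s} vs {config.italian_label} unavailable"
                    )
                comparisons[s] = tables[key].table
            res = css_mod.compute_css(comparisons)
            results["css"] = res
            outliers = css_mod.top_css(res, q=config.css_q)
            results["css_outliers"] = outliers
            all_snps = set(res.table.index)
            enriched = css_mod.map_to_blocks(
                outliers, all_snps, blocks, min_snps=config.min_block_snps
            )
            results["enriched_blocks"] = enriched
            css_df = res.table.reset_index()
            block_df = pd.DataFrame(
                {
                    "Chr": [e.block.chrom for e in enriched],
                    "Starts": [e.block.start for e in enriched],
                    "Ends": [e.block.end for e in enriched],
                    "SNPcount": [e.snp_count for e in enriched],
                    "outlier_count": [e.outlier_count for e in enriched],
                    "reported": [int(e.reported) for e in enriched],
                }
            )
            return [
                _write_tsv(css_df, out_dir / "css.tsv"),
                _write_tsv(block_df, out_dir / "enriched_blocks.tsv"),
            ]

        run_stage("css", _css)

    manifest["outputs"] = [
        {"stage": stage, "path": str(p), "sha256": _sha256(p)}
        for stage, p in outputs
    ]
    partial = out_dir / "manifest.json.partial"
    with open(partial, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    partial.replace(out_dir / "manifest.json")
    manifest["results"] = results
    return manifest
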