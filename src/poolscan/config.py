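"""Run configuration: a single structured file with every analysis default.

All thresholds used by the stages live here, never hard-coded inside them:
site filters (min coverage 20, min count 10, Q20, 98th-percentile coverage
cap), the fixed-differentiation threshold 0.65, the top-quantile pair
(1.0%, 0.1%), the CSS outlier quantile 0.1%, the cluster range 1-10, and
the 250-window locus profile.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .simulate import ITALIAN_STOCKS, RESISTANT_STOCKS

__all__ = ["ConfigError", "RunConfig", "FilterSettings", "SimSettings", "validate_config"]


class ConfigError(ValueError):
    """Aggregated configuration problems, one message per line."""


class FilterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_coverage: int = Field(default=20, ge=1)
    min_count: int = Field(default=10, ge=1)
    min_quality: int = Field(default=20, ge=0)
    max_cov_percentile: float = Field(default=98.0, gt=0, le=100)


class SimSettings(BaseModel):
    """Synthetic-data stage settings (used when no sync input is given)."""

    model_config = ConfigDict(extra="forbid")

    n_sites: int = Field(default=50_000, ge=1)
    depth_mean: float = Field(default=30.0, gt=0)
    drift_F: float = Field(default=0.05, ge=0, lt=1)
    seq_error: float = Field(default=0.001, ge=0, le=1)
    selected_fraction: float = Field(default=0.01, ge=0, le=1)
    n_regions: int = Field(default=5, ge=0)
    freq_shift: float = Field(default=0.4, ge=-1, le=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sync: Path | None = None
    panel: Path | None = None
    blocks: Path | None = None
    out_dir: Path = Path("poolscan_out")
    seed: int = 0

    filters: FilterSettings = Field(default_factory=FilterSettings)
    simulate: SimSettings | None = None

    italian_stocks: list[str] = Field(default_factory=lambda: list(ITALIAN_STOCKS))
    italian_label: str = "Italian"
    resistant_stocks: list[str] = Field(default_factory=lambda: list(RESISTANT_STOCKS))

    window_size: int = Field(default=10_000, ge=1)
    locus_windows: int = Field(default=250, ge=1)
    fixed_threshold: float = Field(default=0.65, gt=0)
    top_q: list[float] = Field(default_factory=lambda: [0.01, 0.001])
    css_q: float = Field(default=0.001, gt=0, le=1)
    min_block_snps: int = Field(default=5, ge=0)
    min_freq: float = Field(default=0.1, ge=0, lt=1)
    k_min: int = Field(default=1, ge=1)
    k_max: int = Field(default=10, ge=1)
    restarts: int = Field(default=25, ge=1)
    n_pcs: int | None = None

    stages: list[str] = Field(
        default_factory=lambda: ["diversity", "fst", "structure", "css"]
    )

    @field_validator("top_q")
    @classmethod
    def _check_q(cls, v: list[float]) -> list[float]:
        for q in v:
            if not 0 < q <= 1:
                raise ValueError(f"top_q values must be in (0, 1], got {q}")
        return v

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v: list[str]) -> list[str]:
        known = {"diversity", "fst", "structure", "css"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; known: {sorted(known)}")
        return v

    def validate_inputs(self) -> None:
        """Fail-fast existence checks before any stage runs."""
        problems: list[str] = []
        if self.simulate is None:
            if self.sync is None or self.panel is None:
                problems.append(
                    "either a 'simulate' block or both 'sync' and 'panel' inputs are required"
                )
            for name in ("sync", "panel"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    problems.append(f"{name} file not found: {p}")
        if "css" in self.stages:
            if self.blocks is None and self.simulate is None:
                problems.append("css stage enabled but no blocks BED provided")
            if self.blocks is not None and not Path(self.blocks).exists():
                problems.append(f"blocks file not found: {self.blocks}")
        if self.k_max < self.k_min:
            problems.append("k_max must be >= k_min")
        if problems:
            raise ConfigError("\n".join(problems))


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML run config; all defaults resolved.

    An empty (or absent) file resolves every analysis default.  Unknown
    keys and type mismatches are aggregated into one :class:`ConfigError`.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: config must be a mapping")
            data = loaded
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("\n".join(lines)) from exc
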