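"""Run configuration: a validated, fully-defaulted description of a workflow.

The config file is YAML.  Unknown keys are rejected, referenced paths must
exist at validation time, and every applied default is echoed into the run
manifest so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .enrichment import (
    DEFAULT_FC_CUTOFF,
    DEFAULT_MAX_SET_SIZE,
    DEFAULT_MIN_SET_SIZE,
    DEFAULT_P_CUTOFF,
)
from .errors import ValidationError
from .pathnet import DEFAULT_JACCARD_THRESHOLD, DEFAULT_METRIC

__all__ = ["RunConfig", "EnrichmentParams", "NetworkParams", "PathnetParams",
           "VizParams", "validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnrichmentParams(_Strict):
    method: str = "ora"
    split: bool = True
    p_cutoff: float = Field(DEFAULT_P_CUTOFF, gt=0, le=1)
    fc_cutoff: float = Field(DEFAULT_FC_CUTOFF, gt=0)
    use_adjusted: bool = True
    min_set_size: int = Field(DEFAULT_MIN_SET_SIZE, ge=1)
    max_set_size: int = Field(DEFAULT_MAX_SET_SIZE, ge=1)
    universe: str = "measured"

    @field_validator("method")
    @classmethod
    def _method(cls, v: str) -> str:
        if v not in ("ora", "gene_pair_ora", "gsea"):
            raise ValueError(f"unknown enrichment method {v!r}")
        return v


class NetworkParams(_Strict):
    order: str = "zero"
    hub_measure: str = "betweenness"
    top_n_hubs: int | None = None

    @field_validator("order")
    @classmethod
    def _order(cls, v: str) -> str:
        if v not in ("zero", "first", "minimum"):
            raise ValueError(f"unknown network order {v!r}")
        return v


class PathnetParams(_Strict):
    metric: str = DEFAULT_METRIC
    threshold: float = DEFAULT_JACCARD_THRESHOLD
    p_cutoff: float = Field(DEFAULT_P_CUTOFF, gt=0, le=1)

    @field_validator("metric")
    @classmethod
    def _metric(cls, v: str) -> str:
        if v not in ("jaccard", "euclidean", "manhattan"):
            raise ValueError(f"unknown distance metric {v!r}")
        return v


class VizParams(_Strict):
    dpi: int = Field(300, ge=50)
    format: str = "png"
    layout_seed: int = 0

    @field_validator("format")
    @classmethod
    def _format(cls, v: str) -> str:
        if v not in ("png", "svg"):
            raise ValueError("figure format must be 'png' or 'svg'")
        return v


class RunConfig(_Strict):
    deg_tables: list[str] = Field(default_factory=list)
    gmt: str | None = None
    interactions: str | None = None
    category_map: str | None = None
    output_dir: str = "pathkit_out"
    seed: int = 0
    enrichment: EnrichmentParams = Field(default_factory=EnrichmentParams)
    network: NetworkParams = Field(default_factory=NetworkParams)
    pathnet: PathnetParams = Field(default_factory=PathnetParams)
    viz: VizParams = Field(default_factory=VizParams)

    def manifest_dict(self) -> dict:
        return self.model_dump()


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ValidationError` naming the offending field for unknown
    keys, out-of-range values, or referenced files that do not exist.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ValidationError(f"invalid config {path}: {exc}") from None
    for label, p in [("gmt", cfg.gmt), ("interactions", cfg.interactions),
                     ("category_map", cfg.category_map),
                     *[("deg_tables", t) for t in cfg.deg_tables]]:
        if p is not None and not Path(p).exists():
            raise ValidationError(f"config field {label!r}: path does not exist: {p}")
    return cfg
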