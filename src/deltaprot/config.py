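"""Run configuration: every threshold the pipeline uses, in one validated object.

The config round-trips through YAML unchanged, and one global seed fans out to
per-stage seeds via stage-name hashing so each stage is individually
reproducible.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class QCThresholds(BaseModel):
    min_fragments: int = Field(3, ge=1)
    min_points_across_peak: int = Field(8, ge=1)
    max_ppm: float = Field(10.0, gt=0)


class RunConfig(BaseModel):
    """Thresholds, paths and seed for an end-to-end run."""

    # discovery
    discovery_fdr: float = Field(0.01, gt=0, le=1)
    z_alpha: float = Field(0.05, gt=0, le=1)
    concordance_pct: float = Field(80.0, gt=0, le=100)
    min_pairs: int = Field(2, ge=1)
    immunoglobulin_keywords: tuple[str, ...] = ("KW-1280", "Immunoglobulin")
    force_include: tuple[str, ...] = ()  # proteins of special interest
    peptide_allow_list: tuple[str, ...] = ()  # C/M-rule overrides

    # enrichment
    enrichment_fdr: float = Field(0.05, gt=0, le=1)
    exclude_evidence: tuple[str, ...] = ("IEA",)

    # verification
    verification_fdr: float = Field(0.05, gt=0, le=1)
    qc: QCThresholds = QCThresholds()
    rel_bias_tol: float = Field(0.20, gt=0)
    ratio_orientation: str = "light_over_heavy"

    # bookkeeping
    seed: int = Field(0, ge=0)
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None

    @field_validator("ratio_orientation")
    @classmethod
    def _check_orientation(cls, v: str) -> str:
        if v not in {"light_over_heavy", "heavy_over_light"}:
            raise ValueError("ratio_orientation must be light_over_heavy or heavy_over_light")
        return v

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
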