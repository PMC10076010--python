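"""Run configuration for the command-line pipeline.

Structured YAML config validated with pydantic; unknown keys are rejected so
typos fail loudly.  All randomness is funneled through the named seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    outdir: Path = Path("exopba_out")
    panel: Optional[Path] = None
    fastq_dir: Optional[Path] = None
    metadata: Optional[Path] = None
    design: Optional[Path] = None  # None -> packaged cohort-like design


class SeedsConfig(_Strict):
    simulate: int = 0
    downsample: int = 1
    som: int = 2
    embed: int = 3


class SimulateConfig(_Strict):
    exosomes_per_sample: Optional[int] = None  # None -> design default


class ProcessConfig(_Strict):
    min_q: int = 20
    min_fraction: float = 0.75
    max_mismatch: int = 1
    umi_method: Literal["exact", "directional"] = "directional"
    collapse_exosome_tags: bool = False


class ExpressionConfig(_Strict):
    logratio_trim: float = 0.30
    sum_trim: float = 0.05
    alpha_normality: float = 0.05
    fallback: Literal["wilcoxon", "parametric"] = "wilcoxon"
    comparisons: list[tuple[str, str]] = Field(default_factory=list)


class ClusterConfig(_Strict):
    grid_rows: int = 10
    grid_cols: int = 10
    k: int = 12
    epochs: int = 20
    row_normalize: bool = True
    reps: int = 100
    subsample: float = 0.8
    downsample_n: int = 3000
    auto_k: bool = False
    k_min: int = 2
    k_max: int = 20
    criterion: Literal["silhouette", "pac", "delta-area"] = "silhouette"
    embed: bool = True


class RocConfig(_Strict):
    comparisons: list[tuple[str, str]] = Field(default_factory=list)
    sources: list[Literal["expression", "proportion"]] = Field(
        default_factory=lambda: ["expression", "proportion"]
    )


class RunConfig(_Strict):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    seeds: SeedsConfig = Field(default_factory=SeedsConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    process: ProcessConfig = Field(default_factory=ProcessConfig)
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    roc: RocConfig = Field(default_factory=RocConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
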