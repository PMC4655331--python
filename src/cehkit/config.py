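"""Pipeline configuration with the published defaults, YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    chrom: str = "chr6"
    region_start: int = 28_500_000
    region_end: int = 33_500_000
    zygosity_window: int = 5_000
    zygosity_ratio_min: float = 0.95
    max_fail_run: int = 4
    flag_window: int = 30_000
    flag_low_max: int = 3
    flag_high_min: int = 15
    roh_window: int = 50_000
    roh_max_het: int = 3
    roh_max_gap: int = 50_000
    roh_min_length: int = 1_000_000
    r2_min: float = 0.8
    bootstrap_reps: int = 500
    mu: float = 1.1e-8
    gen_years: float = 20.0
    n_chrom: int = 6
    promoter_bp: int = 1_000
    detect_limit: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zygosity_ratio_min <= 1:
            raise ValueError("zygosity_ratio_min must lie in [0, 1]")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")
        if min(self.zygosity_window, self.flag_window, self.roh_window) <= 0:
            raise ValueError("window sizes must be positive")

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
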