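"""Run configuration: one YAML file drives the whole pipeline.

Defaults reproduce the standard analysis conditions: 10-volume blocks,
5 initial volumes dropped, LF 0.04-0.15 Hz / HF 0.15-0.40 Hz at a 10 Hz
interpolation rate, 1000 permutations and 1000 bootstrap iterations
with a +/-2.70 bootstrap-ratio threshold, three 4-minute windows at 50%
overlap, and a 2-minute artifact cutoff per window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synth import CohortSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    drop_volumes: int = 5
    block_len: int = 10
    sd_divisor: str = "population"      # or "sample"
    scale_masked_only: bool = True      # 4D mean over in-mask voxels
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    interp_rate: float = 10.0
    n_perm: int = 1000
    n_boot: int = 1000
    bsr_threshold: float = 2.70
    artifact_max_bad_s: float = 120.0
    concordance_mode: str = "salience_sign"  # or "effect_direction"
    perm_seed: int = 101
    boot_seed: int = 202

    def __post_init__(self) -> None:
        for name in ("drop_volumes",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("block_len", "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("bsr_threshold", "interp_rate", "artifact_max_bad_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sd_divisor not in ("population", "sample"):
            raise ValueError("sd_divisor must be 'population' or 'sample'")
        if self.concordance_mode not in ("salience_sign", "effect_direction"):
            raise ValueError(
                "concordance_mode must be 'salience_sign' or 'effect_direction'"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["age_range"] = list(d["cohort"]["age_range"])
        d["cohort"]["grid_dims"] = list(d["cohort"]["grid_dims"])
        d["lf_band"] = list(d["lf_band"])
        d["hf_band"] = list(d["hf_band"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "age_range" in c:
                c["age_range"] = tuple(c["age_range"])
            if "grid_dims" in c:
                c["grid_dims"] = tuple(c["grid_dims"])
            d["cohort"] = CohortSpec(**c)
        for band in ("lf_band", "hf_band"):
            if band in d:
                d[band] = tuple(d[band])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
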