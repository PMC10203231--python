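"""Run configuration: thresholds, grids and mode presets.

Two presets bundle the two acquisition conventions:

* ``exp1`` — breath-hold CVR: TR 2 s, no smoothing, lag grid 0-12 s in TR
  steps;
* ``exp2`` — gas-challenge CVR: TR 1.8 s, 4 mm FWHM smoothing, shift grid
  0-18 s in TR steps.

A saved config re-executes deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "exp1_config", "exp2_config"]


@dataclass
class RunConfig:
    mode: str = "exp1"
    tr: float = 2.0
    seed: int = 0
    # significance thresholds
    voxel_alpha: float = 0.001
    fdr_q: float = 0.05
    min_n: int = 10
    mad_k: float = 3.0
    sd_k: float = 3.0
    mad_center: str = "mean"
    fallback_threshold: int = 100
    # search grids (seconds)
    lag_start: float = 0.0
    lag_max: float = 12.0
    lag_step: float | None = None  # defaults to TR
    shift_max: float = 18.0
    # GLM conventions
    drift: str = "linear"
    highpass_cutoff: float = 128.0
    smooth_fwhm: float | None = None
    psc_scale_by_peak: bool = True
    one_sided: bool = True
    # simulation
    n_parcels: int = 68
    grid_shape: tuple = (24, 24, 18)
    noise_sd: float = 1.0
    baseline: float = 100.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        return d

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid_shape"] = tuple(d.get("grid_shape", (24, 24, 18)))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def exp1_config(**overrides) -> RunConfig:
    """Breath-hold conventions: TR 2 s, unsmoothed, 0-12 s lag grid."""
    base = dict(mode="exp1", tr=2.0, smooth_fwhm=None, lag_max=12.0)
    base.update(overrides)
    return RunConfig(**base)


def exp2_config(**overrides) -> RunConfig:
    """Gas-challenge conventions: TR 1.8 s, 4 mm smoothing, 0-18 s shift grid."""
    base = dict(mode="exp2", tr=1.8, smooth_fwhm=4.0, shift_max=18.0)
    base.update(overrides)
    return RunConfig(**base)
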