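"""Run configuration with the pipeline's default thresholds.

Every tunable threshold of the package lives here with its default value,
so a serialized configuration is a complete record of an analysis run.
A provenance block (package version, timestamp, seeds) is attached when a
manifest is written.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import InvalidParameterError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable parameters of the analysis modules, with defaults."""

    # interference
    shape_cap: float = 1000.0
    # crossover mapping
    window_size: int = 5_000
    depth_window_size: int = 50_000
    gliding_span: int = 100
    bristol_hom_min_ratio: float = 0.9
    hawaiian_hom_max_ratio: float = 0.25
    min_support_reads: int = 1_500
    min_flank_bp: int = 15_000
    haploid_max_cn: float = 1.45
    triploid_min_cn: float = 2.5
    # image quantification
    annulus_rmin_px: float = 10.0
    annulus_rmax_px: float = 50.0
    volume_bounds_um3: tuple[float, float] = (10.0, 60.0)
    min_sphericity: float = 0.4
    ratio_bounds: tuple[float, float] = (0.3, 0.8)
    profile_bins: int = 11
    rad51_diameter_bounds_um: tuple[float, float] = (1.0, 6.0)
    loess_span: float = 0.5
    # tracing
    resample_step_um: float = 0.05
    # misc
    seed: int = 0
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def manifest(self, extra: dict[str, Any] | None = None) -> dict[str, Any]:
        """Machine-readable run manifest: config echo plus provenance."""
        from . import __version__

        return {
            "config": self.to_dict(),
            "provenance": {
                "package": "meioquant",
                "version": __version__,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
                **(extra or {}),
            },
        }

    def write_manifest(self, path: str | Path, extra: dict[str, Any] | None = None) -> None:
        Path(path).write_text(json.dumps(self.manifest(extra), indent=2))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config, overriding defaults; ``None`` gives the defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        default = getattr(cfg, key)
        if isinstance(default, tuple):
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg
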