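"""Pipeline configuration: TOML-backed, with every default explicit.

The configuration mirrors the analysis stages: ``[segmentation]``,
``[morisita]``, ``[glcm]``, ``[fractal]``, ``[stats]`` (plus ``[synthetic]``
consumed by the ``simulate`` CLI verb).  ``load_config`` merges a user TOML
over the defaults; ``config_hash`` fingerprints the exact parameter set so
every feature record can be traced to the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidArgumentError
from .preprocess import SegmentationConfig

__all__ = [
    "MorisitaConfig",
    "GLCMConfig",
    "FractalConfig",
    "StatsConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
    "default_config_toml",
]


@dataclass(frozen=True)
class MorisitaConfig:
    grid_rows: int = 0  # 0 = auto (3x4 landscape, 4x3 portrait)
    grid_cols: int = 0


@dataclass(frozen=True)
class GLCMConfig:
    distance: int = 1
    angle: int = 0
    levels: int = 256
    symmetric: bool = False
    log_base: str = "e"  # "e" or "2"
    use_mask: bool = False  # restrict pairs to the segmented foreground
    enabled: bool = True

    def log_base_value(self) -> float:
        if self.log_base == "e":
            return math.e
        if self.log_base == "2":
            return 2.0
        raise InvalidArgumentError(f"log_base must be 'e' or '2', got {self.log_base!r}")


@dataclass(frozen=True)
class FractalConfig:
    sizes: tuple[int, ...] = ()  # empty = powers of 2 from 2 to min(dims)/4
    n_origins: int = 10
    seed: int = 0
    lacunarity_mode: str = "cv"  # "cv" | "cv_squared"
    use_skeleton: bool = True


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    control_group: str = ""  # empty = first group in manifest order
    comparison_pair: tuple[str, str] | tuple = ()  # empty = last two groups
    dunnett_n_mc: int = 100_000
    seed: int = 0
    # per-feature ROC direction; features not listed default to greater_is_positive
    roc_direction: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morisita: MorisitaConfig = field(default_factory=MorisitaConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    fractal: FractalConfig = field(default_factory=FractalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "morisita": MorisitaConfig,
    "glcm": GLCMConfig,
    "fractal": FractalConfig,
    "stats": StatsConfig,
}


def _build_section(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise InvalidArgumentError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for key, val in data.items():
        if key in ("sizes", "comparison_pair") and isinstance(val, list):
            val = tuple(val)
        if key == "max_area" and val in (0, -1):
            val = None  # TOML has no null; 0/-1 mean unbounded
        coerced[key] = val
    return cls(**coerced)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline configuration, merging a TOML file over the defaults."""
    if path is None:
        return PipelineConfig()
    with open(Path(path), "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name])
    unknown = set(raw) - set(_SECTIONS) - {"synthetic"}
    if unknown:
        raise InvalidArgumentError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    """12-hex-digit digest identifying the exact parameter set."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_config_toml() -> str:
    """The shipped default configuration, as TOML text."""
    return (Path(__file__).parent / "default_config.toml").read_text()
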