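"""Flat key=value pipeline configuration.

Every tunable decision of the pipeline lives here so a run can be
reproduced from its config snapshot alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # edge detection
    edge_alpha: float = 1.0  # Deriche smoothing coefficient
    edge_low_quantile: float = 0.70  # hysteresis thresholds as quantiles of
    edge_high_quantile: float = 0.90  # nonzero gradient magnitude
    # circular Hough transform
    cht_r_min_frac: float = 0.30  # radius search range, fraction of min side
    cht_r_max_frac: float = 0.48
    cht_r_step: int = 1
    cht_score_floor: float = 0.35  # min circumference completeness to accept
    # quadtree
    leaf_size: int = 64
    # GLCM
    glcm_offset_dr: int = 0  # displacement (0,1) = 0 degrees, distance 1
    glcm_offset_dc: int = 1
    glcm_symmetric: bool = True
    glcm_extra_features: bool = False  # difference entropy + info correlation
    # ranking / classification
    top_k: int = 8
    knn_k: int = 1
    within_group: bool = True
    seed: int = 0

    @property
    def glcm_offset(self) -> tuple[int, int]:
        return (self.glcm_offset_dr, self.glcm_offset_dc)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` file; unknown keys are an error."""
    text = Path(path).read_text()
    valid = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        default = getattr(PipelineConfig, key)
        if isinstance(default, bool):
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif isinstance(default, int):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = [f"{key} = {value}" for key, value in asdict(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")
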