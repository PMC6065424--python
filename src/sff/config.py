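"""Run configuration: every tunable of the pipeline with validated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """All pipeline tunables.

    Spectral transform: ``window`` (odd neighborhood side), kernel ``sigma``
    and connection threshold ``r`` on the [0, 1] intensity scale,
    ``filter_sigma`` (px) of the Gaussian low-pass, ``zero_tol`` for the
    smallest-non-zero eigenvalue selection.  Motion: exhaustive search bounds
    and steps, NCC quality floor and the ROI feature-variance threshold.
    Downstream: vessel threshold (None = 95th in-mask percentile), minimum
    patch size, morphology size, diffusion spread ``d_t`` (px^2) and t-test
    ``alpha``.
    """

    window: int = 9
    sigma: float = 0.25
    r: float = 0.3
    filter_sigma: float = 2.0
    zero_tol: float = 1e-8
    baseline_index: int = 0

    max_shift: int = 8
    shift_step: float = 1.0
    max_rot: float = 5.0
    rot_step: float = 0.5
    ncc_floor: float = 0.2
    feature_var_threshold: float = 1e-4

    vessel_threshold: float | None = None
    vessel_min_patch_px: int = 5
    morph_size: int = 3
    d_t: float = 25.0
    alpha: float = 0.05
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError(f"window must be odd and >= 3, got {self.window}")
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be positive, got {self.sigma}")
        if not (0.0 < self.r < 1.0):
            raise ConfigurationError(f"r must be in (0, 1), got {self.r}")
        if self.filter_sigma <= 0:
            raise ConfigurationError("filter_sigma must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_shift < 0 or self.shift_step <= 0 or self.rot_step <= 0:
            raise ConfigurationError("invalid motion search grid")
        if self.d_t <= 0:
            raise ConfigurationError("d_t must be positive")
        if self.baseline_index < 0:
            raise ConfigurationError("baseline_index must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigurationError(f"could not load config {path}: {exc}") from exc
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
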