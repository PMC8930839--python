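"""Pipeline configuration: defaults, file loading, validation.

A single plain-text (YAML ``key: value``) file configures every stage;
command-line flags override file values which override defaults.  Unknown
keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

#: synthetic-cohort keys forwarded to :class:`gwfcc.synth.SynthConfig`
SYNTH_KEYS = (
    "grid_dims", "voxel_size_mm", "tr_s", "n_timepoints", "n_per_group",
    "planted_connections", "latent_sd", "noise_sd", "motion_sd",
)


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults.

    Bands are (low, high) in Hz; ``alpha_screen`` is the uncorrected stage-1
    per-connection threshold; ``fdr_q`` the stage-2 BH level; ``entry_alpha``/
    ``removal_alpha`` the stepwise logistic entry/removal levels.
    """

    n_drop: int = 10
    mask_threshold: float = 0.6
    gm_band: tuple[float, float] = (0.01, 0.1)
    wm_band: tuple[float, float] = (0.01, 0.15)
    fwhm_mm: float = 4.0
    alpha_screen: float = 5e-6
    fdr_q: float = 0.05
    entry_alpha: float = 0.05
    removal_alpha: float = 0.10
    pooling: str = "pooled"
    t_variant: str = "student"
    seed: int = 0
    synth: dict = field(default_factory=dict)   # SynthConfig overrides

    def __post_init__(self):
        if self.n_drop < 0:
            raise ConfigError("n_drop must be >= 0")
        if not 0 <= self.mask_threshold < 1:
            raise ConfigError("mask_threshold must lie in [0, 1)")
        for name in ("gm_band", "wm_band"):
            band = tuple(getattr(self, name))
            if len(band) != 2 or not 0 <= band[0] < band[1]:
                raise ConfigError(f"{name} must be (low, high) with 0 <= low < high")
            object.__setattr__(self, name, band)
        if self.fwhm_mm < 0:
            raise ConfigError("fwhm_mm must be >= 0")
        for name in ("alpha_screen", "fdr_q", "entry_alpha", "removal_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.pooling not in ("pooled", "within_group"):
            raise ConfigError("pooling must be 'pooled' or 'within_group'")
        if self.t_variant not in ("student", "welch"):
            raise ConfigError("t_variant must be 'student' or 'welch'")
        unknown = set(self.synth) - set(SYNTH_KEYS)
        if unknown:
            raise ConfigError(f"unknown synth keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gm_band"] = list(self.gm_band)
        d["wm_band"] = list(self.wm_band)
        return d
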