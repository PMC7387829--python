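"""Run configuration: every default equals the study's printed value.

The configuration round-trips losslessly to YAML/JSON; unknown keys are
rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # optics
    wavelength_nm: float = 550.0
    pupil_grid_mm: list = field(default_factory=lambda: [3.0, 2.5, 2.0, 1.5, 1.35, 1.0])
    eccentricities_deg: list = field(default_factory=lambda: [2.5, 4.25, 9.25])
    field_extent: str | float = "perifovea"
    # Monte-Carlo misalignment
    tip_tilt_bound_deg: float = 0.35
    decenter_bound_mm: float = 0.75
    mc_draws: int = 5000
    strehl_criterion: float = 0.8
    pupil_samples: int = 32
    # display calibration
    display_field_deg: float = 15.0
    display_size_px: int = 2160
    # blur synthesis
    psf_pupil_mm: float = 2.0
    defocus_max_D: float = 5.0
    defocus_step_D: float = 0.05
    blur_extent_deg: float = 7.5
    n_rings: int = 20
    profile_k_list: list = field(default_factory=lambda: [-0.8, -0.53, 1.1, 4.0, 16.7])
    profile_peak_a_D: float = 3.5
    zone_outer_deg: list = field(default_factory=lambda: [1.5, 3.0, 4.5, 6.0, 7.5])
    zone_width_deg: float = 1.5
    # stimulus
    stimulus_central_cutoff_cpd: float = 6.0
    magnification_e2_deg: float = 2.5
    # psychophysics
    staircase_step_D: float = 0.15
    start_level_zonal_D: float = 1.0
    start_level_global_D: float = 2.0
    trials_per_condition: int = 60
    n_boot: int = 1000
    observer_beta: float = 3.0
    # orchestration
    seed: int = 1
    output_dir: str = "runs"

    @property
    def pixel_scale_arcmin(self) -> float:
        return self.display_field_deg * 60.0 / self.display_size_px

    @property
    def extent_deg(self) -> float:
        from .isoplanatism import EXTENTS_DEG
        if isinstance(self.field_extent, str):
            try:
                return EXTENTS_DEG[self.field_extent]
            except KeyError:
                raise ConfigError(f"unknown field extent '{self.field_extent}'")
        return float(self.field_extent)

    def validate(self) -> "RunConfig":
        if not (400 <= self.wavelength_nm <= 900):
            raise ConfigError("wavelength_nm outside 400-900")
        if self.display_field_deg <= 0 or self.display_size_px <= 0:
            raise ConfigError("display calibration must be positive")
        if self.defocus_step_D <= 0 or self.defocus_max_D <= 0:
            raise ConfigError("defocus grid must be positive")
        if any(k <= -1 for k in self.profile_k_list):
            raise ConfigError("profile K values must be > -1")
        if self.mc_draws < 0 or self.trials_per_condition < 0:
            raise ConfigError("counts must be >= 0")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data).validate()


def load_config(path=None) -> RunConfig:
    """Load a YAML/JSON configuration; missing keys take the printed-value
    defaults, unknown keys raise :class:`ConfigError` naming the key."""
    if path is None:
        return RunConfig().validate()
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return RunConfig().validate()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    if "pupil_grid_mm" in data and isinstance(data["pupil_grid_mm"], str):
        data["pupil_grid_mm"] = sorted(
            (float(x) for x in data["pupil_grid_mm"].split(",")), reverse=True)
    return RunConfig.from_dict(data)
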