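"""Analysis configuration: physical constants and pipeline tunables.

Velocities are metres per second, lengths millimetres and times milliseconds
everywhere in the package; unit conversions happen exactly once, inside the
metric computations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError

#: Dynamic viscosity of blood (Pa s) — standard literature value.
DEFAULT_MU = 3.2e-3
#: Density of blood (kg/m^3) — standard literature value.
DEFAULT_RHO = 1060.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants and tunables shared by every pipeline stage.

    Parameters
    ----------
    mu : float
        Dynamic blood viscosity in Pa·s.
    rho : float
        Blood density in kg/m³.
    pcmra_threshold_frac : float
        Fraction of the PC-MRA maximum used by threshold segmentation.
    static_sd_frac : float
        Fraction of venc below which a voxel's temporal speed mean and SD
        classify it as static tissue.
    wss_sample_distances : tuple of float
        Distances (mm) along the inward wall normal at which velocity is
        sampled for the wall-shear-stress fit.  The default spans 0.5–2
        voxels in half-voxel steps of the coarsest acquisition dimension.
    ci_level : float
        Confidence level for group confidence intervals, in (0, 1).
    seed : int
        Seed for every stochastic component.
    """

    mu: float = DEFAULT_MU
    rho: float = DEFAULT_RHO
    pcmra_threshold_frac: float = 0.5
    static_sd_frac: float = 0.05
    wss_sample_distances: tuple[float, ...] = (1.2, 1.8, 2.4, 3.0, 3.6, 4.2, 4.8)
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ConfigError("mu must be > 0")
        if not self.rho > 0:
            raise ConfigError("rho must be > 0")
        if not 0 < self.pcmra_threshold_frac < 1:
            raise ConfigError("pcmra_threshold_frac must lie in (0, 1)")
        if not self.static_sd_frac > 0:
            raise ConfigError("static_sd_frac must be > 0")
        d = tuple(float(x) for x in self.wss_sample_distances)
        if len(d) < 3 or any(x <= 0 for x in d) or sorted(set(d)) != list(d):
            raise ConfigError(
                "wss_sample_distances must be >= 3 strictly increasing positive values"
            )
        object.__setattr__(self, "wss_sample_distances", d)
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML/JSON key-value file.

    Absent keys fall back to the defaults; an empty (or ``None``) file yields
    the default configuration.  Unknown keys raise :class:`ConfigError`.
    """
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a key-value mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "wss_sample_distances" in raw:
        raw["wss_sample_distances"] = tuple(raw["wss_sample_distances"])
    return AnalysisConfig(**raw)
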