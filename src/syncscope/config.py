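"""Run and simulation configuration objects.

``SimulationConfig`` fixes every knob of the synthetic islet generator;
``RunConfig`` carries the analysis thresholds (all of which default to
the values used throughout the package: 5x5 smoothing, 1.5x activity
rule, 0.7 coordination threshold, 0.95 network threshold, 25% hub cut,
80% coordination gate, ROUT Q = 0.1%).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigurationError

PATTERNS = ("slow", "fast", "mixed")

#: Allowed ranges for oscillation periods, seconds.  Slow oscillations in
#: vivo span roughly one to ten minutes; fast oscillations a few seconds
#: to half a minute.
SLOW_PERIOD_RANGE_S = (60.0, 620.0)
FAST_PERIOD_RANGE_S = (4.0, 31.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic islet generator.

    Defaults describe a control-like mouse islet recorded intravitally:
    ~200 endocrine cells (75% beta, 15% alpha, 10% delta) with mostly
    core-mantle sorting, imaged at 0.1 Hz for 10 minutes, showing mixed
    oscillations (a ~4 min slow component carrying fast oscillations on
    its plateau) with mosaic sensor expression and shot-like additive
    noise at one fifth of the oscillation amplitude.
    """

    seed: int = 0
    n_cells: int = 200
    type_fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    intermix: float = 0.1
    frame_interval_s: float = 10.0
    n_frames: int = 60
    z_planes: int = 1
    z_spacing_um: float = 8.0
    pixel_size_um: float = 2.0
    slow_period_s: float = 240.0
    fast_period_s: float = 15.0
    pattern: str = "mixed"
    n_domains: int = 1
    wave_speed_um_s: Optional[float] = None
    noise_sd: float = 2.0
    bleach_slope_per_s: float = 0.0
    sensor_fraction: float = 0.9
    saturation_value: float = 4095.0
    # Perfusion-movie kinetics (used only by generate_perfusion_movie):
    # tissue arrival delay per micrometre from the nearest vessel, bolus
    # onset time and logistic rise constant.
    perfusion_delay_s_per_um: float = 0.15
    bolus_onset_s: float = 10.0
    bolus_tau_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ConfigurationError("n_cells must be >= 10")
        if len(self.type_fractions) != 3 or any(f < 0 for f in self.type_fractions):
            raise ConfigurationError("type_fractions must be three non-negative values")
        if abs(sum(self.type_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("type_fractions must sum to 1")
        if not 0.0 <= self.intermix <= 1.0:
            raise ConfigurationError("intermix must be in [0, 1]")
        if self.frame_interval_s <= 0 or self.n_frames < 2:
            raise ConfigurationError("need frame_interval_s > 0 and n_frames >= 2")
        if self.z_planes < 1 or self.z_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise ConfigurationError("invalid z/pixel geometry")
        if not SLOW_PERIOD_RANGE_S[0] <= self.slow_period_s <= SLOW_PERIOD_RANGE_S[1]:
            raise ConfigurationError(
                f"slow_period_s outside {SLOW_PERIOD_RANGE_S}: {self.slow_period_s}"
            )
        if not FAST_PERIOD_RANGE_S[0] <= self.fast_period_s <= FAST_PERIOD_RANGE_S[1]:
            raise ConfigurationError(
                f"fast_period_s outside {FAST_PERIOD_RANGE_S}: {self.fast_period_s}"
            )
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"pattern must be one of {PATTERNS}")
        if self.n_domains < 1:
            raise ConfigurationError("n_domains must be >= 1")
        if self.wave_speed_um_s is not None and self.wave_speed_um_s <= 0:
            raise ConfigurationError("wave_speed_um_s must be > 0 or None")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 < self.sensor_fraction <= 1.0:
            raise ConfigurationError("sensor_fraction must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["type_fractions"] = list(self.type_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        if "type_fractions" in d:
            d["type_fractions"] = tuple(d["type_fractions"])
        return cls(**d)


#: (low, high) valid range of each analysis threshold.
_THRESHOLD_RANGES = {
    "activity_factor": (0.0, 10.0),
    "coordination_r_min": (-1.0, 1.0),
    "network_r_th": (0.0, 1.0),
    "hub_cut": (0.0, 1.0),
    "coordination_gate": (0.0, 1.0),
    "rout_q": (0.0, 0.5),
    "phase_fit_r2_min": (0.0, 1.0),
}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulation`` (generate inputs) or ``input_dir`` (read a
    previously written movie + sidecar) must be provided.
    """

    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    # analysis thresholds, defaulting to the values used in the study
    activity_factor: float = 1.5
    coordination_r_min: float = 0.7
    network_r_th: float = 0.95
    hub_cut: float = 0.25
    coordination_gate: float = 0.80
    rout_q: float = 0.001
    phase_fit_r2_min: float = 0.5
    min_mean_intensity: Optional[float] = None  # None -> Otsu
    cell_width_um: float = 12.0
    detrend_per_pixel: bool = True
    require_contiguity: bool = False
    lag_mode: str = "as_printed"  # primary phase-lag formula; see wave module
    replicate_policy: str = "islet"  # "islet" | "mouse"

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ConfigurationError("provide either simulation or input_dir")
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside valid range [{lo}, {hi}]")
        if self.lag_mode not in ("as_printed", "standard"):
            raise ConfigurationError("lag_mode must be 'as_printed' or 'standard'")
        if self.replicate_policy not in ("islet", "mouse"):
            raise ConfigurationError("replicate_policy must be 'islet' or 'mouse'")
        if self.cell_width_um <= 0:
            raise ConfigurationError("cell_width_um must be > 0")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    def canonical_json(self) -> str:
        """Stable serialization used for the reproducibility manifest.

        The output directory is not part of the analysis identity and is
        excluded, so runs of one configuration into different locations
        hash identically.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)
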