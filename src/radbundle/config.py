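"""YAML run configuration shared by the CLI commands.

One file carries the device, bundle geometry, kinetics, degradation,
schedule and noise blocks plus the seed; unknown keys are rejected by name so
typos fail loudly.  Every block is optional and defaults to the reference
operating point (25 N/m device, 1800-molecule bundle, b=1/s, beta=8.1e-7,
phi=0.7, four 210 s sessions of 30 Gy with 180 s gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .degradation import REFERENCE_AREA, BundleGeometry, DegradationParams
from .kinetics import KineticsParams
from .oscillator import DeviceParams
from .synthetic import IrradiationSchedule, NoiseModel, make_schedule

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_SCHEDULE_KEYS = {"n_sessions", "session_s", "gap_s", "dose_gy", "start_s"}
_NETWORK_KEYS = {"n_seg", "c", "c_values", "break_fractions", "replicates"}
_SIM_KEYS = {"sample_hz", "eta_dna", "t_end"}
_FIT_KEYS = {"b", "fix_k0", "slope_window", "refine", "phib"}
_RECOVER_KEYS = {"noise_sd", "replicates", "slope_window", "refine", "phib"}


@dataclass
class RunConfig:
    device: DeviceParams = field(default_factory=DeviceParams)
    geometry: BundleGeometry = field(
        default_factory=lambda: BundleGeometry(A=REFERENCE_AREA)
    )
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    degradation: DegradationParams = field(default_factory=DegradationParams)
    schedule: IrradiationSchedule = field(
        default_factory=lambda: make_schedule(4, 210.0, 180.0, 30.0)
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int | None = None
    simulate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    recover: dict = field(default_factory=dict)


def _coerce(value):
    # YAML 1.1 reads exponents without a sign ("3.5e8") as strings
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value


def _build(cls, block: dict, name: str):
    block = {k: _coerce(v) for k, v in dict(block).items()}
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"config block '{name}': {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"config block '{name}': {exc}") from None


def _checked(block: dict, allowed: set, name: str) -> dict:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"config block '{name}': unknown keys {sorted(unknown)}"
        )
    return block


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {
        "device", "geometry", "kinetics", "degradation", "schedule",
        "noise", "seed", "simulate", "fit", "network", "recover",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")

    cfg = RunConfig()
    if "device" in raw:
        cfg.device = _build(DeviceParams, raw["device"], "device")
    if "geometry" in raw:
        cfg.geometry = _build(BundleGeometry, raw["geometry"], "geometry")
    if "kinetics" in raw:
        cfg.kinetics = _build(KineticsParams, raw["kinetics"], "kinetics")
    if "degradation" in raw:
        cfg.degradation = _build(DegradationParams, raw["degradation"],
                                 "degradation")
    if "schedule" in raw:
        block = _checked(dict(raw["schedule"]), _SCHEDULE_KEYS, "schedule")
        cfg.schedule = make_schedule(
            int(block.get("n_sessions", 4)),
            float(block.get("session_s", 210.0)),
            float(block.get("gap_s", 180.0)),
            float(block.get("dose_gy", 30.0)),
            float(block.get("start_s", 0.0)),
        )
    if "noise" in raw:
        cfg.noise = _build(NoiseModel, raw["noise"], "noise")
    if "seed" in raw and raw["seed"] is not None:
        cfg.seed = int(raw["seed"])
    cfg.simulate = _checked(dict(raw.get("simulate") or {}), _SIM_KEYS, "simulate")
    cfg.fit = _checked(dict(raw.get("fit") or {}), _FIT_KEYS, "fit")
    cfg.network = _checked(dict(raw.get("network") or {}), _NETWORK_KEYS,
                           "network")
    cfg.recover = _checked(dict(raw.get("recover") or {}), _RECOVER_KEYS,
                           "recover")
    return cfg
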