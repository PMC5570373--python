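"""Global parameter configuration.

The configuration is a nested mapping whose defaults ship with the package
(``data/default_config.yaml``).  User YAML files and ``key.path=value``
overrides are deep-merged on top.  Every temperature-dependent rate constant
is stored at a declared reference temperature together with a Q10 class; the
modules that consume rates rescale them to the simulation temperature with
:func:`spinesim.receptors.q10_adjust`.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = ["GlobalConfig", "load_config", "default_config_dict", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or missing configuration entries."""


def default_config_dict() -> dict:
    """Return a fresh copy of the packaged default configuration."""
    text = resources.files("spinesim.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, extra: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _coerce(text: str) -> Any:
    """Parse a CLI override value with YAML semantics (numbers, bools, lists)."""
    return yaml.safe_load(text)


class GlobalConfig:
    """Validated parameter set for one simulation run.

    Parameters are addressed by dotted keys, e.g. ``cfg["glutamate.b_total_mM"]``.
    """

    def __init__(self, data: dict):
        self.data = data
        self.validate()

    # -- access ---------------------------------------------------------
    def __getitem__(self, dotted: str) -> Any:
        node: Any = self.data
        for part in dotted.split("."):
            try:
                node = node[part]
            except (KeyError, TypeError):
                raise ConfigError(f"missing configuration key: {dotted!r}") from None
        return node

    def __setitem__(self, dotted: str, value: Any) -> None:
        parts = dotted.split(".")
        node = self.data
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value

    def get(self, dotted: str, default: Any = None) -> Any:
        try:
            return self[dotted]
        except ConfigError:
            return default

    def copy(self) -> "GlobalConfig":
        return GlobalConfig(copy.deepcopy(self.data))

    def with_overrides(self, overrides: Mapping[str, Any]) -> "GlobalConfig":
        new = self.copy()
        for key, value in overrides.items():
            new[key] = _coerce(value) if isinstance(value, str) else value
        new.validate()
        return new

    @property
    def temperature(self) -> float:
        return float(self["temperature_c"])

    def q10(self, class_name: str) -> float:
        return float(self[f"q10.{class_name}"])

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        geo = self["geometry"]
        if geo["head_volume_um3"] <= 0:
            raise ConfigError("geometry.head_volume_um3 must be positive")
        for key in ("neck_length_um", "neck_radius_um", "shaft_radius_um",
                    "shaft_length_um", "cleft_height_nm"):
            if geo[key] <= 0:
                raise ConfigError(f"geometry.{key} must be positive")
        if not 0 < geo["psd_volume_fraction"] < 1:
            raise ConfigError("geometry.psd_volume_fraction must lie in (0, 1)")
        if not 0 < geo["psd_outer_radius_nm"] < geo["perisynaptic_outer_radius_nm"]:
            raise ConfigError("require 0 < psd radius < perisynaptic outer radius")
        glu = self["glutamate"]
        if glu["d_glu_um2_per_ms"] <= 0:
            raise ConfigError("glutamate.d_glu_um2_per_ms must be positive")
        if glu["tortuosity_lambda"] < 1:
            raise ConfigError("glutamate.tortuosity_lambda must be >= 1")
        if glu["b_total_mM"] < 0 or glu["glu_rest_uM"] < 0:
            raise ConfigError("glutamate concentrations must be non-negative")
        for name, count in self["receptors.counts"].items():
            if count < 0 or int(count) != count:
                raise ConfigError(f"receptor count {name} must be a non-negative integer")

    def serialise(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)


def load_config(path: str | None = None,
                overrides: Mapping[str, Any] | None = None) -> GlobalConfig:
    """Build a :class:`GlobalConfig` from defaults, an optional YAML file and
    dotted-key overrides (in that order of precedence)."""
    data = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        data = _deep_merge(data, user)
    cfg = GlobalConfig(data)
    if overrides:
        cfg = cfg.with_overrides(dict(overrides))
    return cfg
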