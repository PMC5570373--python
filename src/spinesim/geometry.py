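"""Spine and dendrite geometry.

The spine head is a hemisphere of volume ``V`` facing the presynaptic
terminal across a flat cylindrical cleft of height 20 nm whose radius equals
the head radius, ``r = (3V / 2pi)^(1/3)``.  The head is split into a PSD
compartment (a cylinder under the synaptic membrane holding a fixed fraction
of the head volume) and the remaining cytosol.  The neck and the parent
dendritic shaft are cylinders.

Membrane zones are defined by radial distance from the cleft centre:
synaptic (PSD) up to 150 nm, perisynaptic up to 365 nm, extrasynaptic
beyond.  Zone intervals are half-open below and closed above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ConfigError, GlobalConfig

__all__ = ["SpineGeometry", "derive_geometry", "zone_of", "ZONES"]

ZONES = ("synaptic", "perisynaptic", "extrasynaptic")

#: validity window (um^-1) of the bAP calibration data for the spine head
HEAD_SV_RANGE = (4.0, 20.0)
#: validity window (um^-1) for the parent dendrite
SHAFT_SV_RANGE = (1.0, 4.0)


@dataclass(frozen=True)
class SpineGeometry:
    """Derived geometric description of one spine and its parent shaft.

    Lengths in um, volumes in um^3, areas in um^2.
    """

    head_volume: float
    head_radius: float
    cleft_height: float
    cleft_radius: float
    psd_outer_radius: float
    perisynaptic_outer_radius: float
    psd_volume_fraction: float
    neck_length: float
    neck_radius: float
    shaft_radius: float
    shaft_length: float

    # -- compartment volumes -------------------------------------------
    @property
    def psd_volume(self) -> float:
        return self.psd_volume_fraction * self.head_volume

    @property
    def cytosol_volume(self) -> float:
        return (1.0 - self.psd_volume_fraction) * self.head_volume

    @property
    def neck_volume(self) -> float:
        return math.pi * self.neck_radius**2 * self.neck_length

    @property
    def shaft_volume(self) -> float:
        return math.pi * self.shaft_radius**2 * self.shaft_length

    # -- membrane areas -------------------------------------------------
    @property
    def head_membrane_area(self) -> float:
        """Curved (non-cleft) surface of the hemispherical head."""
        return 2.0 * math.pi * self.head_radius**2

    @property
    def psd_membrane_area(self) -> float:
        return math.pi * self.psd_outer_radius**2

    @property
    def cytosol_membrane_area(self) -> float:
        return self.head_membrane_area - self.psd_membrane_area

    @property
    def neck_membrane_area(self) -> float:
        return 2.0 * math.pi * self.neck_radius * self.neck_length

    @property
    def shaft_membrane_area(self) -> float:
        return 2.0 * math.pi * self.shaft_radius * self.shaft_length

    # -- diagnostics ----------------------------------------------------
    @property
    def head_surface_to_volume(self) -> float:
        return self.head_membrane_area / self.head_volume

    @property
    def shaft_surface_to_volume(self) -> float:
        return self.shaft_membrane_area / self.shaft_volume

    def neck_cross_section(self) -> float:
        return math.pi * self.neck_radius**2


def derive_geometry(config: GlobalConfig, force: bool | None = None) -> SpineGeometry:
    """Derive all lengths and volumes from the configured geometry section.

    Raises :class:`ConfigError` if the derived surface-to-volume ratios fall
    outside the calibration validity windows, unless ``force`` (or the
    ``geometry.force`` flag) is set.
    """
    geo = config["geometry"]
    head_volume = float(geo["head_volume_um3"])
    if head_volume <= 0:
        raise ConfigError("head volume must be positive")
    head_radius = (3.0 * head_volume / (2.0 * math.pi)) ** (1.0 / 3.0)
    g = SpineGeometry(
        head_volume=head_volume,
        head_radius=head_radius,
        cleft_height=float(geo["cleft_height_nm"]) * 1e-3,
        cleft_radius=head_radius,
        psd_outer_radius=float(geo["psd_outer_radius_nm"]) * 1e-3,
        perisynaptic_outer_radius=float(geo["perisynaptic_outer_radius_nm"]) * 1e-3,
        psd_volume_fraction=float(geo["psd_volume_fraction"]),
        neck_length=float(geo["neck_length_um"]),
        neck_radius=float(geo["neck_radius_um"]),
        shaft_radius=float(geo["shaft_radius_um"]),
        shaft_length=float(geo["shaft_length_um"]),
    )
    if force is None:
        force = bool(geo.get("force", False))
    if not force:
        lo, hi = HEAD_SV_RANGE
        sv = g.head_surface_to_volume
        if not lo <= sv <= hi:
            raise ConfigError(
                f"spine head surface-to-volume ratio {sv:.2f} um^-1 outside the "
                f"calibration validity range {lo}-{hi}; set geometry.force to override")
        lo, hi = SHAFT_SV_RANGE
        sv = g.shaft_surface_to_volume
        if not lo <= sv <= hi:
            raise ConfigError(
                f"shaft surface-to-volume ratio {sv:.2f} um^-1 outside the "
                f"calibration validity range {lo}-{hi}; set geometry.force to override")
    return g


def zone_of(radial_distance_um: float,
            psd_outer_radius_um: float = 0.150,
            perisynaptic_outer_radius_um: float = 0.365) -> str:
    """Classify a membrane point by radial distance from the cleft centre.

    Intervals are (0, r_psd] synaptic, (r_psd, r_peri] perisynaptic, beyond
    extrasynaptic.
    """
    if radial_distance_um < 0:
        raise ValueError("radial distance must be non-negative")
    if radial_distance_um <= psd_outer_radius_um:
        return "synaptic"
    if radial_distance_um <= perisynaptic_outer_radius_um:
        return "perisynaptic"
    return "extrasynaptic"
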