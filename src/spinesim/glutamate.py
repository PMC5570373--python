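"""Glutamate release, diffusion and uptake.

A presynaptic pulse empties one or more vesicles (1500 molecules each by
default) from a point source at the cleft centre.  Two closed-form regimes
describe the resulting concentration field:

* **In-cleft (synaptic zone).**  Instantaneous vertical mixing across the
  20 nm cleft reduces the problem to 2-D diffusion in a slab:

  ``C(r, t) = G / (h 4 pi D t) exp(-r^2 / 4 D t) exp(-t / tau_esc)``

  The exponential factor models clearance of the cleft through its rim.
  Astrocytic transporters have no access to the cleft proper, so uptake does
  not act here.

* **Porous half-space (perisynaptic and extrasynaptic zones).**  Outside the
  PSD the extracellular space is a tortuous porous medium (effective
  diffusivity ``D* = D / lambda^2``, volume fraction ``alpha``) with
  homogeneous transporter uptake linearised to a pseudo-first-order rate
  ``k_up = k_on * B_total``:

  ``C(r, t) = 2 G / (alpha (4 pi D* t)^(3/2)) exp(-r^2 / 4 D* t - k_up t)``

Each zone is evaluated at a representative diffusion distance from the
release site; pulses superpose linearly and the resting extrasynaptic
glutamate level adds to the peri- and extrasynaptic (but not synaptic)
traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import GlobalConfig
from .geometry import SpineGeometry, ZONES
from .receptors import q10_adjust

__all__ = [
    "GlutamateParams",
    "GlutamateTrace",
    "glutamate_params",
    "impulse_response",
    "trace_at_zone",
    "astrocytic_pulse_trace",
    "resting_level",
]

#: molecules per um^3 at 1 uM
MOLECULES_PER_UM3_PER_UM = 602.214

#: mollification of the porous-medium point source, ms
_POROUS_SPREAD_MS = 1e-3


@dataclass(frozen=True)
class GlutamateParams:
    """Diffusion/uptake parameters at simulation temperature."""

    d_glu: float                  # um^2/ms, in-cleft
    tortuosity_lambda: float
    porosity_alpha: float
    b_total: float                # mM
    k_on_transporter: float       # mM^-1 ms^-1
    glu_rest: float               # uM
    molecules_per_vesicle: int
    release_spread: float         # ms
    cleft_escape_tau: float       # ms; inf disables rim clearance
    synaptic_radius: float        # um
    perisynaptic_radius: float    # um
    extrasynaptic_distance: float  # um

    @property
    def d_star(self) -> float:
        return self.d_glu / self.tortuosity_lambda**2

    @property
    def k_up(self) -> float:
        """Pseudo-first-order uptake rate, ms^-1."""
        return self.k_on_transporter * self.b_total

    def zone_radius(self, zone: str) -> float:
        return {"synaptic": self.synaptic_radius,
                "perisynaptic": self.perisynaptic_radius,
                "extrasynaptic": self.extrasynaptic_distance}[zone]


def glutamate_params(config: GlobalConfig) -> GlutamateParams:
    g = config["glutamate"]
    T = config.temperature
    d_glu = q10_adjust(g["d_glu_um2_per_ms"], config.q10("diffusion"),
                       T, g["reference_temperature_c"])
    k_on = q10_adjust(g["k_on_transporter_per_mM_ms"], config.q10("transporter_kinetics"),
                      T, g["reference_temperature_transporter_c"])
    tau = g["cleft_escape_tau_ms"]
    return GlutamateParams(
        d_glu=d_glu,
        tortuosity_lambda=g["tortuosity_lambda"],
        porosity_alpha=g["porosity_alpha"],
        b_total=g["b_total_mM"],
        k_on_transporter=k_on,
        glu_rest=g["glu_rest_uM"],
        molecules_per_vesicle=int(g["molecules_per_vesicle"]),
        release_spread=g["release_spread_ms"],
        cleft_escape_tau=math.inf if tau in (None, 0) else float(tau),
        synaptic_radius=g["synaptic_radius_um"],
        perisynaptic_radius=g["perisynaptic_radius_um"],
        extrasynaptic_distance=g["extrasynaptic_distance_um"],
    )


def impulse_response(release: float, r: float, t, params: GlutamateParams,
                     geometry: SpineGeometry, zone: str = "synaptic"):
    """Concentration (uM) at distance ``r`` (um) and time ``t`` (ms) after an
    instantaneous release of ``release`` molecules.

    The regime (in-cleft slab vs porous half-space) follows the zone of the
    evaluation point.  Vectorised over ``t``.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if zone == "synaptic":
        # vesicle emptying time mollifies the in-cleft point source
        te = t + params.release_spread
        h = geometry.cleft_height
        c = release / (h * 4.0 * math.pi * params.d_glu * te) \
            * np.exp(-r * r / (4.0 * params.d_glu * te))
        if math.isfinite(params.cleft_escape_tau):
            c = c * np.exp(-t / params.cleft_escape_tau)
    elif zone in ZONES:
        # spillover into the porous medium is delayed by cleft transit anyway;
        # only a microsecond-scale mollification is needed
        te = t + _POROUS_SPREAD_MS
        d = params.d_star
        c = 2.0 * release / (params.porosity_alpha * (4.0 * math.pi * d * te) ** 1.5) \
            * np.exp(-r * r / (4.0 * d * te) - params.k_up * t)
    else:
        raise ValueError(f"unknown zone {zone!r}")
    return c / MOLECULES_PER_UM3_PER_UM


def resting_level(zone: str, params: GlutamateParams) -> float:
    """Resting glutamate at a zone: the extrasynaptic ambient level applies
    outside the cleft, the cleft proper rests at zero."""
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    return 0.0 if zone == "synaptic" else params.glu_rest


class GlutamateTrace:
    """Glutamate time course at one zone: a continuous evaluator plus a
    sampled series refined around each release."""

    def __init__(self, zone: str, pulse_times: np.ndarray, params: GlutamateParams,
                 geometry: SpineGeometry, duration: float,
                 release: float | None = None,
                 square_pulse: tuple[float, float, float] | None = None):
        self.zone = zone
        self.pulse_times = np.asarray(pulse_times, dtype=float)
        self.params = params
        self.geometry = geometry
        self.duration = float(duration)
        self.release = params.molecules_per_vesicle if release is None else float(release)
        self.square_pulse = square_pulse  # (onset, duration, amplitude uM)
        self.rest = resting_level(zone, params)
        self._radius = params.zone_radius(zone)
        self.times = self._sample_times()
        self.concentration = self(self.times)

    def _sample_times(self) -> np.ndarray:
        pts = [np.linspace(0.0, self.duration, 201)]
        start = self.params.release_spread if self.zone == "synaptic" \
            else _POROUS_SPREAD_MS
        for tk in self.pulse_times:
            # log-refined window after each release to resolve the spike
            local = tk + np.geomspace(start, 10.0, 120)
            pts.append(local[local <= self.duration])
        if self.square_pulse is not None:
            onset, width, _ = self.square_pulse
            pts.append(np.array([onset, onset + width]))
        times = np.unique(np.concatenate(pts))
        return times[(times >= 0) & (times <= self.duration)]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        c = np.full(t.shape, self.rest)
        for tk in self.pulse_times:
            dt = t - tk
            live = dt >= 0
            if np.any(live):
                c[live] += impulse_response(self.release, self._radius, dt[live],
                                            self.params, self.geometry, self.zone)
        if self.square_pulse is not None and self.zone == "extrasynaptic":
            onset, width, amplitude = self.square_pulse
            c = np.where((t >= onset) & (t < onset + width), c + amplitude, c)
        return c if c.ndim else float(c)

    def scalar(self, t: float) -> float:
        """Fast scalar evaluation used inside ODE right-hand sides."""
        c = self.rest
        if len(self.pulse_times):
            dt = t - self.pulse_times
            dt = dt[dt >= 0]
            if dt.size:
                p, r = self.params, self._radius
                if self.zone == "synaptic":
                    te = dt + p.release_spread
                    v = self.release / (self.geometry.cleft_height
                                        * 4.0 * math.pi * p.d_glu * te) \
                        * np.exp(-r * r / (4.0 * p.d_glu * te))
                    if math.isfinite(p.cleft_escape_tau):
                        v = v * np.exp(-dt / p.cleft_escape_tau)
                else:
                    te = dt + _POROUS_SPREAD_MS
                    d = p.d_star
                    v = 2.0 * self.release / (p.porosity_alpha
                                              * (4.0 * math.pi * d * te) ** 1.5) \
                        * np.exp(-r * r / (4.0 * d * te) - p.k_up * dt)
                c += float(v.sum()) / MOLECULES_PER_UM3_PER_UM
        if self.square_pulse is not None and self.zone == "extrasynaptic":
            onset, width, amplitude = self.square_pulse
            if onset <= t < onset + width:
                c += amplitude
        return c

    @property
    def peak(self) -> float:
        return float(np.max(self.concentration))


def trace_at_zone(pulse_times: Sequence[float], zone: str, params: GlutamateParams,
                  geometry: SpineGeometry, duration: float,
                  release: float | None = None) -> GlutamateTrace:
    """Superpose per-pulse impulse responses at a zone's representative radius
    and add the zone's resting level."""
    pulse_times = np.asarray(list(pulse_times), dtype=float)
    if np.any(pulse_times < 0):
        raise ValueError("pulse times must be non-negative")
    if np.any(np.diff(pulse_times) < 0):
        raise ValueError("pulse times must be sorted")
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    return GlutamateTrace(zone, pulse_times, params, geometry, duration, release=release)


def astrocytic_pulse_trace(duration_ms: float, amplitude_uM: float,
                           params: GlutamateParams, geometry: SpineGeometry,
                           total_duration: float, onset_ms: float = 0.0,
                           zone: str = "extrasynaptic") -> GlutamateTrace:
    """Square pulse of ambient glutamate applied to the extrasynaptic space
    only; synaptic and perisynaptic zones see just their resting level."""
    if duration_ms <= 0:
        raise ValueError("pulse duration must be positive")
    if amplitude_uM < 0:
        raise ValueError("amplitude must be non-negative")
    return GlutamateTrace(zone, np.array([]), params, geometry, total_duration,
                          square_pulse=(onset_ms, duration_ms, amplitude_uM))
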