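"""Deterministic state-fraction kinetics of NMDAR and AMPAR schemes.

Each receptor subtype is a first-order Markov scheme whose transition rates
are either glutamate-independent or proportional to the local glutamate
concentration (binding steps).  The population mean occupancy ``p`` of the
states then obeys the linear ODE

    dp/dt = (A0 + [Glu](t) A1) p

where ``A0``/``A1`` are generator matrices (columns sum to zero).  The NMDAR
schemes have eight states (unbound, two binding, slow and fast desensitised,
two pre-open, open) and differ between the NR2A and NR2B subtypes in binding
affinity, opening equilibrium and desensitisation; the AMPAR scheme has
seven (three closed, open, three desensitised).

All rates are stored at a published-style reference temperature and rescaled
to the simulation temperature through their Q10 class.  Desensitisation
inhibition (an amyloid-beta oligomer effect) multiplies the desensitising
entry rates ``k_d1+``/``k_d2+`` by ``1 - inhibition``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config import ConfigError, GlobalConfig

__all__ = [
    "KineticScheme",
    "StateTrajectory",
    "OccupancyMetrics",
    "q10_adjust",
    "build_scheme",
    "steady_state",
    "integrate",
    "integrate_schemes",
    "metrics_vs_control",
]


def q10_adjust(rate: float, q10: float, temperature: float, reference: float) -> float:
    """Rescale a rate from its reference temperature: ``rate * q10**((T-Tref)/10)``."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return rate * q10 ** ((temperature - reference) / 10.0)


@dataclass(frozen=True)
class KineticScheme:
    """Validated kinetic scheme at simulation temperature (rates in ms^-1,
    binding rates in uM^-1 ms^-1)."""

    subtype: str
    states: tuple[str, ...]
    unbound_state: str
    open_states: tuple[str, ...]
    desensitised_states: tuple[str, ...]
    a0: np.ndarray            # glutamate-independent generator
    a1: np.ndarray            # binding generator (to be scaled by [Glu] in uM)
    conductance_pS: float
    ca_permeability: float    # um^3/ms per open channel (GHK permeability)

    def __post_init__(self):
        n = len(self.states)
        if self.a0.shape != (n, n) or self.a1.shape != (n, n):
            raise ConfigError("generator shape mismatch")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def open_index(self) -> np.ndarray:
        return np.array([self.index(s) for s in self.open_states])

    @property
    def desensitised_index(self) -> np.ndarray:
        return np.array([self.index(s) for s in self.desensitised_states])

    def generator(self, glu_uM: float) -> np.ndarray:
        return self.a0 + glu_uM * self.a1


def build_scheme(subtype: str, config: GlobalConfig,
                 desens_inhibition: float = 0.0) -> KineticScheme:
    """Build the scheme for ``subtype`` from config, Q10-scaled to the
    simulation temperature.

    ``desens_inhibition`` in [0, 1] multiplies the desensitising entry rates
    by ``1 - inhibition``.
    """
    try:
        spec = config[f"receptors.schemes.{subtype}"]
    except ConfigError:
        raise ConfigError(f"no kinetic scheme configured for subtype {subtype!r}")
    if not 0.0 <= desens_inhibition <= 1.0:
        raise ValueError("desensitisation inhibition must lie in [0, 1]")
    states = tuple(spec["states"])
    n = len(states)
    expected = {"nr2a": 8, "nr2b": 8, "ampar": 7}.get(subtype)
    if expected is not None and n != expected:
        raise ConfigError(f"{subtype} scheme must have {expected} states, got {n}")
    factor = config.q10(spec["q10_class"]) ** (
        (config.temperature - spec["reference_temperature_c"]) / 10.0)
    idx = {s: i for i, s in enumerate(states)}
    a0 = np.zeros((n, n))
    a1 = np.zeros((n, n))
    for tr in spec["transitions"]:
        for key in ("from", "to", "rate"):
            if key not in tr:
                raise ConfigError(
                    f"transition in scheme {subtype!r} missing key {key!r}")
        i, j = idx[tr["to"]], idx[tr["from"]]
        rate = float(tr["rate"]) * 1e-3 * factor          # per-second -> per-ms
        if rate < 0:
            raise ConfigError(f"negative rate in scheme {subtype!r}")
        if tr.get("desensitising", False):
            rate *= 1.0 - desens_inhibition
        target = a1 if tr.get("glu_order", 0) == 1 else a0
        target[i, j] += rate
        target[j, j] -= rate
    g_ref = spec.get("conductance_reference_temperature_c", config.temperature)
    cclass = "ampar_conductance" if subtype == "ampar" else "nmdar_conductance"
    gfac = config.q10(cclass) ** ((config.temperature - g_ref) / 10.0)
    return KineticScheme(
        subtype=subtype,
        states=states,
        unbound_state=spec["unbound_state"],
        open_states=tuple(spec["open_states"]),
        desensitised_states=tuple(spec["desensitised_states"]),
        a0=a0,
        a1=a1,
        conductance_pS=float(spec["conductance_pS"]) * gfac,
        ca_permeability=float(spec["ca_permeability_um3_per_ms"]) * gfac,
    )


def steady_state(scheme: KineticScheme, glu_uM: float) -> np.ndarray:
    """Stationary occupancy at clamped glutamate: the generator's null space,
    normalised to sum 1."""
    if glu_uM < 0:
        raise ValueError("glutamate concentration must be non-negative")
    n = scheme.n_states
    m = scheme.generator(glu_uM).copy()
    m[-1, :] = 1.0                       # replace one balance row by normalisation
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(m, b)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(
            f"degenerate generator for {scheme.subtype} at [Glu]={glu_uM} uM: {exc}")
    if np.any(p < -1e-9):
        raise ArithmeticError(
            f"negative stationary occupancy for {scheme.subtype} at [Glu]={glu_uM} uM")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


@dataclass
class StateTrajectory:
    """Occupancy fractions over time for one scheme."""

    scheme: KineticScheme
    times: np.ndarray                     # ms
    occupancy: np.ndarray                 # (n_times, n_states)
    glu: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def open_fraction(self) -> np.ndarray:
        return self.occupancy[:, self.scheme.open_index].sum(axis=1)

    @property
    def desensitised_fraction(self) -> np.ndarray:
        return self.occupancy[:, self.scheme.desensitised_index].sum(axis=1)

    def state(self, name: str) -> np.ndarray:
        return self.occupancy[:, self.scheme.index(name)]


@dataclass
class OccupancyMetrics:
    """Differences vs a control run: extra dwell time per state and extra
    Ca2+ ions."""

    t_add: dict = field(default_factory=dict)    # state -> ms
    ca_add: float = 0.0                          # ions


def _segment_edges(duration: float, breakpoints: Sequence[float]) -> np.ndarray:
    pts = np.asarray([b for b in breakpoints if 0.0 < b < duration], dtype=float)
    return np.unique(np.concatenate([[0.0], pts, [duration]]))


def integrate_schemes(schemes: Sequence[KineticScheme],
                      glu: Callable[[np.ndarray], np.ndarray],
                      duration: float,
                      breakpoints: Sequence[float] = (),
                      dt_out: float = 0.05,
                      initial_glu: float | None = None,
                      rtol: float = 1e-8,
                      atol: float = 1e-10) -> list[StateTrajectory]:
    """Integrate several schemes driven by one glutamate trace.

    The schemes are stacked block-diagonally (the system is linear, so one
    adaptive step control serves all).  ``breakpoints`` (release times) split
    the integration so the stiff solver re-resolves each concentration spike.
    The initial condition of each scheme is its steady state at
    ``initial_glu`` (the zone's resting glutamate; defaults to ``glu(0)``).
    """
    if initial_glu is None:
        initial_glu = float(np.asarray(glu(np.array([0.0]))).ravel()[0])
    sizes = [s.n_states for s in schemes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    ntot = int(offsets[-1])
    a0 = np.zeros((ntot, ntot))
    a1 = np.zeros((ntot, ntot))
    y0 = np.empty(ntot)
    for s, lo, hi in zip(schemes, offsets[:-1], offsets[1:]):
        a0[lo:hi, lo:hi] = s.a0
        a1[lo:hi, lo:hi] = s.a1
        y0[lo:hi] = steady_state(s, initial_glu)

    if hasattr(glu, "scalar"):
        glu_at = glu.scalar
    else:
        def glu_at(t):
            return float(np.asarray(glu(np.array([t]))).ravel()[0])

    def rhs(t, y):
        return a0 @ y + glu_at(t) * (a1 @ y)

    edges = _segment_edges(duration, breakpoints)
    times_out: list[np.ndarray] = [np.array([0.0])]
    states_out: list[np.ndarray] = [y0[None, :]]
    y = y0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        n_eval = max(2, int(np.ceil((t1 - t0) / dt_out)) + 1)
        t_eval = np.linspace(t0, t1, n_eval)[1:]
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol,
                        first_step=min(1e-4, (t1 - t0) / 10.0))
        if not sol.success:
            raise ArithmeticError(
                f"receptor integration failed at t={sol.t[-1] if len(sol.t) else t0} ms: "
                f"{sol.message}")
        y = sol.y[:, -1]
        # guard against slow drift of the simplex across many segments
        for lo, hi in zip(offsets[:-1], offsets[1:]):
            y[lo:hi] = np.clip(y[lo:hi], 0.0, None)
            y[lo:hi] /= y[lo:hi].sum()
        times_out.append(sol.t)
        states_out.append(sol.y.T)
    times = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=0)
    return [StateTrajectory(s, times, states[:, lo:hi], glu)
            for s, lo, hi in zip(schemes, offsets[:-1], offsets[1:])]


def integrate(scheme: KineticScheme, glu: Callable, duration: float,
              **kwargs) -> StateTrajectory:
    """Integrate a single scheme; see :func:`integrate_schemes`."""
    return integrate_schemes([scheme], glu, duration, **kwargs)[0]


def metrics_vs_control(trajectory: StateTrajectory,
                       control: StateTrajectory,
                       ca_ions: float = 0.0,
                       control_ca_ions: float = 0.0) -> OccupancyMetrics:
    """Per-state additional dwell time and additional Ca2+ influx relative to
    a control run on the same time grid."""
    if trajectory.times.shape != control.times.shape or \
            not np.allclose(trajectory.times, control.times):
        raise ValueError("trajectory and control are on different time grids")
    if trajectory.scheme.states != control.scheme.states:
        raise ValueError("trajectory and control schemes differ")
    diff = trajectory.occupancy - control.occupancy
    t_add = {state: float(np.trapezoid(diff[:, i], trajectory.times))
             for i, state in enumerate(trajectory.scheme.states)}
    return OccupancyMetrics(t_add=t_add, ca_add=float(ca_ions - control_ca_ions))
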