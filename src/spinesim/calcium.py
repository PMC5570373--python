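"""Four-compartment Ca2+ dynamics: the integrating core of the simulator.

Compartments PSD, cytosol, spine neck and dendritic shaft are well-mixed
volumes with nearest-neighbour diffusional exchange.  Each receives Ca2+
influx from its membrane channels (synaptic NMDARs into the PSD,
perisynaptic NMDARs and spine VDCCs into the cytosol, extrasynaptic NMDARs
and shaft VDCCs into the shaft), loses Ca2+ to saturable PMCA and NCX
extrusion pumps balanced by a constant resting leak, and exchanges Ca2+ with
an immobile endogenous buffer.

Per-channel Ca2+ flux uses the Goldman-Hodgkin-Katz form

    J(V) = -P u (Ca_i - Ca_o e^{-u}) / (1 - e^{-u}),   u = 2 F V / R T

with the single-channel Ca2+ permeability ``P`` (um^3/ms) configured per
receptor scheme; NMDAR flux additionally carries the open fraction and the
Mg2+ block factor.

``run_simulation`` chains the full pipeline: glutamate field -> receptor
state trajectories -> membrane potential -> Ca2+ ODEs, and returns traces
plus the eight summary outputs used in the sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .config import GlobalConfig
from .electrics import (ElectricalParams, VoltageTrace, electrical_params,
                        mg_block_factor, simulate_potential)
from .geometry import SpineGeometry, derive_geometry
from .glutamate import (MOLECULES_PER_UM3_PER_UM, GlutamateTrace,
                        astrocytic_pulse_trace, glutamate_params, trace_at_zone)
from .protocols import PerturbationSet, StimulusProtocol, control_perturbation
from .receptors import build_scheme, integrate_schemes, steady_state

__all__ = [
    "CalciumTrace",
    "SimulationResult",
    "ghk_ca_influx",
    "nmdar_ca_flux",
    "assemble_odes",
    "run_simulation",
    "summarize",
    "SUMMARY_OUTPUTS",
]

COMPARTMENTS = ("psd", "cytosol", "neck", "shaft")
INFLUX_CLASSES = ("snr2a", "snr2b", "pnr2b", "enr2b", "vdcc")

#: the eight sensitivity outputs
SUMMARY_OUTPUTS = (
    "ca_ions_snr2a", "ca_ions_snr2b", "ca_ions_pnr2b", "ca_ions_enr2b",
    "ca_peak_spine_uM", "ca_peak_shaft_uM", "v_peak_spine_mV", "v_peak_shaft_mV",
)

_FARADAY_RT_34 = None  # computed per-call from temperature


def _rt_over_f_mV(temperature_c: float) -> float:
    return 8.314462 * (temperature_c + 273.15) / 96485.332 * 1e3


def ghk_ca_influx(p_ca: float, v_mV, ca_in_uM, ca_out_uM: float,
                  temperature_c: float):
    """Single-channel Ca2+ influx (uM um^3 / ms, positive inward) through an
    open pore of GHK permeability ``p_ca``."""
    v = np.asarray(v_mV, dtype=float)
    u = 2.0 * v / _rt_over_f_mV(temperature_c)
    small = np.abs(u) < 1e-9
    us = np.where(small, 1.0, u)
    ratio = np.where(small, ca_out_uM - ca_in_uM,
                     -us * (ca_in_uM - ca_out_uM * np.exp(-us)) / (1.0 - np.exp(-us)))
    out = p_ca * ratio
    return out if out.ndim else float(out)


def nmdar_ca_flux(open_fraction, v_mV, count: int, p_ca: float,
                  params: ElectricalParams, ca_in_uM, ca_out_uM: float,
                  temperature_c: float):
    """Ca2+ influx (uM um^3/ms) through ``count`` NMDARs: open fraction x
    Mg2+ block x GHK driving force."""
    of = np.asarray(open_fraction, dtype=float)
    if np.any(of < -1e-9) or np.any(of > 1 + 1e-9):
        raise ValueError("open fraction must lie in [0, 1]")
    block = mg_block_factor(v_mV, params.mg, params.mg_ic50, params.mg_slope)
    out = count * of * block * ghk_ca_influx(p_ca, v_mV, ca_in_uM, ca_out_uM,
                                             temperature_c)
    return out if np.ndim(out) else float(out)


def ions_to_uM(ions: float, volume_um3: float) -> float:
    return ions / (MOLECULES_PER_UM3_PER_UM * volume_um3)


def uM_to_ions(conc_uM: float, volume_um3: float) -> float:
    return conc_uM * MOLECULES_PER_UM3_PER_UM * volume_um3


@dataclass
class CalciumTrace:
    times: np.ndarray
    free: dict                    # compartment -> uM series
    bound: dict                   # compartment -> uM series
    cumulative_ions: dict         # influx class -> ions series
    spine_head: np.ndarray        # volume-weighted PSD+cytosol readout, uM

    @property
    def peak_spine(self) -> float:
        return float(np.max(self.spine_head))

    @property
    def peak_shaft(self) -> float:
        return float(np.max(self.free["shaft"]))


@dataclass
class SimulationResult:
    protocol: StimulusProtocol
    perturbation: PerturbationSet
    glutamate: dict               # zone -> GlutamateTrace
    trajectories: dict            # class -> StateTrajectory
    voltage: VoltageTrace
    calcium: CalciumTrace
    summary: dict = field(default_factory=dict)


class _Pump:
    """Saturable surface pump (Hill n=1) with a resting-balance leak."""

    def __init__(self, density_per_um2: float, turnover_per_s: float,
                 km_uM: float, area_um2: float):
        self.vmax = density_per_um2 * area_um2 * turnover_per_s * 1e-3 \
            / MOLECULES_PER_UM3_PER_UM     # uM um^3 / ms
        self.km = km_uM

    def rate(self, ca):
        return self.vmax * ca / (ca + self.km)


def _apply_perturbation(config: GlobalConfig, pert: PerturbationSet) -> GlobalConfig:
    cfg = config.copy()
    cfg["glutamate.molecules_per_vesicle"] = float(pert.molecules_per_release)
    cfg["glutamate.b_total_mM"] = config["glutamate.b_total_mM"] * pert.b_total_scale
    cfg["glutamate.glu_rest_uM"] = float(pert.glu_rest_uM)
    for name, n in pert.counts.items():
        cfg[f"receptors.counts.{name}"] = int(n)
    cfg["receptors.eampar_density_per_um2"] = float(pert.eampar_density_per_um2)
    return cfg


def assemble_odes(config: GlobalConfig, geometry: SpineGeometry,
                  times: np.ndarray, open_fractions: dict,
                  voltage: VoltageTrace, counts: dict):
    """Build the Ca2+ right-hand side and the initial state.

    ``open_fractions`` maps the five influx classes to arrays on ``times``
    (vdcc entries are gate traces per compartment).  Returns
    ``(rhs, y0, unpack)`` where the state is [free(4), bound(4), cum(5)].
    """
    cal = config["calcium"]
    T = config.temperature
    ca_out = cal["ca_out_mM"] * 1e3
    ca_rest = cal["ca_rest_uM"]
    vols = np.array([geometry.psd_volume, geometry.cytosol_volume,
                     geometry.neck_volume, geometry.shaft_volume])
    areas = np.array([geometry.psd_membrane_area, geometry.cytosol_membrane_area,
                      geometry.neck_membrane_area, geometry.shaft_membrane_area])

    d_ca = cal["d_ca_um2_per_ms"]
    dist = cal["diffusion_distances_um"]
    cross = np.array([geometry.psd_membrane_area,     # PSD-cytosol interface
                      geometry.neck_cross_section(),  # cytosol-neck
                      geometry.neck_cross_section()])  # neck-shaft
    dists = np.array([dist["psd_cytosol"], dist["cytosol_neck"], dist["neck_shaft"]])
    g_diff = d_ca * cross / dists                     # um^3/ms

    pm = cal["pmca"]
    nx = cal["ncx"]
    pumps = []
    for i, comp in enumerate(COMPARTMENTS):
        where = "spine" if comp in ("psd", "cytosol", "neck") else "shaft"
        pumps.append((
            _Pump(pm[f"density_{where}_per_um2"], pm["turnover_per_s"],
                  pm["km_uM"], areas[i]),
            _Pump(nx[f"density_{where}_per_um2"], nx["turnover_per_s"],
                  nx["km_uM"], areas[i]),
        ))
    leak = np.array([p.rate(ca_rest) + n.rate(ca_rest) for p, n in pumps])

    buf = cal["buffer"]
    b_tot = np.array([buf["total_spine_uM"]] * 3 + [buf["total_shaft_uM"]])
    k_on, k_off = buf["k_on_per_uM_ms"], buf["k_off_per_ms"]

    vd = config["electrics.vdcc"]
    n_vdcc_spine = vd["density_spine_per_um2"] * (areas[0] + areas[1])
    n_vdcc_shaft = vd["density_shaft_per_um2"] * areas[3]
    p_vdcc = vd["ca_permeability_um3_per_ms"]

    el = electrical_params(config, geometry)
    schemes_pca = open_fractions.pop("_p_ca")  # class -> permeability

    def interp(arr):
        return lambda t: float(np.interp(t, times, arr))

    f_open = {k: interp(v) for k, v in open_fractions.items()
              if k in ("snr2a", "snr2b", "pnr2b", "enr2b")}
    f_gate_s = interp(voltage.gate_spine)
    f_gate_d = interp(voltage.gate_shaft)
    f_vs = interp(voltage.v_spine)
    f_vd = interp(voltage.v_shaft)
    n_cls = {k: counts.get(k, 0) for k in ("snr2a", "snr2b", "pnr2b", "enr2b")}

    def rhs(t, y):
        free = y[0:4]
        bound = y[4:8]
        vs, vdv = f_vs(t), f_vd(t)
        # channel influx per class, uM um^3/ms
        j = {}
        for cls, vloc, ca_loc in (("snr2a", vs, free[0]), ("snr2b", vs, free[0]),
                                  ("pnr2b", vs, free[1]), ("enr2b", vdv, free[3])):
            j[cls] = nmdar_ca_flux(f_open[cls](t), vloc, n_cls[cls],
                                   schemes_pca[cls], el, ca_loc, ca_out, T)
        j_vdcc_s = n_vdcc_spine * f_gate_s(t) * ghk_ca_influx(
            p_vdcc, vs, free[1], ca_out, T)
        j_vdcc_d = n_vdcc_shaft * f_gate_d(t) * ghk_ca_influx(
            p_vdcc, vdv, free[3], ca_out, T)
        influx = np.array([j["snr2a"] + j["snr2b"],
                           j["pnr2b"] + j_vdcc_s,
                           0.0,
                           j["enr2b"] + j_vdcc_d])
        extrusion = np.array([p.rate(c) + n.rate(c)
                              for (p, n), c in zip(pumps, free)]) - leak
        b_net = k_on * free * (b_tot - bound) - k_off * bound      # uM/ms
        dfree = (influx - extrusion) / vols - b_net
        exch = g_diff * (free[:-1] - free[1:])                     # uM um^3/ms
        dfree[:-1] -= exch / vols[:-1]
        dfree[1:] += exch / vols[1:]
        dcum = np.array([j["snr2a"], j["snr2b"], j["pnr2b"], j["enr2b"],
                         j_vdcc_s + j_vdcc_d]) * MOLECULES_PER_UM3_PER_UM
        return np.concatenate([dfree, b_net, dcum])

    # fold the background (resting) channel influx into the leak balance so
    # the resting state is an exact fixed point; at y_rest the pump/leak,
    # buffer and diffusion terms vanish, so rhs gives influx/volume directly
    y_rest = np.concatenate([np.full(4, ca_rest),
                             b_tot * ca_rest / (ca_rest + k_off / k_on),
                             np.zeros(5)])
    influx0 = np.asarray(rhs(times[0], y_rest))[:4] * vols
    leak -= influx0

    bound0 = b_tot * ca_rest / (ca_rest + k_off / k_on)
    y0 = np.concatenate([np.full(4, ca_rest), bound0, np.zeros(5)])

    def unpack(t_out, y_out):
        free = {c: y_out[i] for i, c in enumerate(COMPARTMENTS)}
        bound = {c: y_out[4 + i] for i, c in enumerate(COMPARTMENTS)}
        cum = {c: y_out[8 + i] for i, c in enumerate(INFLUX_CLASSES)}
        w = vols[:2] / vols[:2].sum()
        head = w[0] * free["psd"] + w[1] * free["cytosol"]
        return CalciumTrace(times=t_out, free=free, bound=bound,
                            cumulative_ions=cum, spine_head=head)

    return rhs, y0, unpack


def _integrate_calcium(rhs, y0, times, breakpoints, rtol=1e-6, atol=1e-9):
    t0, t1 = float(times[0]), float(times[-1])
    edges = np.unique(np.concatenate([[t0, t1],
                                      [b for b in breakpoints if t0 < b < t1]]))
    ts, ys = [np.array([t0])], [np.asarray(y0)[None, :]]
    y = np.asarray(y0)
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = times[(times > a) & (times <= b)]
        if len(t_eval) == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, first_step=min(1e-3, (b - a) / 10))
        if not sol.success:
            raise ArithmeticError(f"calcium integration failed at t={a}: {sol.message}")
        y = sol.y[:, -1]
        ts.append(sol.t)
        ys.append(sol.y.T)
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=0).T
    out = np.empty((y_all.shape[0], len(times)))
    for i in range(y_all.shape[0]):
        out[i] = np.interp(times, t_all, y_all[i])
    return out


def run_simulation(protocol: StimulusProtocol,
                   perturbation: PerturbationSet | None = None,
                   config: GlobalConfig | None = None,
                   dt_out: float = 0.05) -> SimulationResult:
    """Run the full pipeline for one protocol/perturbation pair."""
    from .config import load_config
    if config is None:
        config = load_config()
    if perturbation is None:
        perturbation = control_perturbation()
    cfg = _apply_perturbation(config, perturbation)
    geometry = derive_geometry(cfg)
    gparams = glutamate_params(cfg)
    duration = protocol.duration

    # stage 1: glutamate
    glu = {}
    for zone in ("synaptic", "perisynaptic", "extrasynaptic"):
        if protocol.astro_pulse is not None and zone == "extrasynaptic":
            onset, width, amp = protocol.astro_pulse
            glu[zone] = astrocytic_pulse_trace(width, amp, gparams, geometry,
                                               duration, onset_ms=onset)
        else:
            glu[zone] = trace_at_zone(protocol.pulse_times, zone, gparams,
                                      geometry, duration)

    # stage 2: receptor kinetics (per class, desensitisation knob per class)
    inh = perturbation.desens_inhibition
    cls_scheme = {
        "snr2a": ("nr2a", "synaptic"), "snr2b": ("nr2b", "synaptic"),
        "sampar": ("ampar", "synaptic"), "pnr2b": ("nr2b", "perisynaptic"),
        "enr2b": ("nr2b", "extrasynaptic"), "eampar": ("ampar", "extrasynaptic"),
    }
    schemes = {c: build_scheme(sub, cfg, desens_inhibition=inh.get(c, 0.0))
               for c, (sub, _) in cls_scheme.items()}
    bps = protocol.breakpoints
    trajectories = {}
    quiescent = len(protocol.pulse_times) == 0 and protocol.astro_pulse is None
    grid = np.arange(0.0, duration + dt_out / 2, dt_out)
    for zone in ("synaptic", "perisynaptic", "extrasynaptic"):
        members = [c for c, (_, z) in cls_scheme.items() if z == zone]
        if quiescent:
            for c in members:
                p = steady_state(schemes[c], glu[zone].rest)
                occ = np.tile(p, (len(grid), 1))
                from .receptors import StateTrajectory
                trajectories[c] = StateTrajectory(schemes[c], grid, occ, glu[zone])
        else:
            trs = integrate_schemes([schemes[c] for c in members], glu[zone],
                                    duration, breakpoints=bps, dt_out=dt_out,
                                    initial_glu=glu[zone].rest)
            trajectories.update(dict(zip(members, trs)))

    times = trajectories["snr2a"].times

    # stage 3: membrane potential
    el = electrical_params(cfg, geometry)
    counts = {c: cfg[f"receptors.counts.{c}"] for c in
              ("snr2a", "snr2b", "pnr2b", "enr2b", "sampar")}
    counts["eampar"] = cfg["receptors.eampar_density_per_um2"] * \
        geometry.shaft_membrane_area
    g_nmdar = {c: schemes[c].conductance_pS * 1e-3 for c in
               ("snr2a", "snr2b", "pnr2b", "enr2b")}
    g_ampar = schemes["sampar"].conductance_pS * 1e-3
    drives = {
        "g_syn_ampar": counts["sampar"] * g_ampar *
            trajectories["sampar"].open_fraction,
        "g_syn_nmdar": counts["snr2a"] * g_nmdar["snr2a"] *
            trajectories["snr2a"].open_fraction
            + counts["snr2b"] * g_nmdar["snr2b"] *
            trajectories["snr2b"].open_fraction,
        "g_peri_nmdar": counts["pnr2b"] * g_nmdar["pnr2b"] *
            trajectories["pnr2b"].open_fraction,
        "g_extra_ampar": counts["eampar"] * g_ampar *
            trajectories["eampar"].open_fraction,
        "g_extra_nmdar": counts["enr2b"] * g_nmdar["enr2b"] *
            trajectories["enr2b"].open_fraction,
    }
    voltage = simulate_potential(times, drives, el, protocol)

    # stage 4: calcium
    open_fr = {c: trajectories[c].open_fraction
               for c in ("snr2a", "snr2b", "pnr2b", "enr2b")}
    open_fr["_p_ca"] = {c: schemes[c].ca_permeability
                        for c in ("snr2a", "snr2b", "pnr2b", "enr2b")}
    rhs, y0, unpack = assemble_odes(cfg, geometry, times, open_fr, voltage, counts)
    y_out = _integrate_calcium(rhs, y0, times, bps)
    calcium = unpack(times, y_out)

    result = SimulationResult(protocol=protocol, perturbation=perturbation,
                              glutamate=glu, trajectories=trajectories,
                              voltage=voltage, calcium=calcium)
    result.summary = summarize(result)
    return result


def summarize(result: SimulationResult) -> dict:
    """The eight sensitivity outputs as a flat record."""
    ca = result.calcium
    v = result.voltage
    return {
        "ca_ions_snr2a": float(ca.cumulative_ions["snr2a"][-1]),
        "ca_ions_snr2b": float(ca.cumulative_ions["snr2b"][-1]),
        "ca_ions_pnr2b": float(ca.cumulative_ions["pnr2b"][-1]),
        "ca_ions_enr2b": float(ca.cumulative_ions["enr2b"][-1]),
        "ca_peak_spine_uM": ca.peak_spine,
        "ca_peak_shaft_uM": ca.peak_shaft,
        "v_peak_spine_mV": v.peak_spine,
        "v_peak_shaft_mV": v.peak_shaft,
    }
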