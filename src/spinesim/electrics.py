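"""Two-compartment membrane-potential model (spine head + dendritic shaft).

The spine head and its parent shaft are RC compartments joined by the neck
resistance.  Synaptic AMPAR and NMDAR currents enter the spine head;
extrasynaptic AMPAR currents enter the shaft, which additionally carries a
resistive/capacitive load standing in for the rest of the dendritic tree.
NMDAR current is gated by the voltage-dependent Mg2+ block in the standard
extracellular-Mg sigmoidal (Jahr-Stevens) form.  Voltage-dependent Ca2+
channels (VDCC) are Hodgkin-Huxley-type activation gates driven by the local
potential; their Ca2+ current is small and is not fed back into the voltage
equation.

Units: mV, ms, pA, pF, nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .config import GlobalConfig
from .geometry import SpineGeometry
from .protocols import StimulusProtocol

__all__ = [
    "ElectricalParams",
    "VoltageTrace",
    "electrical_params",
    "mg_block_factor",
    "vdcc_gate_inf",
    "vdcc_open_fraction",
    "bap_waveform",
    "simulate_potential",
]

_CLAMP_TAU_MS = 0.02  # relaxation time of voltage commands (pairing, bAP)


@dataclass(frozen=True)
class ElectricalParams:
    c_spine: float            # pF
    c_shaft: float            # pF
    g_leak_spine: float       # nS
    g_leak_shaft: float       # nS
    g_neck: float             # nS
    g_load: float             # nS (dendritic tree load on the shaft)
    v_rest: float             # mV
    e_ampar: float
    e_nmdar: float
    mg: float                 # mM
    mg_ic50: float            # mM at 0 mV
    mg_slope: float           # per mV
    g_ampar: float            # nS per channel
    g_nmdar: float            # nS per channel
    vdcc_vhalf: float
    vdcc_slope: float
    vdcc_tau: float
    vdcc_power: int
    bap_amplitude: float
    bap_rise: float
    bap_decay: float
    pairing_voltage: float


def electrical_params(config: GlobalConfig, geometry: SpineGeometry) -> ElectricalParams:
    el = config["electrics"]
    cm = el["membrane_capacitance_pF_per_um2"]
    gl = el["leak_conductance_nS_per_um2"]
    spine_area = geometry.head_membrane_area + geometry.neck_membrane_area
    shaft_area = geometry.shaft_membrane_area
    # nmdar conductance is carried on the schemes; here only AMPAR/NMDAR
    # unitary conductances for current summation
    g_ampar = config["receptors.schemes.ampar.conductance_pS"] * 1e-3
    g_nmdar = config["receptors.schemes.nr2a.conductance_pS"] * 1e-3
    return ElectricalParams(
        c_spine=cm * spine_area,
        c_shaft=cm * shaft_area + el["dendritic_load_capacitance_pF"],
        g_leak_spine=gl * spine_area,
        g_leak_shaft=gl * shaft_area,
        g_neck=1e3 / el["neck_resistance_Mohm"],
        g_load=1e3 / el["dendritic_load_resistance_Mohm"],
        v_rest=el["resting_potential_mV"],
        e_ampar=el["reversal_ampar_mV"],
        e_nmdar=el["reversal_nmdar_mV"],
        mg=el["mg_mM"],
        mg_ic50=el["mg_ic50_0mV_mM"],
        mg_slope=el["mg_slope_per_mV"],
        g_ampar=g_ampar,
        g_nmdar=g_nmdar,
        vdcc_vhalf=el["vdcc"]["vhalf_mV"],
        vdcc_slope=el["vdcc"]["slope_mV"],
        vdcc_tau=el["vdcc"]["tau_ms"],
        vdcc_power=int(el["vdcc"]["gate_power"]),
        bap_amplitude=el["bap"]["amplitude_mV"],
        bap_rise=el["bap"]["rise_ms"],
        bap_decay=el["bap"]["decay_ms"],
        pairing_voltage=el["pairing_voltage_mV"],
    )


def mg_block_factor(v_mV, mg_mM: float, ic50_mM: float = 3.57,
                    slope_per_mV: float = 0.062):
    """Fraction of NMDAR current passed at potential ``v`` under external
    Mg2+ (Jahr-Stevens sigmoid); 1 with no Mg2+, monotone in v, -> 1 as
    v -> +inf."""
    if mg_mM < 0:
        raise ValueError("Mg concentration must be non-negative")
    v = np.asarray(v_mV, dtype=float)
    out = 1.0 / (1.0 + (mg_mM / ic50_mM) * np.exp(-slope_per_mV * v))
    return out if out.ndim else float(out)


def vdcc_gate_inf(v_mV, params: ElectricalParams):
    v = np.asarray(v_mV, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - params.vdcc_vhalf) / params.vdcc_slope))
    return out if out.ndim else float(out)


@dataclass
class VoltageTrace:
    times: np.ndarray
    v_spine: np.ndarray
    v_shaft: np.ndarray
    gate_spine: np.ndarray        # VDCC activation gate (already ^power)
    gate_shaft: np.ndarray
    v_rest: float

    @property
    def epsp_spine(self) -> float:
        """Peak depolarisation above rest in the spine head, mV."""
        return float(np.max(self.v_spine) - self.v_rest)

    @property
    def epsp_shaft(self) -> float:
        return float(np.max(self.v_shaft) - self.v_rest)

    @property
    def peak_spine(self) -> float:
        return float(np.max(self.v_spine))

    @property
    def peak_shaft(self) -> float:
        return float(np.max(self.v_shaft))


def bap_waveform(params: ElectricalParams) -> Callable[[float], float]:
    """Stereotyped AP-shaped depolarisation (difference of exponentials,
    normalised to the configured amplitude) as a function of time since
    onset, mV above rest."""
    rise, decay, amp = params.bap_rise, params.bap_decay, params.bap_amplitude
    if decay <= rise:
        raise ValueError("bAP decay must exceed rise time")
    tpk = rise * decay / (decay - rise) * math.log(decay / rise)
    norm = math.exp(-tpk / decay) - math.exp(-tpk / rise)

    def shape(dt: float) -> float:
        if dt < 0:
            return 0.0
        return amp * (math.exp(-dt / decay) - math.exp(-dt / rise)) / norm

    return shape


def _in_windows(t: float, windows) -> bool:
    return any(a <= t <= b for a, b in windows)


def simulate_potential(times: np.ndarray, drives: dict, params: ElectricalParams,
                       protocol: StimulusProtocol,
                       rtol: float = 1e-6, atol: float = 1e-8) -> VoltageTrace:
    """Integrate the two-compartment voltage model.

    ``drives`` maps conductance sources to open-fraction arrays sampled on
    ``times`` (already multiplied by channel counts):

    * ``g_syn_ampar``, ``g_syn_nmdar`` — spine-head synaptic conductances (nS)
    * ``g_peri_nmdar`` — perisynaptic NMDAR conductance entering the spine (nS)
    * ``g_extra_ampar``, ``g_extra_nmdar`` — shaft conductances (nS)

    NMDAR conductances are multiplied by the Mg2+ block factor at the
    instantaneous local potential inside the right-hand side.
    """
    t0, t1 = float(times[0]), float(times[-1])
    bap = bap_waveform(params)
    bap_end = [t + 6.0 * params.bap_decay for t in protocol.bap_times]

    def interp(key):
        arr = drives.get(key)
        if arr is None:
            return lambda t: 0.0
        return lambda t: float(np.interp(t, times, arr))

    g_sa = interp("g_syn_ampar")
    g_sn = interp("g_syn_nmdar")
    g_pn = interp("g_peri_nmdar")
    g_ea = interp("g_extra_ampar")
    g_en = interp("g_extra_nmdar")

    def rhs(t, y):
        vs, vd, ms, md = y
        block_s = mg_block_factor(vs, params.mg, params.mg_ic50, params.mg_slope)
        block_d = mg_block_factor(vd, params.mg, params.mg_ic50, params.mg_slope)
        i_spine = (g_sa(t) * (vs - params.e_ampar)
                   + (g_sn(t) + g_pn(t)) * block_s * (vs - params.e_nmdar)
                   + params.g_leak_spine * (vs - params.v_rest))
        i_shaft = (g_ea(t) * (vd - params.e_ampar)
                   + g_en(t) * block_d * (vd - params.e_nmdar)
                   + params.g_leak_shaft * (vd - params.v_rest)
                   + params.g_load * (vd - params.v_rest))
        i_neck = params.g_neck * (vs - vd)
        dvs = (-i_spine - i_neck) / params.c_spine
        dvd = (-i_shaft + i_neck) / params.c_shaft
        if _in_windows(t, protocol.pairing_windows):
            dvs = (params.pairing_voltage - vs) / _CLAMP_TAU_MS
            dvd = (params.pairing_voltage - vd) / _CLAMP_TAU_MS
        else:
            for tb, te in zip(protocol.bap_times, bap_end):
                if tb <= t <= te:
                    dvd = (params.v_rest + bap(t - tb) - vd) / _CLAMP_TAU_MS
        dms = (vdcc_gate_inf(vs, params) - ms) / params.vdcc_tau
        dmd = (vdcc_gate_inf(vd, params) - md) / params.vdcc_tau
        return [dvs, dvd, dms, dmd]

    m0 = vdcc_gate_inf(params.v_rest, params)
    y0 = [params.v_rest, params.v_rest, m0, m0]
    edges = np.unique(np.concatenate([[t0, t1],
                                      [b for b in protocol.breakpoints if t0 < b < t1],
                                      [b for b in bap_end if t0 < b < t1]]))
    ts_out, ys_out = [np.array([t0])], [np.array(y0)[None, :]]
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = times[(times > a) & (times <= b)]
        if len(t_eval) == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, first_step=min(1e-3, (b - a) / 10))
        if not sol.success:
            raise ArithmeticError(f"voltage integration failed at t={a}: {sol.message}")
        y = sol.y[:, -1]
        ts_out.append(sol.t)
        ys_out.append(sol.y.T)
    t_all = np.concatenate(ts_out)
    y_all = np.concatenate(ys_out, axis=0)
    # resample on the common grid
    vs = np.interp(times, t_all, y_all[:, 0])
    vd = np.interp(times, t_all, y_all[:, 1])
    ms = np.interp(times, t_all, y_all[:, 2])
    md = np.interp(times, t_all, y_all[:, 3])
    p = params.vdcc_power
    return VoltageTrace(times=times, v_spine=vs, v_shaft=vd,
                        gate_spine=ms**p, gate_shaft=md**p, v_rest=params.v_rest)


def vdcc_open_fraction(times: np.ndarray, v_mV: np.ndarray,
                       params: ElectricalParams,
                       v_init: float | None = None) -> np.ndarray:
    """Integrate the VDCC activation gate along a given voltage trace and
    return the open fraction (gate^power).  The gate starts at its steady
    state for ``v_init`` (default: the first voltage sample)."""
    def rhs(t, m):
        v = float(np.interp(t, times, v_mV))
        return [(vdcc_gate_inf(v, params) - m[0]) / params.vdcc_tau]

    m0 = vdcc_gate_inf(float(v_mV[0]) if v_init is None else v_init, params)
    sol = solve_ivp(rhs, (times[0], times[-1]), [m0], method="LSODA",
                    t_eval=times, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise ArithmeticError(f"VDCC gate integration failed: {sol.message}")
    return sol.y[0] ** params.vdcc_power
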