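"""Downstream CaMKII state transitions driven by spine-head Ca2+.

A structural reimplementation of the kinase cascade that links the Ca2+
transient to early LTP: sequential two-lobe Ca2+ loading of calmodulin to
Ca4CaM, Ca4CaM binding to CaMKII subunits, inter-subunit autophosphorylation
(neighbour-catalysed, approximated by a quadratic dependence on the active
fraction), opposed by a saturable phosphatase (which makes activation
switch-like), translocation of phosphorylated subunits to the PSD, and
anchoring to NR2B tails with a capacity proportional to the PSD NR2B count.
All rates are configurable; defaults are tuned so the qualitative behaviours
(no activation without pairing, blocking thresholds under NR2A reduction,
an interior optimum of the NR2A:NR2B ratio for complex formation) hold.

State variables are concentrations (uM) in the spine head.  CaM and CaMKII
totals are conserved exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .config import GlobalConfig, load_config
from .glutamate import MOLECULES_PER_UM3_PER_UM
from .protocols import PerturbationSet, StimulusProtocol, control_perturbation

__all__ = [
    "CamPools",
    "CamkiiPools",
    "cam_loading",
    "camkii_transition",
    "ratio_experiment",
    "run_cascade",
    "CASCADE_OUTPUTS",
]

CASCADE_OUTPUTS = ("ca4cam", "autophosphorylated", "camkii_psd", "camkii_nmdar")


@dataclass
class CamPools:
    """Calmodulin loading states over time (uM)."""

    times: np.ndarray
    free: np.ndarray          # apo-CaM
    half: np.ndarray          # C-lobe loaded (2 Ca2+)
    full: np.ndarray          # Ca4CaM

    @property
    def total(self) -> np.ndarray:
        return self.free + self.half + self.full


@dataclass
class CamkiiPools:
    """CaMKII subunit states over time (uM) plus the four summary outputs."""

    times: np.ndarray
    inactive: np.ndarray
    cam_bound: np.ndarray
    phosphorylated: np.ndarray     # cytosolic autophosphorylated
    psd: np.ndarray                # PSD-resident, unanchored
    complexed: np.ndarray          # CaMKII-NMDAR complex
    ca4cam: np.ndarray             # free + kinase-bound Ca4CaM
    outputs: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return (self.inactive + self.cam_bound + self.phosphorylated
                + self.psd + self.complexed)


def _count_to_uM(count: float, volume_um3: float) -> float:
    return count / (MOLECULES_PER_UM3_PER_UM * volume_um3)


def _uM_to_count(conc: float, volume_um3: float) -> float:
    return conc * MOLECULES_PER_UM3_PER_UM * volume_um3


def _ca_interp(ca_times: np.ndarray, ca_uM: np.ndarray, rest: float):
    t_end = float(ca_times[-1])

    def ca(t: float) -> float:
        if t >= t_end:
            return rest
        return float(np.interp(t, ca_times, ca_uM))

    return ca, t_end


def cam_loading(ca_times: np.ndarray, ca_uM: np.ndarray,
                config: GlobalConfig | None = None,
                duration_ms: float | None = None) -> CamPools:
    """Integrate sequential two-lobe Ca2+ binding to CaM along a Ca2+ trace.

    Each lobe binds two Ca2+ ions cooperatively; the loading steps are
    mass-action with rate k_on * [Ca]^2.
    """
    if config is None:
        config = load_config()
    p = config["camkii"]
    rest = float(ca_uM[0])
    ca, t_end = _ca_interp(np.asarray(ca_times, float), np.asarray(ca_uM, float), rest)
    duration = duration_ms if duration_ms is not None else t_end
    k1, k1b = p["k_lobe1_on_per_uM2_ms"], p["k_lobe1_off_per_ms"]
    k2, k2b = p["k_lobe2_on_per_uM2_ms"], p["k_lobe2_off_per_ms"]

    def rhs(t, y):
        m0, m2, m4 = y
        c2 = ca(t) ** 2
        j1 = k1 * c2 * m0 - k1b * m2
        j2 = k2 * c2 * m2 - k2b * m4
        return [-j1, j1 - j2, j2]

    y0 = [p["cam_total_uM"], 0.0, 0.0]
    t_eval = np.linspace(0.0, duration, 2001)
    sol = solve_ivp(rhs, (0.0, duration), y0, method="LSODA", t_eval=t_eval,
                    rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise ArithmeticError(f"CaM loading integration failed: {sol.message}")
    return CamPools(times=sol.t, free=sol.y[0], half=sol.y[1], full=sol.y[2])


def camkii_transition(ca_times: np.ndarray, ca_uM: np.ndarray, nr2b_count: int,
                      config: GlobalConfig | None = None,
                      duration_s: float = 300.0,
                      spine_volume_um3: float = 0.1) -> CamkiiPools:
    """Integrate the full cascade for ``duration_s`` seconds of biological
    time; the Ca2+ trace is held at its resting value beyond its end.

    Returns the state trajectories and the four summary outputs (molecule
    counts in the spine head): peak Ca4CaM, peak autophosphorylated
    subunits, peak PSD-resident CaMKII, and the final CaMKII-NMDAR complex
    level.
    """
    if nr2b_count < 0:
        raise ValueError("NR2B count must be non-negative")
    if config is None:
        config = load_config()
    p = config["camkii"]
    rest = float(ca_uM[0])
    ca, t_end = _ca_interp(np.asarray(ca_times, float), np.asarray(ca_uM, float), rest)
    duration = duration_s * 1e3

    k1, k1b = p["k_lobe1_on_per_uM2_ms"], p["k_lobe1_off_per_ms"]
    k2, k2b = p["k_lobe2_on_per_uM2_ms"], p["k_lobe2_off_per_ms"]
    ka, kub = p["k_cam_bind_per_uM_ms"], p["k_cam_unbind_per_ms"]
    kauto = p["k_auto_per_ms"]
    vpp, kmpp = p["v_phosphatase_uM_per_ms"], p["km_phosphatase_uM"]
    ktr, kret = p["k_translocate_per_ms"], p["k_return_per_ms"]
    kbind, kunb = p["k_slot_bind_per_uM_ms"], p["k_slot_unbind_per_ms"]
    ktot = p["camkii_total_uM"]
    cap = p["slots_per_nr2b"] * _count_to_uM(nr2b_count, spine_volume_um3)

    # y = [M0, M2, M4, K, KC, KP, KD, KN]
    def rhs(t, y):
        m0, m2, m4, k, kc, kp, kd, kn = y
        c2 = ca(t) ** 2
        j1 = k1 * c2 * m0 - k1b * m2
        j2 = k2 * c2 * m2 - k2b * m4
        jbind = ka * m4 * k - kub * kc
        act = max(kc + kp + kd + kn, 0.0) / ktot
        jauto = kauto * kc * act * act          # CaM released on autophosphorylation
        jpp = vpp * kp / (kmpp + kp)
        jtr = ktr * kp - kret * kd
        jslot = kbind * kd * max(cap - kn, 0.0) - kunb * kn
        return [
            -j1,
            j1 - j2,
            j2 - jbind + jauto,
            -jbind + jpp,
            jbind - jauto,
            jauto - jpp - jtr,
            jtr - jslot,
            jslot,
        ]

    y0 = [p["cam_total_uM"], 0.0, 0.0, ktot, 0.0, 0.0, 0.0, 0.0]
    # dense sampling through the stimulation window, coarse afterwards
    t_eval = np.unique(np.concatenate([
        np.linspace(0.0, min(t_end, duration), 1001),
        np.linspace(0.0, duration, 1501),
    ]))
    sol = solve_ivp(rhs, (0.0, duration), y0, method="LSODA", t_eval=t_eval,
                    rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise ArithmeticError(f"CaMKII cascade integration failed: {sol.message}")
    m0, m2, m4, k, kc, kp, kd, kn = sol.y
    pools = CamkiiPools(
        times=sol.t, inactive=k, cam_bound=kc, phosphorylated=kp,
        psd=kd, complexed=kn, ca4cam=m4 + kc,
    )
    to_n = lambda c: _uM_to_count(c, spine_volume_um3)
    pools.outputs = {
        "ca4cam": to_n(float(np.max(m4 + kc))),
        "autophosphorylated": to_n(float(np.max(kp + kd + kn))),
        "camkii_psd": to_n(float(np.max(kd + kn))),
        "camkii_nmdar": to_n(float(kn[-1])),
    }
    return pools


def run_cascade(protocol: StimulusProtocol,
                perturbation: PerturbationSet | None = None,
                config: GlobalConfig | None = None,
                duration_s: float = 300.0):
    """Full pipeline: Ca2+ model then CaMKII cascade.  Returns
    ``(SimulationResult, CamkiiPools)``."""
    from .calcium import run_simulation
    if config is None:
        config = load_config()
    if perturbation is None:
        perturbation = control_perturbation()
    sim = run_simulation(protocol, perturbation, config)
    ca = sim.calcium
    pools = camkii_transition(ca.times, ca.spine_head,
                              perturbation.counts.get("snr2b", 8),
                              config=config, duration_s=duration_s)
    return sim, pools


def ratio_experiment(ratios, protocol: StimulusProtocol,
                     config: GlobalConfig | None = None,
                     total: int = 20, duration_s: float = 300.0) -> dict:
    """Run the cascade across PSD NR2A:NR2B splits at fixed total and
    normalise the four outputs to the control split (12:8).

    ``ratios`` is an iterable of ``(nr2a, nr2b)`` pairs summing to ``total``.
    Returns a dict with the normalised output table, the raw control
    outputs, and the argmax ratio for complex formation.
    """
    if config is None:
        config = load_config()
    control = control_perturbation()
    _, ctrl_pools = run_cascade(protocol, control, config, duration_s)
    ctrl = ctrl_pools.outputs
    rows = []
    for nr2a, nr2b in ratios:
        if nr2a + nr2b != total:
            raise ValueError(f"ratio {nr2a}:{nr2b} does not sum to {total}")
        pert = control.with_ratio(nr2a, nr2b)
        _, pools = run_cascade(protocol, pert, config, duration_s)
        row = {"nr2a": nr2a, "nr2b": nr2b}
        for key in CASCADE_OUTPUTS:
            row[key] = pools.outputs[key] / ctrl[key] if ctrl[key] > 0 else np.nan
        rows.append(row)
    best = max(rows, key=lambda r: (r["camkii_nmdar"]
                                    if np.isfinite(r["camkii_nmdar"]) else -1))
    return {"table": rows, "control_outputs": ctrl,
            "argmax_ratio": (best["nr2a"], best["nr2b"])}
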