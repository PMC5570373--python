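"""Global sensitivity analysis and Bayesian parameter calibration.

Two independent pieces:

* **LHS + PRCC.**  Latin hypercube sampling over the fifteen perturbation
  factors (release size, resting glutamate, transporter level, six
  desensitisation-inhibition fractions, five receptor counts and the
  extrasynaptic AMPAR density), the full simulator run per design row, and
  partial rank correlation coefficients between each factor and the eight
  summary outputs.  PRCC is computed by rank-transforming the design and
  output columns, residualising each against all remaining factors by
  ordinary least squares, and correlating the residuals; p-values use the
  t approximation with ``df = n - 2 - p`` (p factors partialled out).

* **MCMC calibration.**  Affine-invariant ensemble sampling (emcee) of the
  ten uncertain Ca2+-model parameters (VDCC, PMCA and NCX surface densities
  and immobile-buffer concentrations, each for the spine and dendrite
  locations, plus the shared buffer on/off rates) against the amplitude and
  decay time constant of the Ca2+ transient evoked by a single
  backpropagating action potential in the spine and the parent dendrite.
  Priors are log-uniform spanning a factor of ten either side of the
  defaults; the likelihood is Gaussian in the four transient features.
  Because the bAP voltage command does not depend on any of the ten
  parameters, the glutamate/receptor/voltage stages are computed once and
  only the Ca2+ ODE stage is repeated per likelihood evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .calcium import (SUMMARY_OUTPUTS, _integrate_calcium, assemble_odes,
                      run_simulation)
from .config import GlobalConfig, load_config
from .protocols import PerturbationSet, bap_protocol, control_perturbation, make_train

__all__ = [
    "FACTORS",
    "CalibrationTarget",
    "SensitivityResult",
    "PosteriorSample",
    "lhs_sample",
    "prcc",
    "sensitivity_experiment",
    "BapFeatureModel",
    "mcmc_calibrate",
    "MCMC_PARAMETERS",
]

#: the fifteen sensitivity factors: name -> (low, high, integer?)
FACTORS = {
    "G0": (500.0, 10000.0, True),
    "glu_rest": (0.0, 1.0, False),          # uM
    "TP": (0.0, 1.0, False),                # transporter concentration, mM
    "Ds2A": (0.0, 1.0, False),
    "Ds2B": (0.0, 1.0, False),
    "DsAMPAR": (0.0, 1.0, False),
    "Dp2B": (0.0, 1.0, False),
    "De2B": (0.0, 1.0, False),
    "DeAMPAR": (0.0, 1.0, False),
    "n_snr2a": (6, 18, True),
    "n_snr2b": (4, 12, True),
    "n_sampar": (43, 130, True),
    "n_pnr2b": (1, 5, True),
    "n_enr2b": (4, 12, True),
    "eampar_density": (15.0, 30.0, False),
}

_CONTROL_TP_MM = 0.5


def lhs_sample(n: int, seed: int, factors: dict | None = None) -> pd.DataFrame:
    """Stratified Latin hypercube design: one sample per equal-probability
    bin per factor; integer factors are rounded."""
    if n < 2:
        raise ValueError("LHS needs at least two samples")
    factors = FACTORS if factors is None else factors
    sampler = qmc.LatinHypercube(d=len(factors), seed=seed)
    unit = sampler.random(n)
    cols = {}
    for j, (name, (lo, hi, integer)) in enumerate(factors.items()):
        x = lo + unit[:, j] * (hi - lo)
        cols[name] = np.round(x).astype(int) if integer else x
    return pd.DataFrame(cols)


def row_to_perturbation(row) -> PerturbationSet:
    """Translate one design row into a perturbation set."""
    base = control_perturbation()
    counts = dict(base.counts)
    counts.update(snr2a=int(row["n_snr2a"]), snr2b=int(row["n_snr2b"]),
                  sampar=int(row["n_sampar"]), pnr2b=int(row["n_pnr2b"]),
                  enr2b=int(row["n_enr2b"]))
    inh = {"snr2a": row["Ds2A"], "snr2b": row["Ds2B"], "sampar": row["DsAMPAR"],
           "pnr2b": row["Dp2B"], "enr2b": row["De2B"], "eampar": row["DeAMPAR"]}
    return PerturbationSet(
        molecules_per_release=float(row["G0"]),
        b_total_scale=float(row["TP"]) / _CONTROL_TP_MM,
        glu_rest_uM=float(row["glu_rest"]),
        counts=counts,
        eampar_density_per_um2=float(row["eampar_density"]),
        desens_inhibition={k: float(v) for k, v in inh.items()},
    )


@dataclass
class SensitivityResult:
    prcc: pd.DataFrame                 # factor x output
    pvalue: pd.DataFrame
    n: int
    significant: pd.DataFrame = field(init=False)
    failures: int = 0
    constant_outputs: list = field(default_factory=list)

    def __post_init__(self):
        self.significant = (self.prcc.abs() > 0.5) & (self.pvalue < 0.05)

    def masked_table(self) -> pd.DataFrame:
        """Long-form table matching the heat-map layout: one row per
        (factor, output) with the PRCC, p-value and significance flag."""
        rows = []
        for f in self.prcc.index:
            for o in self.prcc.columns:
                rows.append({"factor": f, "output": o,
                             "prcc": self.prcc.loc[f, o],
                             "p_value": self.pvalue.loc[f, o],
                             "significant": bool(self.significant.loc[f, o])})
        return pd.DataFrame(rows)


def _rank(a: np.ndarray) -> np.ndarray:
    return np.column_stack([stats.rankdata(a[:, j]) for j in range(a.shape[1])])


def prcc(X, Y, factor_names=None, output_names=None) -> SensitivityResult:
    """Partial rank correlation of each design factor with each output.

    Constant output columns are flagged (NaN PRCC) rather than computed;
    a rank-deficient design raises with the offending factors named.
    """
    if isinstance(X, pd.DataFrame):
        factor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    if isinstance(Y, pd.DataFrame):
        output_names = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y must have aligned rows")
    factor_names = factor_names or [f"x{j}" for j in range(k)]
    output_names = output_names or [f"y{j}" for j in range(Y.shape[1])]

    rx = _rank(X)
    const_out = [output_names[j] for j in range(Y.shape[1])
                 if np.ptp(Y[:, j]) == 0]
    ry = _rank(Y)
    pr = np.full((k, Y.shape[1]), np.nan)
    pv = np.full((k, Y.shape[1]), np.nan)
    df = n - 2 - (k - 1)
    if df < 1:
        raise ValueError("not enough samples for the number of factors")
    for j in range(k):
        others = np.delete(rx, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient design; collinear factors among "
                f"{[f for i, f in enumerate(factor_names) if i != j]}")
        beta_x, *_ = np.linalg.lstsq(design, rx[:, j], rcond=None)
        resid_x = rx[:, j] - design @ beta_x
        for m in range(Y.shape[1]):
            if output_names[m] in const_out:
                continue
            beta_y, *_ = np.linalg.lstsq(design, ry[:, m], rcond=None)
            resid_y = ry[:, m] - design @ beta_y
            denom = np.linalg.norm(resid_x) * np.linalg.norm(resid_y)
            r = float(resid_x @ resid_y / denom) if denom > 0 else np.nan
            pr[j, m] = r
            if np.isfinite(r) and abs(r) < 1:
                t = r * np.sqrt(df / (1.0 - r * r))
                pv[j, m] = 2.0 * stats.t.sf(abs(t), df)
            elif np.isfinite(r):
                pv[j, m] = 0.0
    return SensitivityResult(
        prcc=pd.DataFrame(pr, index=factor_names, columns=output_names),
        pvalue=pd.DataFrame(pv, index=factor_names, columns=output_names),
        n=n, constant_outputs=const_out)


def sensitivity_experiment(protocol: str, n: int, seed: int,
                           config: GlobalConfig | None = None,
                           train_duration_ms: float | None = None,
                           post_train_ms: float | None = None,
                           verbose: bool = False) -> SensitivityResult:
    """LHS design -> full simulator per row -> PRCC over the eight outputs.

    ``protocol`` is "lfs" (10 Hz) or "hfs" (100 Hz); ``train_duration_ms``
    can shorten the train for inexpensive designs.  Failed rows are excluded
    and counted.
    """
    if config is None:
        config = load_config()
    freq = {"lfs": 10.0, "hfs": 100.0}[protocol.lower()]
    duration = train_duration_ms or config["protocol.train_duration_ms"]
    if post_train_ms is None:
        post_train_ms = config["protocol.post_train_ms"]
    proto = make_train(freq, duration_ms=duration, post_train_ms=post_train_ms)
    design = lhs_sample(n, seed)
    outputs, ok_rows = [], []
    failures = 0
    for i, row in design.iterrows():
        try:
            res = run_simulation(proto, row_to_perturbation(row), config)
            outputs.append([res.summary[k] for k in SUMMARY_OUTPUTS])
            ok_rows.append(i)
        except (ArithmeticError, ValueError):
            failures += 1
        if verbose and (i + 1) % 10 == 0:
            print(f"  {i + 1}/{n} rows done", flush=True)
    Y = pd.DataFrame(outputs, columns=list(SUMMARY_OUTPUTS))
    result = prcc(design.loc[ok_rows], Y)
    result.failures = failures
    return result


# ---------------------------------------------------------------------------
# MCMC calibration against bAP-evoked transients
# ---------------------------------------------------------------------------

MCMC_PARAMETERS = (
    "vdcc_density_spine", "vdcc_density_shaft",
    "pmca_density_spine", "pmca_density_shaft",
    "ncx_density_spine", "ncx_density_shaft",
    "buffer_total_spine", "buffer_total_shaft",
    "buffer_k_on", "buffer_k_off",
)

_PARAM_KEYS = {
    "vdcc_density_spine": "electrics.vdcc.density_spine_per_um2",
    "vdcc_density_shaft": "electrics.vdcc.density_shaft_per_um2",
    "pmca_density_spine": "calcium.pmca.density_spine_per_um2",
    "pmca_density_shaft": "calcium.pmca.density_shaft_per_um2",
    "ncx_density_spine": "calcium.ncx.density_spine_per_um2",
    "ncx_density_shaft": "calcium.ncx.density_shaft_per_um2",
    "buffer_total_spine": "calcium.buffer.total_spine_uM",
    "buffer_total_shaft": "calcium.buffer.total_shaft_uM",
    "buffer_k_on": "calcium.buffer.k_on_per_uM_ms",
    "buffer_k_off": "calcium.buffer.k_off_per_ms",
}

FEATURES = ("amp_spine_uM", "tau_spine_ms", "amp_shaft_uM", "tau_shaft_ms")


@dataclass(frozen=True)
class CalibrationTarget:
    """bAP-evoked Ca2+ transient features with uncertainties (synthetic
    stand-ins for the experimental dataset)."""

    amp_spine_uM: float
    tau_spine_ms: float
    amp_shaft_uM: float
    tau_shaft_ms: float
    sigma_amp_spine: float = 0.05
    sigma_tau_spine: float = 5.0
    sigma_amp_shaft: float = 0.01
    sigma_tau_shaft: float = 10.0

    def __post_init__(self):
        for name in FEATURES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURES])

    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_amp_spine, self.sigma_tau_spine,
                         self.sigma_amp_shaft, self.sigma_tau_shaft])


def transient_features(times: np.ndarray, trace: np.ndarray,
                       rest: float) -> tuple[float, float]:
    """Amplitude above rest and 1/e decay time of a transient."""
    i_pk = int(np.argmax(trace))
    amp = float(trace[i_pk] - rest)
    if amp <= 0:
        return 0.0, np.nan
    target = rest + amp / np.e
    tail = trace[i_pk:]
    below = np.nonzero(tail <= target)[0]
    if len(below) == 0:
        return amp, float(times[-1] - times[i_pk])
    j = below[0]
    t_hi, t_lo = times[i_pk + j], times[i_pk + j - 1] if j > 0 else times[i_pk]
    c_hi, c_lo = tail[j], tail[j - 1] if j > 0 else tail[0]
    if c_lo == c_hi:
        tau = t_hi - times[i_pk]
    else:
        frac = (c_lo - target) / (c_lo - c_hi)
        tau = t_lo + frac * (t_hi - t_lo) - times[i_pk]
    return amp, float(tau)


class BapFeatureModel:
    """Cached bAP pipeline: glutamate/receptor/voltage stages run once, the
    Ca2+ stage re-runs per parameter vector."""

    def __init__(self, config: GlobalConfig | None = None,
                 total_ms: float = 200.0):
        from .electrics import electrical_params
        from .geometry import derive_geometry
        self.config = config.copy() if config is not None else load_config()
        self.protocol = bap_protocol(total_ms=total_ms)
        base = run_simulation(self.protocol, control_perturbation(), self.config)
        self._times = base.calcium.times
        self._voltage = base.voltage
        self._open = {c: base.trajectories[c].open_fraction
                      for c in ("snr2a", "snr2b", "pnr2b", "enr2b")}
        self._schemes_pca = {c: base.trajectories[c].scheme.ca_permeability
                             for c in ("snr2a", "snr2b", "pnr2b", "enr2b")}
        self._counts = {c: self.config[f"receptors.counts.{c}"]
                        for c in ("snr2a", "snr2b", "pnr2b", "enr2b")}
        self._geometry = derive_geometry(self.config)
        self.ca_rest = self.config["calcium.ca_rest_uM"]

    def default_theta(self) -> np.ndarray:
        return np.array([self.config[_PARAM_KEYS[p]] for p in MCMC_PARAMETERS])

    def simulate(self, theta) -> dict:
        cfg = self.config.copy()
        for name, value in zip(MCMC_PARAMETERS, theta):
            cfg[_PARAM_KEYS[name]] = float(value)
        open_fr = dict(self._open)
        open_fr["_p_ca"] = dict(self._schemes_pca)
        rhs, y0, unpack = assemble_odes(cfg, self._geometry, self._times,
                                        open_fr, self._voltage, self._counts)
        y = _integrate_calcium(rhs, y0, self._times, self.protocol.bap_times)
        return {"calcium": unpack(self._times, y)}

    # -- fast likelihood path -------------------------------------------
    def _precompute_unit_fluxes(self):
        """Per-compartment drive fluxes that do not depend on the ten
        calibrated parameters: total NMDAR Ca2+ influx (uM um^3/ms) and the
        per-channel VDCC flux for the spine and shaft, all on the cached
        time grid (receptor Ca2+ back-flux dependence on intracellular Ca2+
        is evaluated at rest; the error is < 1e-3 at these levels)."""
        from .calcium import ghk_ca_influx, nmdar_ca_flux
        from .electrics import electrical_params
        cfg, v = self.config, self._voltage
        el = electrical_params(cfg, self._geometry)
        T = cfg.temperature
        ca_out = cfg["calcium.ca_out_mM"] * 1e3
        rest = self.ca_rest
        j_psd = np.zeros_like(self._times)
        j_cyt = np.zeros_like(self._times)
        j_shaft = np.zeros_like(self._times)
        for cls, vloc, tgt in (("snr2a", v.v_spine, "psd"), ("snr2b", v.v_spine, "psd"),
                               ("pnr2b", v.v_spine, "cyt"), ("enr2b", v.v_shaft, "sh")):
            j = nmdar_ca_flux(self._open[cls], vloc, self._counts[cls],
                              self._schemes_pca[cls], el, rest, ca_out, T)
            if tgt == "psd":
                j_psd += j
            elif tgt == "cyt":
                j_cyt += j
            else:
                j_shaft += j
        p_vdcc = cfg["electrics.vdcc.ca_permeability_um3_per_ms"]
        vdcc_unit_spine = v.gate_spine * ghk_ca_influx(p_vdcc, v.v_spine, rest,
                                                       ca_out, T)
        vdcc_unit_shaft = v.gate_shaft * ghk_ca_influx(p_vdcc, v.v_shaft, rest,
                                                       ca_out, T)
        self._unit = (j_psd, j_cyt, j_shaft, vdcc_unit_spine, vdcc_unit_shaft)

    def features_fast(self, theta) -> np.ndarray:
        """Features via a reduced Ca2+ integration that rebuilds only the
        theta-dependent terms (pump/buffer/VDCC scaling)."""
        from scipy.integrate import solve_ivp
        if not hasattr(self, "_unit"):
            self._precompute_unit_fluxes()
        (vdcc_s, vdcc_sh, pmca_s, pmca_sh, ncx_s, ncx_sh,
         btot_s, btot_sh, k_on, k_off) = [float(x) for x in theta]
        cfg, g = self.config, self._geometry
        cal = cfg["calcium"]
        vols = np.array([g.psd_volume, g.cytosol_volume, g.neck_volume,
                         g.shaft_volume])
        areas = np.array([g.psd_membrane_area, g.cytosol_membrane_area,
                          g.neck_membrane_area, g.shaft_membrane_area])
        dist = cal["diffusion_distances_um"]
        cross = np.array([g.psd_membrane_area, g.neck_cross_section(),
                          g.neck_cross_section()])
        g_diff = cal["d_ca_um2_per_ms"] * cross / np.array(
            [dist["psd_cytosol"], dist["cytosol_neck"], dist["neck_shaft"]])
        pm, nx = cal["pmca"], cal["ncx"]
        dens_p = np.array([pmca_s, pmca_s, pmca_s, pmca_sh])
        dens_n = np.array([ncx_s, ncx_s, ncx_s, ncx_sh])
        vmax_p = dens_p * areas * pm["turnover_per_s"] * 1e-3 / 602.214
        vmax_n = dens_n * areas * nx["turnover_per_s"] * 1e-3 / 602.214
        km_p, km_n = pm["km_uM"], nx["km_uM"]
        rest = self.ca_rest
        leak = vmax_p * rest / (rest + km_p) + vmax_n * rest / (rest + km_n)
        b_tot = np.array([btot_s, btot_s, btot_s, btot_sh])
        n_vdcc = np.array([0.0, vdcc_s * (areas[0] + areas[1]), 0.0,
                           vdcc_sh * areas[3]])
        times = self._times
        j_psd, j_cyt, j_sh, u_s, u_sh = self._unit

        def rhs(t, y):
            free, bound = y[:4], y[4:8]
            j = np.array([np.interp(t, times, j_psd),
                          np.interp(t, times, j_cyt)
                          + n_vdcc[1] * np.interp(t, times, u_s),
                          0.0,
                          np.interp(t, times, j_sh)
                          + n_vdcc[3] * np.interp(t, times, u_sh)])
            ext = vmax_p * free / (free + km_p) + vmax_n * free / (free + km_n) \
                - leak
            b_net = k_on * free * (b_tot - bound) - k_off * bound
            dfree = (j - ext) / vols - b_net
            exch = g_diff * (free[:-1] - free[1:])
            dfree[:-1] -= exch / vols[:-1]
            dfree[1:] += exch / vols[1:]
            return np.concatenate([dfree, b_net])

        bound0 = b_tot * rest / (rest + k_off / k_on)
        y0 = np.concatenate([np.full(4, rest), bound0])
        t_out = times[::4]  # 0.2 ms output grid resolves the ~3 ms decays
        sol = solve_ivp(rhs, (t_out[0], t_out[-1]), y0, method="LSODA",
                        t_eval=t_out, rtol=1e-6, atol=1e-9)
        if not sol.success:
            raise ArithmeticError(f"fast Ca integration failed: {sol.message}")
        free = sol.y[:4]
        w = vols[:2] / vols[:2].sum()
        head = w[0] * free[0] + w[1] * free[1]
        a_sp, t_sp = transient_features(t_out, head, rest)
        a_sh, t_sh = transient_features(t_out, free[3], rest)
        return np.array([a_sp, t_sp, a_sh, t_sh])

    def features(self, theta) -> np.ndarray:
        ca = self.simulate(theta)["calcium"]
        a_sp, t_sp = transient_features(ca.times, ca.spine_head, self.ca_rest)
        a_sh, t_sh = transient_features(ca.times, ca.free["shaft"], self.ca_rest)
        return np.array([a_sp, t_sp, a_sh, t_sh])

    def target_from(self, theta, noise_level: float = 0.0,
                    seed: int | None = None) -> CalibrationTarget:
        """Simulate at ``theta`` and wrap the (optionally noise-corrupted)
        features as a calibration target."""
        f = self.features(theta)
        if noise_level > 0:
            rng = np.random.default_rng(seed)
            f = f * (1.0 + noise_level * rng.standard_normal(4))
            f = np.abs(f)
        return CalibrationTarget(*f,
                                 sigma_amp_spine=max(0.05 * f[0], 1e-4),
                                 sigma_tau_spine=max(0.05 * f[1], 1e-2),
                                 sigma_amp_shaft=max(0.05 * f[2], 1e-5),
                                 sigma_tau_shaft=max(0.05 * f[3], 1e-2))


@dataclass
class PosteriorSample:
    parameter_names: tuple
    chain: np.ndarray            # (n_steps, n_walkers, n_dim), natural units
    log_prob: np.ndarray
    acceptance_fraction: np.ndarray
    seed: int
    prior_low: np.ndarray
    prior_high: np.ndarray

    def flat(self, burn: int | None = None) -> np.ndarray:
        burn = self.chain.shape[0] // 4 if burn is None else burn
        return self.chain[burn:].reshape(-1, self.chain.shape[2])

    def credible_interval(self, level: float = 0.95, burn: int | None = None):
        lo = (1.0 - level) / 2.0
        flat = self.flat(burn)
        return (np.quantile(flat, lo, axis=0), np.quantile(flat, 1.0 - lo, axis=0))

    def ess(self, burn: int | None = None) -> np.ndarray:
        """Crude effective sample size from the walker-averaged
        autocorrelation time."""
        import emcee.autocorr as ac
        burn = self.chain.shape[0] // 4 if burn is None else burn
        chain = self.chain[burn:]
        n = chain.shape[0] * chain.shape[1]
        try:
            tau = ac.integrated_time(chain, quiet=True)
        except Exception:
            tau = np.full(chain.shape[2], np.nan)
        return n / np.maximum(tau, 1.0)

    def gelman_rubin(self, burn: int | None = None) -> np.ndarray:
        """Split-walker potential scale reduction factor per parameter."""
        burn = self.chain.shape[0] // 4 if burn is None else burn
        c = self.chain[burn:]
        m = c.shape[1]
        means = c.mean(axis=0)
        var_w = c.var(axis=0, ddof=1).mean(axis=0)
        var_b = c.shape[0] * means.var(axis=0, ddof=1)
        var_hat = (c.shape[0] - 1) / c.shape[0] * var_w + var_b / c.shape[0]
        return np.sqrt(var_hat / var_w)


def mcmc_calibrate(target: CalibrationTarget, n_walkers: int = 24,
                   n_steps: int = 400, seed: int = 0,
                   config: GlobalConfig | None = None,
                   prior_span: float = 10.0,
                   model: BapFeatureModel | None = None) -> PosteriorSample:
    """Sample the posterior of the ten Ca2+-model parameters given bAP
    transient features, with log-uniform priors spanning ``prior_span``
    either side of the configured defaults."""
    import emcee

    if model is None:
        model = BapFeatureModel(config)
    if n_walkers < 2 * len(MCMC_PARAMETERS):
        raise ValueError("need at least twice as many walkers as parameters")
    theta0 = model.default_theta()
    low = np.log(theta0 / prior_span)
    high = np.log(theta0 * prior_span)
    values = target.values()
    sigmas = target.sigmas()

    def log_prob(log_theta):
        if np.any(log_theta < low) or np.any(log_theta > high):
            return -np.inf
        try:
            f = model.features_fast(np.exp(log_theta))
        except (ArithmeticError, ValueError):
            return -np.inf
        if not np.all(np.isfinite(f)):
            return -np.inf
        return -0.5 * float(np.sum(((f - values) / sigmas) ** 2))

    rng = np.random.default_rng(seed)
    ndim = len(MCMC_PARAMETERS)
    p0 = np.log(theta0) + 0.05 * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, low + 1e-6, high - 1e-6)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, n_steps, progress=False)
    return PosteriorSample(
        parameter_names=MCMC_PARAMETERS,
        chain=np.exp(sampler.get_chain()),
        log_prob=sampler.get_log_prob(),
        acceptance_fraction=sampler.acceptance_fraction,
        seed=seed,
        prior_low=np.exp(low),
        prior_high=np.exp(high),
    )
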