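"""Stimulation protocols and amyloid-beta-oligomer perturbation sets.

Protocols describe what the presynaptic terminal, the astrocyte and the
recording electrode do: presynaptic pulse trains (single pulse, 10 Hz LFS,
100 Hz HFS, theta-burst trains), an optional pairing depolarisation of the
postsynaptic membrane during the train, an optional square pulse of ambient
glutamate mimicking astrocytic release, and an optional backpropagating
action potential command used for calibration runs.

Perturbation sets hold the disease-mimicking knobs: glutamate molecules per
release (G0), transporter level scale, resting extrasynaptic glutamate,
receptor counts per class, and per-class desensitisation inhibition
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusProtocol",
    "PerturbationSet",
    "make_train",
    "single_pulse",
    "make_tbs",
    "astro_protocol",
    "bap_protocol",
    "control_perturbation",
    "sweep",
    "RECEPTOR_CLASSES",
]

RECEPTOR_CLASSES = ("snr2a", "snr2b", "pnr2b", "enr2b", "sampar", "eampar")

#: PSD NMDAR complement under control conditions (12 NR2A + 8 NR2B)
PSD_NMDAR_TOTAL = 20


@dataclass(frozen=True)
class StimulusProtocol:
    name: str
    pulse_times: tuple[float, ...] = ()          # ms
    duration: float = 500.0                      # ms, total simulated window
    pairing_windows: tuple[tuple[float, float], ...] = ()
    astro_pulse: tuple[float, float, float] | None = None  # onset, width, uM
    bap_times: tuple[float, ...] = ()

    def __post_init__(self):
        times = np.asarray(self.pulse_times)
        if times.size and (np.any(np.diff(times) < 0) or np.any(times < 0)):
            raise ValueError("pulse times must be sorted and non-negative")
        if times.size and times.max() > self.duration:
            raise ValueError("pulse times must lie within the protocol duration")

    @property
    def breakpoints(self) -> tuple[float, ...]:
        pts = list(self.pulse_times) + list(self.bap_times)
        for w in self.pairing_windows:
            pts.extend(w)
        if self.astro_pulse is not None:
            onset, width, _ = self.astro_pulse
            pts.extend((onset, onset + width))
        return tuple(sorted(set(pts)))


@dataclass(frozen=True)
class PerturbationSet:
    """Deviations from the control condition; absent knobs stay at control."""

    molecules_per_release: float = 1500.0
    b_total_scale: float = 1.0
    glu_rest_uM: float = 0.25
    counts: dict = field(default_factory=lambda: {
        "snr2a": 12, "snr2b": 8, "pnr2b": 3, "enr2b": 8, "sampar": 85})
    eampar_density_per_um2: float = 20.0
    desens_inhibition: dict = field(default_factory=lambda: {
        c: 0.0 for c in RECEPTOR_CLASSES})

    def __post_init__(self):
        if self.molecules_per_release < 0 or self.glu_rest_uM < 0:
            raise ValueError("release size and resting glutamate must be >= 0")
        if not 0.0 <= self.b_total_scale:
            raise ValueError("transporter scale must be >= 0")
        for name, n in self.counts.items():
            if n < 0:
                raise ValueError(f"receptor count {name} must be >= 0")
        for name, f in self.desens_inhibition.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"desensitisation inhibition {name} must be in [0,1]")

    def with_ratio(self, nr2a: int, nr2b: int) -> "PerturbationSet":
        """Set the PSD NR2A:NR2B split; the total must stay at 20."""
        if nr2a + nr2b != PSD_NMDAR_TOTAL:
            raise ValueError(f"PSD NMDAR total must stay {PSD_NMDAR_TOTAL}")
        counts = dict(self.counts)
        counts["snr2a"], counts["snr2b"] = int(nr2a), int(nr2b)
        return replace(self, counts=counts)


def control_perturbation() -> PerturbationSet:
    """The condition without amyloid-beta-oligomer disturbances: the
    standard parameter values."""
    return PerturbationSet()


def make_train(frequency_hz: float, count: int | None = None,
               duration_ms: float | None = None, pairing: bool = False,
               post_train_ms: float = 500.0, name: str | None = None) -> StimulusProtocol:
    """Evenly spaced pulse train starting at t=0."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    period = 1000.0 / frequency_hz
    if count is None:
        if duration_ms is None:
            raise ValueError("give either a pulse count or a train duration")
        count = int(round(duration_ms * frequency_hz / 1000.0))
    if count < 1:
        raise ValueError("a train needs at least one pulse")
    times = tuple(i * period for i in range(count))
    total = times[-1] + period + post_train_ms
    windows = ((0.0, times[-1] + period),) if pairing else ()
    return StimulusProtocol(name=name or f"train{frequency_hz:g}Hz",
                            pulse_times=times, duration=total,
                            pairing_windows=windows)


def single_pulse(post_ms: float = 500.0) -> StimulusProtocol:
    return StimulusProtocol(name="1pulse", pulse_times=(0.0,), duration=post_ms)


def make_tbs(trains: int = 4, pairing: bool = True,
             pulses_per_burst: int = 4, intra_burst_hz: float = 100.0,
             bursts_per_train: int = 10, burst_hz: float = 5.0,
             inter_train_ms: float = 2000.0,
             post_train_ms: float = 500.0) -> StimulusProtocol:
    """Theta-burst stimulation: bursts of 100 Hz pulses repeated at 5 Hz,
    grouped into trains."""
    if trains < 1:
        raise ValueError("need at least one train")
    pulse_period = 1000.0 / intra_burst_hz
    burst_period = 1000.0 / burst_hz
    times = []
    t_train = 0.0
    for _ in range(trains):
        for b in range(bursts_per_train):
            t_burst = t_train + b * burst_period
            times.extend(t_burst + i * pulse_period for i in range(pulses_per_burst))
        t_train += (bursts_per_train - 1) * burst_period + inter_train_ms
    times = tuple(times)
    total = times[-1] + pulse_period + post_train_ms
    windows = ((0.0, times[-1] + pulse_period),) if pairing else ()
    return StimulusProtocol(name=f"tbs{trains}", pulse_times=times,
                            duration=total, pairing_windows=windows)


def astro_protocol(duration_ms: float = 20.0, amplitude_uM: float = 1000.0,
                   onset_ms: float = 10.0, total_ms: float = 500.0) -> StimulusProtocol:
    """Astrocytic glutamate release: a square extrasynaptic pulse, no
    presynaptic stimulation."""
    if duration_ms <= 0:
        raise ValueError("pulse duration must be positive")
    return StimulusProtocol(name="astro", duration=total_ms,
                            astro_pulse=(onset_ms, duration_ms, amplitude_uM))


def bap_protocol(total_ms: float = 200.0, bap_at_ms: float = 20.0) -> StimulusProtocol:
    """A single backpropagating action potential, the calibration stimulus."""
    return StimulusProtocol(name="bap", duration=total_ms, bap_times=(bap_at_ms,))


_SWEEPABLE = {
    "G0": lambda p, v: replace(p, molecules_per_release=float(v)),
    "b_total_scale": lambda p, v: replace(p, b_total_scale=float(v)),
    "glu_rest": lambda p, v: replace(p, glu_rest_uM=float(v)),
    "eampar_density": lambda p, v: replace(p, eampar_density_per_um2=float(v)),
}


def _set_count(p: PerturbationSet, name: str, v) -> PerturbationSet:
    counts = dict(p.counts)
    counts[name] = int(v)
    return replace(p, counts=counts)


def _set_desens(p: PerturbationSet, name: str, v) -> PerturbationSet:
    inh = dict(p.desens_inhibition)
    inh[name] = float(v)
    return replace(p, desens_inhibition=inh)


def sweep(parameter: str, values) -> list[PerturbationSet]:
    """One perturbation set per value, all other knobs at control.

    Recognised names: G0, b_total_scale, glu_rest, eampar_density,
    n_<class>, desens_<class> for class in {snr2a, snr2b, pnr2b, enr2b,
    sampar, eampar}, and "ratio" with (nr2a, nr2b) tuples.
    """
    control = control_perturbation()
    if parameter in _SWEEPABLE:
        setter = _SWEEPABLE[parameter]
    elif parameter.startswith("n_") and parameter[2:] in RECEPTOR_CLASSES:
        name = parameter[2:]
        setter = lambda p, v: _set_count(p, name, v)
    elif parameter.startswith("desens_") and parameter[7:] in RECEPTOR_CLASSES:
        name = parameter[7:]
        setter = lambda p, v: _set_desens(p, name, v)
    elif parameter == "ratio":
        setter = lambda p, v: p.with_ratio(*v)
    else:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    return [setter(control, v) for v in values]
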