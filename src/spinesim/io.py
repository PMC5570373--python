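"""Writers, manifests and fixture generation.

Every run can be serialised as a trace bundle: CSV files with documented
column schemas, an HDF5 bundle with the same arrays, a summary JSON and a
run manifest (config hash, seed, protocol and perturbation spec, package
version, per-stage timings).  Identical manifests imply identical outputs
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calcium import SimulationResult
from .config import GlobalConfig
from .inference import FEATURES, CalibrationTarget
from .protocols import PerturbationSet, StimulusProtocol

__all__ = [
    "RunManifest",
    "protocol_to_dict",
    "protocol_from_dict",
    "perturbation_to_dict",
    "perturbation_from_dict",
    "write_bundle",
    "write_target_file",
    "load_target_file",
]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def protocol_to_dict(p: StimulusProtocol) -> dict:
    return _jsonable(dataclasses.asdict(p))


def protocol_from_dict(d: dict) -> StimulusProtocol:
    d = dict(d)
    for key in ("pulse_times", "bap_times"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    d["pairing_windows"] = tuple(tuple(w) for w in d.get("pairing_windows") or ())
    if d.get("astro_pulse") is not None:
        d["astro_pulse"] = tuple(d["astro_pulse"])
    return StimulusProtocol(**d)


def perturbation_to_dict(p: PerturbationSet) -> dict:
    return _jsonable(dataclasses.asdict(p))


def perturbation_from_dict(d: dict) -> PerturbationSet:
    return PerturbationSet(**d)


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    protocol: dict
    perturbation: dict
    version: str = __version__
    timings_s: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def for_run(cls, config: GlobalConfig, protocol: StimulusProtocol,
                perturbation: PerturbationSet, seed: int | None = None,
                timings: dict | None = None) -> "RunManifest":
        digest = hashlib.sha256(config.serialise().encode()).hexdigest()[:16]
        return cls(config_hash=digest, seed=seed,
                   protocol=protocol_to_dict(protocol),
                   perturbation=perturbation_to_dict(perturbation),
                   timings_s=timings or {})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def write_bundle(result: SimulationResult, outdir, config: GlobalConfig,
                 seed: int | None = None, timings: dict | None = None,
                 hdf5: bool = True) -> dict:
    """Write CSV traces, optional HDF5 bundle, summary JSON and manifest.

    Returns the mapping of artefact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    glu_frames = {}
    for zone, tr in result.glutamate.items():
        glu_frames[zone] = pd.DataFrame({"time_ms": tr.times,
                                         f"glu_{zone}_uM": tr.concentration})
    glu = glu_frames["synaptic"]
    for zone in ("perisynaptic", "extrasynaptic"):
        glu = pd.merge_asof(glu, glu_frames[zone], on="time_ms")
    paths["glutamate"] = outdir / "glutamate.csv"
    glu.to_csv(paths["glutamate"], index=False)

    v = result.voltage
    paths["voltage"] = outdir / "voltage.csv"
    pd.DataFrame({"time_ms": v.times, "V_spine_mV": v.v_spine,
                  "V_shaft_mV": v.v_shaft}).to_csv(paths["voltage"], index=False)

    ca = result.calcium
    ca_df = {"time_ms": ca.times}
    for comp, series in ca.free.items():
        ca_df[f"ca_{comp}_uM"] = series
    ca_df["ca_spine_head_uM"] = ca.spine_head
    for cls, series in ca.cumulative_ions.items():
        ca_df[f"ions_{cls}"] = series
    paths["calcium"] = outdir / "calcium.csv"
    pd.DataFrame(ca_df).to_csv(paths["calcium"], index=False)

    for cls, tr in result.trajectories.items():
        df = pd.DataFrame(tr.occupancy, columns=list(tr.scheme.states))
        df.insert(0, "time_ms", tr.times)
        p = outdir / f"receptor_{cls}.csv"
        df.to_csv(p, index=False)
        paths[f"receptor_{cls}"] = p

    paths["summary"] = outdir / "summary.json"
    Path(paths["summary"]).write_text(
        json.dumps(_jsonable(result.summary), indent=2, sort_keys=True) + "\n")

    if hdf5:
        paths["bundle"] = outdir / "bundle.h5"
        with h5py.File(paths["bundle"], "w") as f:
            f.attrs["version"] = __version__
            f.create_dataset("time_ms", data=ca.times)
            f.create_dataset("v_spine_mV", data=v.v_spine)
            f.create_dataset("v_shaft_mV", data=v.v_shaft)
            for comp, series in ca.free.items():
                f.create_dataset(f"ca/{comp}_uM", data=series)
            for cls, series in ca.cumulative_ions.items():
                f.create_dataset(f"ions/{cls}", data=series)

    manifest = RunManifest.for_run(config, result.protocol, result.perturbation,
                                   seed=seed, timings=timings)
    paths["manifest"] = outdir / "manifest.json"
    manifest.write(paths["manifest"])
    return paths


def write_target_file(target: CalibrationTarget, path, seed: int | None = None,
                      true_parameters: dict | None = None) -> None:
    """Write a calibration-target fixture (synthetic stand-in for the
    experimental bAP dataset) as YAML."""
    doc = {"features": {f: float(getattr(target, f)) for f in FEATURES},
           "sigmas": {f"sigma_{f.rsplit('_', 1)[0]}":
                      float(s) for f, s in zip(FEATURES, target.sigmas())},
           "seed": seed}
    if true_parameters:
        doc["true_parameters"] = {k: float(v) for k, v in true_parameters.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_target_file(path) -> CalibrationTarget:
    doc = yaml.safe_load(Path(path).read_text())
    f = doc["features"]
    sig = doc.get("sigmas", {})
    kwargs = {k: f[k] for k in FEATURES}
    kwargs.update(sig)
    return CalibrationTarget(**kwargs)
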