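"""Plain-text readers and writers: model/protocol configs (YAML or JSON),
trace CSVs with JSON sidecars, and simulation-result tables.

All floats are written with repr-level precision so identical computations
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .metrics import Trace
from .model import (
    PRESETS,
    BarrierCoupling,
    BinaryElement,
    ChannelModel,
    Destabilization,
    pair_coupling,
)
from .protocol import Epoch, Protocol, SimulationResult, current_trace
from .stochastic import EnsembleOccupancy

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# model configs
# ---------------------------------------------------------------------------

def model_to_dict(model: ChannelModel) -> dict:
    return {
        "RT": model.RT,
        "elements": [
            {
                "name": e.name,
                "kind": e.kind,
                "k_fwd": e.k_fwd,
                "k_bwd": e.k_bwd,
                **({"ligand": e.ligand} if e.ligand else {}),
                **({"conducts_when_on": True} if e.conducts_when_on else {}),
                **({"blocks_when_on": True} if e.blocks_when_on else {}),
            }
            for e in model.elements
        ],
        "couplings": [
            {
                "source_element": c.source_element,
                "source_config": c.source_config,
                "target_element": c.target_element,
                "direction": c.direction,
                "ddG": c.ddG,
                "derived": c.derived,
                **({"pair": c.pair} if c.pair else {}),
            }
            for c in model.couplings
        ],
        "destabilizations": [
            {
                "condition": [list(pair) for pair in d.condition],
                "dG": d.dG,
                "partition": d.partition,
            }
            for d in model.destabilizations
        ],
    }


def model_from_dict(data: dict) -> ChannelModel:
    elements = tuple(BinaryElement(**e) for e in data["elements"])
    couplings = []
    for c in data.get("couplings", []):
        if "ddG" in c:
            couplings.append(BarrierCoupling(**c))
        else:  # pairwise shorthand: three stated energies, fourth derived
            couplings.extend(pair_coupling(**c))
    destab = tuple(
        Destabilization(
            tuple(tuple(pair) for pair in d["condition"]),
            d["dG"],
            d.get("partition", 1.0),
        )
        for d in data.get("destabilizations", [])
    )
    return ChannelModel(elements, tuple(couplings), destab, data.get("RT", 0.593))


def load_model(source) -> ChannelModel:
    """Load a model from a preset name (e.g. ``"otop3-zn"``) or a YAML/JSON
    config file."""
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]()
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(
            f"model source {source!r} is neither a preset "
            f"({sorted(PRESETS)}) nor an existing file"
        )
    with open(path) as fh:
        data = yaml.safe_load(fh)  # YAML is a superset of JSON
    return model_from_dict(data)


def save_model(model: ChannelModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# protocol configs
# ---------------------------------------------------------------------------

def protocol_from_dict(data: dict) -> Protocol:
    epochs = tuple(
        Epoch(
            duration_s=e["duration_s"],
            pH=e["pH"],
            zn_molar=e.get("zn_mM", 0.0) * 1e-3 if "zn_mM" in e
            else e.get("zn_molar", 0.0),
            driving_mV=e.get("driving_mV"),
        )
        for e in data["epochs"]
    )
    initial = data.get("initial", "equilibrium")
    if not isinstance(initial, str):
        initial = tuple(float(x) for x in initial)
    return Protocol(
        epochs,
        sample_interval_s=data.get("sample_interval_s", 1e-3),
        initial=initial,
        marks=data.get("marks", {}),
    )


def load_protocol(path) -> Protocol:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return protocol_from_dict(data)


def save_protocol(protocol: Protocol, path) -> None:
    data = {
        "epochs": [
            {
                "duration_s": e.duration_s,
                "pH": e.pH,
                "zn_molar": e.zn_molar,
                **(
                    {"driving_mV": e.driving_mV}
                    if e.driving_mV is not None
                    else {}
                ),
            }
            for e in protocol.epochs
        ],
        "sample_interval_s": protocol.sample_interval_s,
        "initial": protocol.initial
        if isinstance(protocol.initial, str)
        else list(protocol.initial),
        "marks": dict(protocol.marks),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# traces (CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.time_s, "current_pA": trace.current_pA}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"sampling_hz": trace.sampling_hz, "annotations": trace.annotations}
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_trace(path) -> Trace:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        current = df["current_pA"].to_numpy(dtype=float)
    except (KeyError, ValueError, OSError) as exc:
        raise DataError(f"cannot read trace {path}: {exc}") from exc
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        sampling = float(meta["sampling_hz"])
        annotations = meta.get("annotations", {})
    else:
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2 or t[1] == t[0]:
            raise DataError(f"cannot infer sampling rate of {path}")
        sampling = 1.0 / (t[1] - t[0])
        annotations = {}
    return Trace(sampling, current, annotations)


# ---------------------------------------------------------------------------
# simulation results
# ---------------------------------------------------------------------------

def result_frame(
    result: SimulationResult,
    conductance_pS: float = 1.0,
    n_channels: int = 1,
) -> pd.DataFrame:
    """Tidy table: time, one column per state probability (named by the
    configuration string), open/conducting probability, and current."""
    df = pd.DataFrame({"time_s": result.time_s})
    for j, label in enumerate(result.space.labels()):
        df[label] = result.probabilities[:, j]
    df["p_open"] = result.p_open
    df["p_conducting"] = result.p_conducting
    df["current_pA"] = current_trace(result, conductance_pS, n_channels)
    return df


def write_result(result: SimulationResult, path, **kwargs) -> None:
    result_frame(result, **kwargs).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def occupancy_frame(occ: EnsembleOccupancy) -> pd.DataFrame:
    """Ensemble-count table mirroring the probability schema."""
    from .stochastic import occupancy_to_current

    df = pd.DataFrame({"time_s": occ.time_s})
    for j, label in enumerate(occ.space.labels()):
        df[label] = occ.counts[:, j]
    df["n_conducting"] = occ.conducting_counts
    df["current_pA"] = occupancy_to_current(occ)
    return df


def write_occupancy(occ: EnsembleOccupancy, path) -> None:
    occupancy_frame(occ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(path, **fields) -> None:
    """Run manifest: seed, parameter echo and versions, for reproducibility."""
    import otopkin

    payload = {"otopkin_version": getattr(otopkin, "__version__", "unknown"),
               "numpy_version": np.__version__}
    payload.update(fields)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
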