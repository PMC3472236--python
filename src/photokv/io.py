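"""File round-tripping: traces, cells, protocols, stimuli, reports.

Formats are deliberately plain:

* traces and simulation results -- tab-separated tables with a unit-bearing
  header row, plus a JSON metadata sidecar (``<file>.meta.json``);
* cell parameters and protocols -- YAML documents in which every physical
  quantity is a ``"<value> <unit>"`` string.  Quantities are written in SI
  base units (V, S, F, s, A) so round-trips are bit-identical, but loaders
  also accept the bench units (mV, nS, pF, ms, pA, ...) -- guarding against
  the millivolt/volt exponent pitfall in the time-constant laws.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .clamp_analysis import FitResult, Trace, TraceSet
from .kinetics import CellParameters, ConductanceSpec, GatingParameters
from .simulator import SimulationResult, StimulusWaveform, VoltageProtocol

__all__ = [
    "parse_quantity",
    "format_quantity",
    "save_cell",
    "load_cell",
    "cell_to_dict",
    "cell_from_dict",
    "load_protocol",
    "save_protocol",
    "write_trace",
    "read_trace",
    "write_traceset",
    "read_traceset",
    "write_simulation_result",
    "load_stimulus",
    "write_stimulus",
    "fit_report_dict",
]

#: Accepted unit suffixes and their SI scale factors.
UNIT_SCALES: dict[str, float] = {
    "V": 1.0, "mV": 1e-3, "uV": 1e-6,
    "S": 1.0, "mS": 1e-3, "uS": 1e-6, "nS": 1e-9, "pS": 1e-12,
    "F": 1.0, "uF": 1e-6, "nF": 1e-9, "pF": 1e-12,
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9, "pA": 1e-12,
    "Hz": 1.0, "kHz": 1e3,
    "ohm": 1.0, "kohm": 1e3, "Mohm": 1e6, "Gohm": 1e9,
    "K": 1.0,
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9,
    "1/V": 1.0, "1/s": 1.0, "": 1.0,
}


def parse_quantity(text: Union[str, float, int]) -> float:
    """Parse ``"<value> <unit>"`` into an SI float (bare numbers pass through)."""
    if isinstance(text, (int, float)):
        return float(text)
    parts = text.strip().split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) != 2:
        raise ValueError(f"cannot parse quantity {text!r}")
    value, unit = parts
    if unit not in UNIT_SCALES:
        raise ValueError(f"unknown unit {unit!r} in {text!r}")
    return float(value) * UNIT_SCALES[unit]


def format_quantity(value: float, unit: str) -> str:
    """Format an SI value with its base-unit suffix (lossless round-trip)."""
    if unit not in UNIT_SCALES or UNIT_SCALES[unit] != 1.0:
        raise ValueError(f"quantities are written in SI base units, not {unit!r}")
    return f"{value!r} {unit}".strip()


# ---------------------------------------------------------------------------
# cells and protocols
# ---------------------------------------------------------------------------

def _gating_to_dict(gp: GatingParameters) -> dict:
    d = {
        "v_half": format_quantity(gp.v_half, "V"),
        "slope": format_quantity(gp.slope, "V"),
        "order": gp.order,
        "tau_alpha": format_quantity(gp.tau_alpha, "1/s"),
        "tau_beta": format_quantity(gp.tau_beta, "1/s"),
        "tau_slope": format_quantity(gp.tau_slope, "1/V"),
        "tau_offset": format_quantity(gp.tau_offset, "s"),
    }
    if gp.tau_constant is not None:
        d["tau_constant"] = format_quantity(gp.tau_constant, "s")
    return d


def _gating_from_dict(d: dict) -> GatingParameters:
    return GatingParameters(
        v_half=parse_quantity(d["v_half"]),
        slope=parse_quantity(d["slope"]),
        order=int(d.get("order", 1)),
        tau_alpha=parse_quantity(d.get("tau_alpha", 0.0)),
        tau_beta=parse_quantity(d.get("tau_beta", 0.0)),
        tau_slope=parse_quantity(d.get("tau_slope", 0.0)),
        tau_offset=parse_quantity(d.get("tau_offset", 0.0)),
        tau_constant=(parse_quantity(d["tau_constant"])
                      if "tau_constant" in d else None),
    )


def cell_to_dict(cell: CellParameters) -> dict:
    """Serializable view of a whole-cell model (SI quantities with units)."""
    return {
        "capacitance": format_quantity(cell.capacitance, "F"),
        "g_leak": format_quantity(cell.g_leak, "S"),
        "e_leak": format_quantity(cell.e_leak, "V"),
        "e_light": format_quantity(cell.e_light, "V"),
        "v_rest": format_quantity(cell.v_rest, "V"),
        "temperature": format_quantity(cell.temperature, "K"),
        "conductances": [
            {
                "name": spec.name,
                "g_max": format_quantity(spec.g_max, "S"),
                "e_rev": format_quantity(spec.e_rev, "V"),
                "activation": _gating_to_dict(spec.activation),
                **({"inactivation": _gating_to_dict(spec.inactivation)}
                   if spec.inactivation is not None else {}),
            }
            for spec in cell.conductances
        ],
    }


def cell_from_dict(d: dict) -> CellParameters:
    conductances = tuple(
        ConductanceSpec(
            name=c["name"],
            g_max=parse_quantity(c["g_max"]),
            e_rev=parse_quantity(c["e_rev"]),
            activation=_gating_from_dict(c["activation"]),
            inactivation=(_gating_from_dict(c["inactivation"])
                          if "inactivation" in c else None),
        )
        for c in d["conductances"]
    )
    return CellParameters(
        capacitance=parse_quantity(d["capacitance"]),
        g_leak=parse_quantity(d["g_leak"]),
        e_leak=parse_quantity(d["e_leak"]),
        e_light=parse_quantity(d["e_light"]),
        conductances=conductances,
        v_rest=parse_quantity(d["v_rest"]),
        temperature=parse_quantity(d.get("temperature", 293.15)),
    )


def save_cell(path: Union[str, Path], cell: CellParameters) -> None:
    Path(path).write_text(yaml.safe_dump(cell_to_dict(cell), sort_keys=False))


def load_cell(path: Union[str, Path]) -> CellParameters:
    return cell_from_dict(yaml.safe_load(Path(path).read_text()))


def save_protocol(path: Union[str, Path], protocol: VoltageProtocol) -> None:
    doc = {
        "holding": format_quantity(protocol.holding, "V"),
        "sample_interval": format_quantity(protocol.sample_interval, "s"),
        "epochs": [[format_quantity(v, "V"), format_quantity(d, "s")]
                   for v, d in protocol.epochs],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_protocol(path: Union[str, Path]) -> VoltageProtocol:
    d = yaml.safe_load(Path(path).read_text())
    return VoltageProtocol(
        epochs=tuple((parse_quantity(v), parse_quantity(dur))
                     for v, dur in d["epochs"]),
        holding=parse_quantity(d["holding"]),
        sample_interval=parse_quantity(d["sample_interval"]),
    )


# ---------------------------------------------------------------------------
# traces and results
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trace(path: Union[str, Path], trace: Trace) -> None:
    """Trace as TSV (time + value column with units) plus a metadata sidecar."""
    path = Path(path)
    unit = "A" if trace.kind == "current" else "V"
    df = pd.DataFrame({"time_s": trace.time, f"value_{unit}": trace.values})
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"kind": trace.kind, "meta": _jsonable(trace.meta)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1))


def read_trace(path: Union[str, Path]) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    kind, meta = "current", {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        kind = sidecar.get("kind", "current")
        meta = sidecar.get("meta", {})
    value_col = [c for c in df.columns if c.startswith("value_")][0]
    return Trace(time=df["time_s"].to_numpy(),
                 values=df[value_col].to_numpy(), kind=kind, meta=meta)


def write_traceset(directory: Union[str, Path], ts: TraceSet,
                   prefix: str = "trace") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, trace in enumerate(ts.traces):
        p = directory / f"{prefix}_{k:03d}.tsv"
        write_trace(p, trace)
        paths.append(p)
    (directory / "traceset.meta.json").write_text(
        json.dumps(_jsonable(ts.meta), indent=1))
    return paths


def read_traceset(directory: Union[str, Path], prefix: str = "trace") -> TraceSet:
    directory = Path(directory)
    traces = [read_trace(p) for p in sorted(directory.glob(f"{prefix}_*.tsv"))]
    meta_path = directory / "traceset.meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TraceSet(traces=traces, meta=meta)


def write_simulation_result(path: Union[str, Path], result: SimulationResult,
                            meta: Optional[dict] = None) -> None:
    """Simulation output as a wide TSV (units in column names) + sidecar."""
    path = Path(path)
    result.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = {"mode": result.mode, "meta": _jsonable(meta or {})}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1))


def write_stimulus(path: Union[str, Path], stim: StimulusWaveform) -> None:
    cols = {"time_s": stim.time, "g_light_S": stim.g_light}
    if stim.i_inj is not None:
        cols["i_inj_A"] = stim.i_inj
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_stimulus(path: Union[str, Path]) -> StimulusWaveform:
    df = pd.read_csv(path, sep="\t")
    return StimulusWaveform(
        time=df["time_s"].to_numpy(),
        g_light=df["g_light_S"].to_numpy(),
        i_inj=df["i_inj_A"].to_numpy() if "i_inj_A" in df.columns else None,
    )


def fit_report_dict(fit: FitResult) -> dict:
    """Structured key-value report of one fit (for YAML/JSON emission)."""
    return {
        "model": fit.model,
        "converged": fit.converged,
        "rss": fit.rss,
        "flags": list(fit.flags),
        "parameters": {
            k: {"value": v, "stderr": fit.stderr.get(k)}
            for k, v in fit.params.items()
        },
    }
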