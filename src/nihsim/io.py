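"""Readers and writers for the on-disk formats.

Clinical units live at the file boundary — mm for geometry, Pa·s/ml and
ml/Pa for lumped elements, m/s or m^3/s for waveforms — and everything
is converted to SI exactly once, at load.  CSV files are comma
separated, UTF-8, with a mandatory header row; numbers are serialized
with 17 significant digits (shortest exact float64 representation) so
a write/read round trip reproduces the in-memory objects exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biochemistry import KineticParameters
from .hemodynamics import FlowWaveform, WindkesselElement, WindkesselNetwork
from .remodeling import RemodelingConfig, RemodelingHistory, summarize
from .vessel_geometry import Station, VesselTree

__all__ = [
    "save_tree", "load_tree",
    "save_waveform", "load_waveform",
    "save_network", "load_network",
    "save_params", "load_params",
    "save_run_config", "load_run", "RunInputs",
    "export_history", "write_vtk_polyline",
]

_FMT = "%.17g"


def _num(x: float) -> float:
    """Round-trip-exact float for deterministic JSON payloads."""
    return float(_FMT % x)


# ---------------------------------------------------------------- tree JSON

def save_tree(tree: VesselTree, path: str | Path) -> None:
    doc = {
        "units": "mm",
        "inlet": tree.inlet,
        "segments": {
            name: {"stations": [
                {"id": st.id, "z_mm": _num(st.z * 1e3),
                 "radius_mm": _num(st.radius * 1e3),
                 "length_mm": _num(st.length * 1e3),
                 "tags": list(st.tags)}
                for st in stations]}
            for name, stations in tree.segments.items()
        },
        "connectivity": {k: list(v) for k, v in tree.connectivity.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_tree(path: str | Path) -> VesselTree:
    doc = json.loads(Path(path).read_text())
    segments: dict[str, list[Station]] = {}
    for name, seg in doc["segments"].items():
        stations = []
        for i, s in enumerate(seg["stations"]):
            if s["radius_mm"] <= 0:
                raise ValueError(f"{path}: segment {name!r} station {i}: radius <= 0")
            stations.append(Station(
                id=s["id"], z=s["z_mm"] * 1e-3, radius=s["radius_mm"] * 1e-3,
                length=s["length_mm"] * 1e-3, tags=tuple(s.get("tags", ()))))
        segments[name] = stations
    return VesselTree(segments=segments,
                      connectivity={k: list(v) for k, v in
                                    doc.get("connectivity", {}).items()},
                      inlet=doc.get("inlet"))


# ------------------------------------------------------------ waveform CSV

def save_waveform(wave: FlowWaveform, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": wave.t, "value": wave.v})
    df.to_csv(path, index=False, float_format=_FMT)


def load_waveform(path: str | Path, period: float, kind: str = "velocity") -> FlowWaveform:
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return FlowWaveform(t=df["time_s"].to_numpy(), v=df["value"].to_numpy(),
                        period=period, kind=kind)


# ------------------------------------------------------------- network JSON

def save_network(network: WindkesselNetwork, path: str | Path) -> None:
    """Write in the clinical units (R in Pa·s/ml, C in ml/Pa, L in Pa·s^2/ml)."""
    doc = {
        outlet: {"R": _num(el.R * 1e-6), "C": _num(el.C * 1e6),
                 "L": _num(el.L * 1e-6)}
        for outlet, el in network.elements.items()
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_network(path: str | Path) -> WindkesselNetwork:
    doc = json.loads(Path(path).read_text())
    elements = {}
    for outlet, el in doc.items():
        if "R" not in el:
            raise ValueError(f"{path}: outlet {outlet!r} is missing R")
        elements[outlet] = WindkesselElement(
            R=el["R"] * 1e6, C=el.get("C", 0.0) * 1e-6, L=el.get("L", 0.0) * 1e6)
    return WindkesselNetwork(elements=elements)


# -------------------------------------------------------------- params YAML

_PARAM_FIELDS = {f.name for f in dataclasses.fields(KineticParameters)}


def save_params(params: KineticParameters, path: str | Path) -> None:
    doc = dataclasses.asdict(params)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_params(path: str | Path) -> KineticParameters:
    """Load kinetic parameters; unspecified fields keep their published
    defaults, but ``phi`` (which has no published value) must be given
    explicitly."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(doc) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown parameter fields {sorted(unknown)}")
    if "phi" not in doc:
        raise ValueError(
            f"{path}: 'phi' (growth-factor production coefficient) must be set "
            "explicitly — it has no published value")
    return KineticParameters(**doc)


# ----------------------------------------------------------------- run YAML

@dataclass
class RunInputs:
    """Fully validated, SI-converted simulation inputs."""

    tree: VesselTree
    inflow: FlowWaveform
    network: WindkesselNetwork
    params: KineticParameters
    config: RemodelingConfig
    base_dir: Path


def save_run_config(config: RemodelingConfig, wave: FlowWaveform,
                    path: str | Path, *, tree: str, waveform: str,
                    network: str, params: str) -> None:
    doc = {
        "inputs": {"tree": tree, "waveform": waveform,
                   "network": network, "params": params},
        "waveform": {"kind": wave.kind, "period_s": wave.period,
                     "smooth_window": 11},
        "remodeling": dataclasses.asdict(config),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_run(path: str | Path) -> RunInputs:
    """Load a run.yaml and every file it references (paths relative to
    the run file); all invariants are checked here, units become SI."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent
    try:
        inputs = doc["inputs"]
        wf = doc["waveform"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing required section: {exc}") from exc
    if wf.get("kind") not in ("velocity", "flow"):
        raise ValueError(f"{path}: waveform.kind must be 'velocity' or 'flow'")
    for key in ("tree", "waveform", "network", "params"):
        if not (base / inputs[key]).exists():
            raise FileNotFoundError(f"{path}: referenced file missing: {inputs[key]}")
    tree = load_tree(base / inputs["tree"])
    inflow = load_waveform(base / inputs["waveform"], period=float(wf["period_s"]),
                           kind=wf["kind"])
    window = int(wf.get("smooth_window", 1))
    if window > 1:
        from .hemodynamics import smooth_waveform
        inflow = smooth_waveform(inflow, window)
    network = load_network(base / inputs["network"])
    network.check_outlets(tree.outlet_ids)
    params = load_params(base / inputs["params"])
    config = RemodelingConfig(**doc.get("remodeling", {}))
    return RunInputs(tree=tree, inflow=inflow, network=network,
                     params=params, config=config, base_dir=base)


# --------------------------------------------------------------- exporters

def export_history(history: RemodelingHistory, out_dir: str | Path,
                   formats: tuple = ()) -> dict[str, Path]:
    """Write per-epoch station CSVs, a machine-readable summary JSON and
    (with ``"vtk"`` in formats) a VTK-legacy polyline per epoch."""
    if not history.epochs:
        raise ValueError("cannot export an empty history")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for k, ep in enumerate(history.epochs):
        rows = []
        for f in ep.fields:
            st = ep.tree.station(f.station_id)
            w = ep.wall[f.station_id]
            rows.append({
                "station_id": f.station_id, "z_m": st.z, "radius_m": st.radius,
                "tags": ",".join(st.tags),
                "tawss_pa": f.tawss, "osi": f.osi, "rrt_per_pa": f.rrt,
                "occlusion_pct": ep.occlusion[f.station_id],
                "dV_i_m3": ep.dV_i[f.station_id],
                **{name: getattr(w, name) for name in
                   ("Q_i", "S_i", "C_i", "G_P", "G_F", "Q_m", "S_m", "C_m")},
            })
        p = out / f"epoch_{k:03d}.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format=_FMT)
        written[f"epoch_{k:03d}"] = p
        if "vtk" in formats:
            pv = out / f"epoch_{k:03d}.vtk"
            write_vtk_polyline(ep.tree, {f.station_id: {"TAWSS": f.tawss, "OSI": f.osi}
                                         for f in ep.fields}, pv)
            written[f"epoch_{k:03d}_vtk"] = pv
    rep = summarize(history)
    last = history.epochs[-1]
    summary = {
        "total_days": history.epochs[-1].day,
        "n_epochs": len(history.epochs) - 1,
        "low_wss_area_cm2": [_num(ep.low_wss_area_cm2) for ep in history.epochs],
        "max_occlusion_pct": _num(max(last.occlusion.values())),
        "occlusion_pct": {sid: _num(v) for sid, v in sorted(last.occlusion.items())},
        "restenosis": [[sid, _num(v)] for sid, v in rep["restenosis"]],
    }
    sp = out / "summary.json"
    sp.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    written["summary"] = sp
    return written


def write_vtk_polyline(tree: VesselTree, point_data: dict[str, dict],
                       path: str | Path) -> None:
    """ASCII VTK-legacy POLYDATA: one polyline per segment, stations as
    points, per-station scalars (radius plus any supplied fields)."""
    stations = list(tree.stations())
    index = {st.id: i for i, st in enumerate(stations)}
    lines = ["# vtk DataFile Version 3.0", "nihsim vessel tree", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(stations)} float"]
    for st in stations:
        lines.append(f"{_FMT % st.z} 0 0")
    seg_lines = [[index[st.id] for st in sts] for sts in tree.segments.values()]
    total = sum(len(s) + 1 for s in seg_lines)
    lines.append(f"LINES {len(seg_lines)} {total}")
    for s in seg_lines:
        lines.append(" ".join(str(x) for x in [len(s), *s]))
    scalar_names = ["radius_m"]
    if point_data:
        first = next(iter(point_data.values()))
        scalar_names += list(first)
    lines.append(f"POINT_DATA {len(stations)}")
    for name in scalar_names:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        for st in stations:
            v = st.radius if name == "radius_m" else point_data[st.id][name]
            lines.append(_FMT % v)
    Path(path).write_text("\n".join(lines) + "\n")
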