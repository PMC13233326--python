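"""Readers/writers: traces (CSV/XYZ), trajectories (HDF5), configs (YAML),
run manifests (JSON)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .dynamics import SimConfig, Trajectory
from .geometry import (FilamentLattice, HelicalGeometry, PotentialParams,
                       build_filament)
from .protocols import ForceProtocol
from .traces import Trace

__all__ = ["read_trace", "write_trace", "save_trajectory", "load_trajectory",
           "load_config", "write_manifest"]

_PRECISION = "%.4f"  # 0.0001 nm, comfortably inside the declared 0.001 nm


class TraceParseError(ValueError):
    pass


def write_trace(trace: Trace, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a trace as CSV (x_nm, y_nm, z_nm) or XYZ."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix.lower() == ".xyz" else "csv")
    pts = trace.points
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    if fmt == "csv":
        np.savetxt(path, pts, delimiter=",", header="x_nm,y_nm,z_nm",
                   comments="", fmt=_PRECISION)
    elif fmt == "xyz":
        lines = [str(len(pts)), f"trace source={trace.source} units=nm"]
        lines += [f"C {x:.4f} {y:.4f} {z:.4f}" for x, y, z in pts]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def read_trace(path: str | Path, fmt: Optional[str] = None) -> Trace:
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix.lower() == ".xyz" else "csv")
    if fmt == "csv":
        rows = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ln == 1 and any(c.isalpha() for c in line):
                continue  # header
            parts = line.split(",")
            try:
                rows.append([float(v) for v in parts[:3]])
            except ValueError as exc:
                raise TraceParseError(f"{path}:{ln}: malformed row {line!r}") from exc
        return Trace(points=np.array(rows), source="file")
    if fmt == "xyz":
        lines = path.read_text().splitlines()
        try:
            n = int(lines[0].strip())
        except (IndexError, ValueError) as exc:
            raise TraceParseError(f"{path}:1: bad XYZ atom count") from exc
        rows = []
        for ln, line in enumerate(lines[2:2 + n], start=3):
            parts = line.split()
            try:
                rows.append([float(v) for v in parts[1:4]])
            except (IndexError, ValueError) as exc:
                raise TraceParseError(f"{path}:{ln}: malformed XYZ row") from exc
        return Trace(points=np.array(rows), source="file")
    raise ValueError(f"unknown trace format {fmt!r}")


# ---------------------------------------------------------------------------
# trajectories

def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Single HDF5 file: frames, times, bond flags, and JSON-encoded
    config/protocol/rupture metadata in attributes."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=traj.frames, compression="gzip")
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("bond_intact", data=traj.bond_intact.astype(np.uint8),
                          compression="gzip")
        h5.create_dataset("final_velocities", data=traj.final_velocities)
        h5.attrs["config"] = json.dumps(asdict(traj.config))
        h5.attrs["protocol"] = json.dumps(traj.protocol.to_dict())
        h5.attrs["rupture_events"] = json.dumps(traj.rupture_events)
        h5.attrs["geometry"] = json.dumps(asdict(traj.lattice.geometry))
        h5.attrs["params"] = json.dumps(asdict(traj.lattice.params))
        h5.attrs["metadata"] = json.dumps(
            {k: v for k, v in traj.metadata.items()}, default=str)


def load_trajectory(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        frames = h5["frames"][...]
        times = h5["times"][...]
        vel = (h5["final_velocities"][...] if "final_velocities" in h5
               else np.zeros_like(frames[-1]))
        intact = h5["bond_intact"][...].astype(bool)
        cfg_d = json.loads(h5.attrs["config"])
        cfg_d["rupture_thresholds"] = (tuple(cfg_d["rupture_thresholds"])
                                       if cfg_d["rupture_thresholds"] else None)
        config = SimConfig(**cfg_d)
        protocol = ForceProtocol.from_dict(json.loads(h5.attrs["protocol"]))
        events = [tuple(e) for e in json.loads(h5.attrs["rupture_events"])]
        geometry = HelicalGeometry(**json.loads(h5.attrs["geometry"]))
        params = PotentialParams(**json.loads(h5.attrs["params"]))
        metadata = json.loads(h5.attrs["metadata"])
    lattice = build_filament(geometry, params)
    return Trajectory(frames=frames, times=times, bond_intact=intact,
                      rupture_events=events, final_velocities=vel,
                      lattice=lattice, config=config,
                      protocol=protocol, metadata=metadata)


# ---------------------------------------------------------------------------
# configuration and manifests

def load_config(path: str | Path) -> dict:
    """Parse a YAML run configuration into model objects.

    Recognized blocks: ``geometry`` (rise_nm/twist_deg/radius_nm/n_subunits),
    ``params`` (k_l/k_theta/k_phi), ``sim`` (SimConfig fields) and
    ``protocol`` (preset name + arguments).
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"geometry", "params", "sim", "protocol"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    out: dict = {"raw": raw}
    geometry = HelicalGeometry(**raw.get("geometry", {}))
    out["geometry"] = geometry
    if "params" in raw:
        out["params"] = PotentialParams(**raw["params"])
    if "sim" in raw:
        sim = dict(raw["sim"])
        if "rupture_thresholds" in sim and sim["rupture_thresholds"]:
            sim["rupture_thresholds"] = tuple(sim["rupture_thresholds"])
        out["sim"] = SimConfig(**sim)
    if "protocol" in raw:
        from . import presets
        spec = dict(raw["protocol"])
        name = spec.pop("preset")
        out["protocol"] = presets.protocol_preset(
            name, n_subunits=geometry.n_subunits,
            n_steps=out["sim"].n_steps if "sim" in out else 0, **spec)
    return out


def write_manifest(out_dir: str | Path, command: str, inputs: dict,
                   outputs: list[str]) -> Path:
    """One JSON manifest per CLI run: config hash, seeds, versions, paths."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(inputs, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "inputs": inputs,
        "outputs": outputs,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
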