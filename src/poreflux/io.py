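"""Readers, writers and run manifests shared by both analysis arms.

Formats: the trajectory TSV dialect (columns frame, time_ns, ion_id,
species, x_nm, y_nm, z_nm) with a JSON metadata sidecar; current-trace CSV
(time_s, current_pA) with a JSON sidecar carrying voltage/rate/filter;
standard MD trajectory ingestion (GRO/PDB topology + XTC/DCD coordinates)
through MDAnalysis.  Readers validate and reject malformed input rather
than silently coercing it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .pore_sim import IonTrajectory, SPECIES_K, SPECIES_CL
from .trace_sim import CurrentTrace

SCHEMA_VERSION = "1"

#: MD-style residue/atom names mapped onto the two ion species
DEFAULT_ION_NAME_MAP = {
    "K+": SPECIES_K, "K": SPECIES_K, "POT": SPECIES_K,
    "Cl-": SPECIES_CL, "CL-": SPECIES_CL, "CL": SPECIES_CL, "CLA": SPECIES_CL,
}

_TRAJ_COLUMNS = ["frame", "time_ns", "ion_id", "species", "x_nm", "y_nm", "z_nm"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record attached to every pipeline output."""

    tool: str
    version: str
    config: dict
    seeds: list[int]
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["config_hash"] = config_hash(self.config)
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")


def write_trajectory(traj: IonTrajectory, prefix: str | Path) -> tuple[Path, Path]:
    """Write a trajectory as ``<prefix>.tsv`` plus ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    f, n = traj.n_frames, traj.n_ions
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(f), n),
            "time_ns": np.repeat(traj.times_ns, n),
            "ion_id": np.tile(traj.ion_ids, f),
            "species": np.tile(traj.species, f),
            "x_nm": traj.positions[:, :, 0].ravel(),
            "y_nm": traj.positions[:, :, 1].ravel(),
            "z_nm": traj.positions[:, :, 2].ravel(),
        }
    )
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6f")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "box": list(traj.box),
        "metadata": traj.metadata,
        "config_hash": config_hash(traj.metadata.get("config", {})),
    }
    meta_path = prefix.parent / (prefix.name + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return tsv, meta_path


def read_trajectory_table(
    path: str | Path,
    box: tuple[float, float, float] | None = None,
    species_map: dict | None = None,
) -> IonTrajectory:
    """Read the trajectory TSV dialect back into a validated IonTrajectory.

    The box is taken from the ``<path>.meta.json`` sidecar when present,
    else it must be supplied.  Species codes are translated through
    ``species_map`` (MD-style names like K/CL/POT/CLA are understood by
    default); unknown codes, missing columns, non-monotone or gapped frames
    and ions missing from frames are rejected with the offending row/frame.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    smap = dict(DEFAULT_ION_NAME_MAP)
    if species_map:
        smap.update(species_map)
    species_raw = df["species"].astype(str)
    unknown = ~species_raw.isin(smap.keys())
    if unknown.any():
        row = int(np.nonzero(unknown.to_numpy())[0][0])
        raise ValueError(
            f"{path}: unknown species code {species_raw.iloc[row]!r} at row {row + 2}"
        )
    df = df.assign(species=species_raw.map(smap))

    frames = np.sort(df["frame"].unique())
    if np.any(np.diff(frames) != 1):
        gap = int(frames[np.nonzero(np.diff(frames) != 1)[0][0]] + 1)
        raise ValueError(f"{path}: gap in frame numbering at frame {gap}")
    ions = np.sort(df["ion_id"].unique())
    counts = df.groupby("frame")["ion_id"].nunique()
    bad = counts[counts != ions.size]
    if not bad.empty:
        raise ValueError(
            f"{path}: frame {int(bad.index[0])} is missing ions "
            f"({int(bad.iloc[0])}/{ions.size} present)"
        )

    meta_path = path.parent / (path.stem + ".meta.json")
    metadata: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        metadata = meta.get("metadata", {})
        if box is None and "box" in meta:
            box = tuple(meta["box"])
    if box is None:
        raise ValueError(f"{path}: no box given and no metadata sidecar found")

    df = df.sort_values(["frame", "ion_id"], kind="stable")
    f, n = frames.size, ions.size
    times = df.drop_duplicates("frame")["time_ns"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        k = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise ValueError(f"{path}: frame times not strictly increasing at frame {k + 1}")
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float).reshape(f, n, 3)
    species = df["species"].to_numpy()[:n]
    return IonTrajectory(
        times_ns=times,
        ion_ids=ions,
        species=species,
        positions=pos,
        box=box,
        metadata=metadata,
    )


def read_md_trajectory(
    topology: str | Path,
    coordinates: str | Path | None = None,
    name_map: dict | None = None,
) -> IonTrajectory:
    """Extract K+/Cl- ion records from standard MD files via MDAnalysis.

    Selects atoms whose atom or residue name appears in the name map,
    converts Å to nm, reads the box per frame (not assumed constant), and
    returns the same in-memory trajectory the TSV path produces.
    """
    import MDAnalysis as mda

    smap = {k.upper(): v for k, v in (name_map or DEFAULT_ION_NAME_MAP).items()}
    u = (
        mda.Universe(str(topology), str(coordinates))
        if coordinates is not None
        else mda.Universe(str(topology))
    )
    sel = [
        atom
        for atom in u.atoms
        if atom.name.upper() in smap or atom.resname.upper() in smap
    ]
    if not sel:
        raise ValueError("no ions matching the name map found in the topology")
    ag = u.atoms[[a.index for a in sel]]
    species = np.array(
        [
            smap.get(a.name.upper(), smap.get(a.resname.upper()))
            for a in ag
        ]
    )
    times, frames, boxes = [], [], []
    for ts in u.trajectory:
        times.append(float(ts.time) / 1000.0)  # ps -> ns
        frames.append(ag.positions / 10.0)     # Å -> nm
        boxes.append(np.array(ts.dimensions[:3]) / 10.0)
    times = np.asarray(times)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(times.size, dtype=float)  # dump files without times
    box = tuple(float(v) for v in np.max(boxes, axis=0))
    pos = np.asarray(frames)
    pos = pos % np.asarray(box)  # wrap into [0, box)
    return IonTrajectory(
        times_ns=times,
        ion_ids=ag.indices,
        species=species,
        positions=pos,
        box=box,
        metadata={"source": str(topology), "per_frame_box": [b.tolist() for b in boxes]},
    )


def write_trace_csv(
    trace: CurrentTrace, path: str | Path
) -> tuple[Path, Path]:
    """Write a trace as CSV (time_s, current_pA) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.times_s, "current_pA": trace.samples_pA}
    )
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "voltage_mV": trace.protocol.get("voltage_mV"),
        "rate_Hz": trace.sampling_hz,
        "filter_Hz": trace.protocol.get("filter_hz"),
        "protocol": trace.protocol,
    }
    meta_path = path.parent / (path.stem + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return path, meta_path


def read_trace_csv(
    path: str | Path, meta_path: str | Path | None = None
) -> CurrentTrace:
    """Read a trace CSV (+ sidecar) back into a CurrentTrace."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trace needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or (np.max(dt) - np.min(dt)) > 1e-6 * np.mean(dt) + 1e-12:
        raise ValueError(f"{path}: sampling is not uniform")
    if meta_path is None:
        candidate = path.parent / (path.stem + ".meta.json")
        meta_path = candidate if candidate.exists() else None
    protocol: dict = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        protocol = meta.get("protocol", {}) or {}
        if "voltage_mV" not in protocol and meta.get("voltage_mV") is not None:
            protocol["voltage_mV"] = meta["voltage_mV"]
    return CurrentTrace(
        samples_pA=df["current_pA"].to_numpy(dtype=float),
        sampling_hz=1.0 / float(np.mean(dt)),
        protocol=protocol,
    )


def write_events_tsv(events, voltage_mV: float, path: str | Path) -> Path:
    """Idealized event table: start_s, end_s, duration_s, class, mean_open_pA,
    conductance_nS, n_levels."""
    path = Path(path)
    rows = [
        {
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_s": ev.duration_s,
            "class": ev.label,
            "mean_open_pA": ev.mean_open_pA,
            "conductance_nS": ev.conductance_nS,
            "n_levels": ev.n_levels,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "start_s", "end_s", "duration_s", "class",
            "mean_open_pA", "conductance_nS", "n_levels",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
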