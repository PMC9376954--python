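"""Coordinate, trajectory and curve file formats.

GRO is the primary coordinate dialect (fixed-width, positions in nm to
0.001 nm, optional velocities in nm/ps); XYZ is the dependency-free
alternative with the box edge and time carried on the comment line.  Bead
kinds are encoded in the atom-name column (B, S, TN, TC).  Multi-frame
files are concatenated blocks.  Kinetic curves go to CSV with documented
column headers.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import KineticCurves
from .system import Frame, Trajectory
from .topology import Topology

#: CSV schema for kinetic curves, version 1.
CURVE_COLUMNS = ("time_ns", "n1_mean", "n1_sem", "n2_mean", "n2_sem",
                 "n3_mean", "n3_sem", "nc_mean", "nc_sem")


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _gro_frame_lines(frame: Frame, topology: Topology) -> list[str]:
    lines = [f"twobead frame t= {frame.time:.6f} ns"]
    lines.append(f"{frame.n_beads:5d}")
    vel = frame.velocities
    for b in topology.beads:
        x, y, z = frame.positions[b.index]
        resnr = (b.chain % 99999) + 1
        atomnr = (b.index % 99999) + 1
        line = (f"{resnr:5d}{'PEP':<5s}{b.kind.value:>5s}{atomnr:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}")
        if vel is not None:
            vx, vy, vz = vel[b.index]
            line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
        lines.append(line)
    L = frame.box
    lines.append(f"{L:10.5f}{L:10.5f}{L:10.5f}")
    return lines


def write_gro(path, frames: Frame | Trajectory | list[Frame],
              topology: Topology) -> None:
    """Write one frame or a trajectory as (multi-frame) GRO."""
    if isinstance(frames, Frame):
        frames = [frames]
    lines: list[str] = []
    for f in frames:
        lines.extend(_gro_frame_lines(f, topology))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path) -> Trajectory:
    """Read a (multi-frame) GRO file written in this dialect.

    Bead kinds are taken from the atom-name column; malformed records raise
    with the offending line number.
    """
    text = Path(path).read_text().splitlines()
    traj = Trajectory()
    ln = 0
    while ln < len(text):
        title = text[ln]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            n = int(text[ln + 1])
        except (ValueError, IndexError) as e:
            raise ValueError(f"line {ln + 2}: expected atom count") from e
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        has_vel = True
        for a in range(n):
            raw = text[ln + 2 + a]
            try:
                pos[a] = [float(raw[20:28]), float(raw[28:36]), float(raw[36:44])]
            except (ValueError, IndexError) as e:
                raise ValueError(f"line {ln + 3 + a}: malformed coordinate record") from e
            if len(raw.rstrip()) >= 68:
                vel[a] = [float(raw[44:52]), float(raw[52:60]), float(raw[60:68])]
            else:
                has_vel = False
        box_line = text[ln + 2 + n].split()
        try:
            L = float(box_line[0])
        except (ValueError, IndexError) as e:
            raise ValueError(f"line {ln + 3 + n}: malformed box record") from e
        traj.frames.append(Frame(pos, box=L, time=time,
                                 velocities=vel if has_vel else None))
        ln += n + 3
    return traj


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, frames: Frame | Trajectory | list[Frame],
              topology: Topology) -> None:
    """XYZ with 'box=<L> time=<t>' on the comment line; positions in nm."""
    if isinstance(frames, Frame):
        frames = [frames]
    out: list[str] = []
    for f in frames:
        out.append(str(f.n_beads))
        out.append(f"box={f.box:.6f} time={f.time:.6f}")
        for b in topology.beads:
            x, y, z = f.positions[b.index]
            out.append(f"{b.kind.value:4s} {x:12.6f} {y:12.6f} {z:12.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_xyz(path) -> Trajectory:
    """Read (multi-frame) XYZ; the comment line must carry box=<L>."""
    text = Path(path).read_text().splitlines()
    traj = Trajectory()
    ln = 0
    while ln < len(text):
        if not text[ln].strip():
            ln += 1
            continue
        try:
            n = int(text[ln])
        except ValueError as e:
            raise ValueError(f"line {ln + 1}: expected atom count") from e
        comment = text[ln + 1]
        fields = dict(tok.split("=", 1) for tok in comment.split() if "=" in tok)
        if "box" not in fields:
            raise ValueError(
                f"line {ln + 2}: XYZ comment must carry 'box=<edge nm>' "
                "(cubic-box convention)")
        L = float(fields["box"])
        time = float(fields.get("time", 0.0))
        pos = np.empty((n, 3))
        for a in range(n):
            parts = text[ln + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(f"line {ln + 3 + a}: malformed XYZ record")
            pos[a] = [float(p) for p in parts[1:4]]
        traj.frames.append(Frame(pos, box=L, time=time))
        ln += n + 2
    return traj


def read_coordinates(path, dialect: str | None = None) -> Trajectory:
    """Read GRO or XYZ, inferring the dialect from the suffix if not given."""
    dialect = dialect or Path(path).suffix.lstrip(".").lower()
    if dialect == "gro":
        return read_gro(path)
    if dialect == "xyz":
        return read_xyz(path)
    raise ValueError(f"unknown coordinate dialect {dialect!r} (use 'gro' or 'xyz')")


def write_coordinates(path, frames, topology: Topology,
                      dialect: str | None = None) -> None:
    dialect = dialect or Path(path).suffix.lstrip(".").lower()
    if dialect == "gro":
        write_gro(path, frames, topology)
    elif dialect == "xyz":
        write_xyz(path, frames, topology)
    else:
        raise ValueError(f"unknown coordinate dialect {dialect!r} (use 'gro' or 'xyz')")


# ---------------------------------------------------------------------------
# kinetic curves CSV
# ---------------------------------------------------------------------------

def write_curves_csv(path, curves: KineticCurves) -> None:
    """CSV schema v1: time_ns, then <name>_mean and <name>_sem per curve."""
    df = pd.DataFrame({"time_ns": curves.time_ns})
    for name in KineticCurves.NAMES:
        df[f"{name}_mean"] = curves.mean[name]
        df[f"{name}_sem"] = curves.sem[name]
    with open(path, "w") as fh:
        fh.write(f"# twobead kinetic curves v1; n_repeats={curves.n_repeats}\n")
        df.to_csv(fh, index=False)


def read_curves_csv(path) -> KineticCurves:
    n_repeats = 1
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "n_repeats=" in first:
                n_repeats = int(first.split("n_repeats=")[1].split()[0])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curves CSV missing columns: {missing}")
    mean = {name: df[f"{name}_mean"].to_numpy() for name in KineticCurves.NAMES}
    sem = {name: df[f"{name}_sem"].to_numpy() for name in KineticCurves.NAMES}
    return KineticCurves(time_ns=df["time_ns"].to_numpy(), mean=mean, sem=sem,
                         n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# run metadata sidecar
# ---------------------------------------------------------------------------

def write_run_metadata(path, **payload) -> None:
    """JSON sidecar with settings, seeds and the package version."""
    from . import __version__

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items() if not k.startswith("_")}
        return str(o)

    payload = {"twobead_version": __version__, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
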