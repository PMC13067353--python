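"""File formats and run configuration.

Plain-text formats throughout: minimal fixed-width PDB (read/write) and
XYZ-like whitespace tables for coordinate frames, COLVAR-style and
HILLS-style files ('#'-prefixed header naming the fields, whitespace
columns, time first) for biased time series and metadynamics hills, a
whitespace grid file for free-energy surfaces, and a YAML/JSON run
configuration whose defaults reproduce the published protocol constants
(310 K, 25 nodes, hills of 0.6 kcal/mol with sigma 0.02, bias factor 35,
pace 1000, 8 walkers sharing every 100 steps, 2500 and 10-30 kcal/mol
force constants, 8/4 and 6/3 block averaging).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protonpath.colvars import HydrationFrame
from protonpath.free_energy import (
    BiasedTimeSeries,
    FreeEnergyGrid,
    GridAxis,
    HillsLog,
    RestraintSpec,
)
from protonpath.path_geometry import PathNodes

__all__ = [
    "RunConfig",
    "read_frames",
    "write_frames",
    "read_point_cloud",
    "write_path_nodes",
    "read_path_nodes",
    "write_path_nodes_pdb",
    "write_colvar",
    "read_colvar",
    "write_hills",
    "read_hills",
    "write_grid",
    "read_grid",
]

_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"}
_WATER_ATOMS = {"OW", "O", "OH2"}
_PROBE_NAMES = {"PRB", "CEC", "H3O"}


# ---------------------------------------------------------------------------
# coordinate frames

def _parse_pdb_atom(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        resname = line[17:21].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as e:
        raise ValueError(f"malformed PDB record at line {lineno}: {line.rstrip()!r}") from e
    return name, resname, (x, y, z)


def read_frames(path, format: str | None = None) -> list[HydrationFrame]:
    """Read hydration frames (water oxygens + excess-charge probe).

    ``format`` is "pdb" (fixed-width ATOM/HETATM records, frames split on
    MODEL/ENDMDL, waters identified by residue name, probe by atom or
    residue name PRB/CEC/H3O) or "xyz" (repeated blocks of: atom count,
    comment, then one "LABEL x y z" line per atom, label O/OW for water and
    PRB for the probe).  Inferred from the suffix when omitted.
    """
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz")
    text = path.read_text()
    if fmt == "pdb":
        return _frames_from_pdb(text)
    if fmt == "xyz":
        return _frames_from_xyz(text)
    raise ValueError(f"unknown frame format {fmt!r}")


def _frames_from_pdb(text: str) -> list[HydrationFrame]:
    frames, waters, probe = [], [], None

    def flush(lineno):
        nonlocal waters, probe
        if not waters and probe is None:
            return
        if probe is None:
            raise ValueError(f"frame ending at line {lineno} has no probe atom")
        if not waters:
            raise ValueError(f"frame ending at line {lineno} has no water oxygens")
        frames.append(HydrationFrame(np.asarray(waters), np.asarray(probe)))
        waters, probe = [], None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            name, resname, xyz = _parse_pdb_atom(line, lineno)
            if name in _PROBE_NAMES or resname in _PROBE_NAMES:
                probe = xyz
            elif resname in _WATER_RESNAMES and name in _WATER_ATOMS:
                waters.append(xyz)
        elif rec in ("ENDMDL", "END"):
            flush(lineno)
    flush(lineno if text else 0)
    if not frames:
        raise ValueError("no frames found in PDB input")
    return frames


def _frames_from_xyz(text: str) -> list[HydrationFrame]:
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as e:
            raise ValueError(f"malformed atom count at line {i + 1}") from e
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"truncated frame starting at line {i + 1}")
        waters, probe = [], None
        for k, raw in enumerate(block):
            parts = raw.split()
            if len(parts) < 4:
                raise ValueError(f"malformed record at line {i + 3 + k}")
            label = parts[0].upper()
            try:
                xyz = tuple(float(v) for v in parts[1:4])
            except ValueError as e:
                raise ValueError(f"malformed record at line {i + 3 + k}") from e
            if label in _PROBE_NAMES:
                probe = xyz
            elif label in _WATER_ATOMS:
                waters.append(xyz)
        if probe is None:
            raise ValueError(f"frame starting at line {i + 1} has no probe atom")
        frames.append(HydrationFrame(np.asarray(waters), np.asarray(probe)))
        i += 2 + n
    if not frames:
        raise ValueError("no frames found in XYZ input")
    return frames


def write_frames(path, frames, format: str | None = None) -> None:
    """Write hydration frames in the minimal PDB or XYZ-like dialect."""
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz")
    buf = _io.StringIO()
    if fmt == "pdb":
        def atom_line(serial, name, res, xyz):
            # fixed-width PDB columns: name 13-16, resName 18-21, x/y/z 31-54
            return (
                f"HETATM{serial:>5} {name:<4} {res:<4} {serial % 10000:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n"
            )

        for m, fr in enumerate(frames, start=1):
            buf.write(f"MODEL {m:>8}\n")
            serial = 1
            for w in fr.water_oxygens:
                buf.write(atom_line(serial, "OW", "HOH", w))
                serial += 1
            buf.write(atom_line(serial, "PRB", "PRB", fr.probe))
            buf.write("ENDMDL\n")
    elif fmt == "xyz":
        for fr in frames:
            buf.write(f"{len(fr.water_oxygens) + 1}\n")
            buf.write("hydration frame\n")
            for w in fr.water_oxygens:
                buf.write(f"OW {w[0]:.6f} {w[1]:.6f} {w[2]:.6f}\n")
            p = fr.probe
            buf.write(f"PRB {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    else:
        raise ValueError(f"unknown frame format {fmt!r}")
    path.write_text(buf.getvalue())


def read_point_cloud(path, format: str | None = None) -> np.ndarray:
    """Water-oxygen positions pooled over all frames (for path fitting).

    Accepts the PDB/XYZ frame formats or a bare whitespace table of
    x y z rows (lines starting with '#' ignored).
    """
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else \
              ("xyz" if path.suffix.lower() == ".xyz" else "table")
    if fmt in ("pdb", "xyz"):
        frames = read_frames(path, fmt)
        return np.concatenate([f.water_oxygens for f in frames])
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 3:
        raise ValueError("point table needs at least 3 columns (x y z)")
    return arr[:, :3]


# ---------------------------------------------------------------------------
# path nodes

def write_path_nodes(path, nodes: PathNodes) -> None:
    with open(path, "w") as fh:
        fh.write("# FIELDS index x y z\n")
        fh.write(f"# SET spacing {float(nodes.spacing)!r}\n")
        fh.write(f"# SET origin_index {nodes.origin_index}\n")
        fh.write(f"# SET orientation {nodes.orientation}\n")
        for i, (x, y, z) in enumerate(nodes.nodes):
            fh.write(f"{i} {x:.10g} {y:.10g} {z:.10g}\n")


def read_path_nodes(path) -> PathNodes:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# SET"):
            _, _, key, val = line.split(maxsplit=3)
            meta[key] = val
        elif line.startswith("#") or not line.strip():
            continue
        else:
            rows.append([float(v) for v in line.split()[1:4]])
    return PathNodes(
        np.asarray(rows),
        spacing=float(meta["spacing"]) if "spacing" in meta else None,
        origin_index=int(meta.get("origin_index", 0)),
        orientation=int(meta.get("orientation", 1)),
    )


def write_path_nodes_pdb(path, nodes: PathNodes) -> None:
    """Path nodes as PDB pseudo-atoms for visualization."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(nodes.nodes, start=1):
            fh.write(
                f"HETATM{i:>5} {'ND':<4}{'PTH':<4} {i:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# COLVAR / HILLS

def write_colvar(path, series: BiasedTimeSeries) -> None:
    cols = list(series.data.columns)
    with open(path, "w") as fh:
        fh.write("# FIELDS " + " ".join(cols) + "\n")
        for r in series.restraints:
            fh.write(f"# SET restraint {r.cv} {float(r.center)!r} "
                     f"{float(r.kappa)!r}\n")
        series.data.to_csv(fh, sep=" ", header=False, index=False,
                           float_format="%.10g")


def read_colvar(path) -> BiasedTimeSeries:
    fields, restraints, skip = None, [], 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                parts = line[1:].split()
                if parts[:1] == ["FIELDS"]:
                    fields = parts[1:]
                elif parts[:2] == ["SET", "restraint"]:
                    restraints.append(
                        RestraintSpec(parts[2], float(parts[3]), float(parts[4]))
                    )
            else:
                break
    if fields is None:
        raise ValueError(f"{path}: missing '# FIELDS' header")
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=fields)
    return BiasedTimeSeries(df, restraints=tuple(restraints))


def write_hills(path, hills: HillsLog) -> None:
    names = hills.cv_names
    cols = (["time"] + [f"center_{n}" for n in names]
            + [f"sigma_{n}" for n in names] + ["height", "walker"])
    with open(path, "w") as fh:
        fh.write("# FIELDS " + " ".join(cols) + "\n")
        fh.write("# SET cvs " + " ".join(names) + "\n")
        fh.write(f"# SET biasfactor {float(hills.bias_factor)!r}\n")
        for k in range(hills.n_hills):
            row = [hills.times[k], *hills.centers[k], *hills.sigmas[k],
                   hills.heights[k]]
            fh.write(" ".join(f"{v:.10g}" for v in row)
                     + f" {int(hills.walkers[k])}\n")


def read_hills(path) -> HillsLog:
    meta, skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts[:2] == ["SET", "cvs"]:
                meta["cvs"] = tuple(parts[2:])
            elif parts[:2] == ["SET", "biasfactor"]:
                meta["gamma"] = float(parts[2])
    if "cvs" not in meta or "gamma" not in meta:
        raise ValueError(f"{path}: missing cvs/biasfactor metadata")
    arr = np.loadtxt(path, comments="#", ndmin=2)
    d = len(meta["cvs"])
    if arr.size == 0:
        raise ValueError(f"{path}: empty hills log")
    return HillsLog(
        cv_names=meta["cvs"],
        times=arr[:, 0],
        centers=arr[:, 1:1 + d],
        sigmas=arr[:, 1 + d:1 + 2 * d],
        heights=arr[:, 1 + 2 * d],
        bias_factor=meta["gamma"],
        walkers=arr[:, 2 + 2 * d].astype(int),
    )


# ---------------------------------------------------------------------------
# free-energy grids

def write_grid(path, grid: FreeEnergyGrid) -> None:
    axes = grid.axes
    with open(path, "w") as fh:
        for ax in axes:
            fh.write(f"# AXIS {ax.cv} {float(ax.lo)!r} {float(ax.hi)!r} "
                     f"{ax.n_bins}\n")
        names = " ".join(ax.cv for ax in axes)
        fh.write(f"# FIELDS {names} free_energy se mask\n")
        mesh = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
        coords = [m.ravel() for m in mesh]
        F = grid.free_energy.ravel()
        se = (grid.se.ravel() if grid.se is not None
              else np.zeros_like(F))
        m = grid.mask.ravel()
        for k in range(F.size):
            vals = [c[k] for c in coords] + [F[k], se[k]]
            fh.write(" ".join("nan" if np.isnan(v) else f"{v:.10g}" for v in vals)
                     + f" {int(m[k])}\n")


def read_grid(path) -> FreeEnergyGrid:
    axes = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts[:1] == ["AXIS"]:
                axes.append(GridAxis(parts[1], float(parts[2]),
                                     float(parts[3]), int(parts[4])))
    if not axes:
        raise ValueError(f"{path}: missing '# AXIS' header")
    arr = np.loadtxt(path, comments="#", ndmin=2)
    d = len(axes)
    shape = tuple(ax.n_bins for ax in axes)
    F = arr[:, d].reshape(shape)
    se = arr[:, d + 1].reshape(shape)
    mask = arr[:, d + 2].astype(bool).reshape(shape)
    return FreeEnergyGrid(tuple(axes), F, mask, se)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved run parameters.  The defaults are the published protocol:
    310 K, 25 path nodes, metadynamics hills of 0.6 kcal/mol with width
    0.02 at pace 1000, bias factor 35, 8 walkers sharing every 100 steps,
    harmonic force constants 2500 (hydration CV) and 10-30 (path CV)
    kcal/mol, 130 windows for the 2D protocol and 24 for the 1D protocol,
    block averaging 8/4 (2D) and 6/3 (1D)."""

    temperature: float = 310.0
    n_nodes: int = 25
    switch_r0: float = 2.5
    switch_exponents: tuple[int, int] = (6, 12)
    locality_sigma: float = 3.0
    metad_height: float = 0.6
    metad_sigma: float = 0.02
    metad_bias_factor: float = 35.0
    metad_pace: int = 1000
    metad_walkers: int = 8
    metad_share_interval: int = 100
    kappa_phi: float = 2500.0
    kappa_xi_range: tuple[float, float] = (10.0, 30.0)
    n_windows_2d: int = 130
    n_windows_1d: int = 24
    blocks_2d: tuple[int, int] = (8, 4)   # (n_blocks, keep_last)
    blocks_1d: tuple[int, int] = (6, 3)
    wham_tol: float = 1e-7
    wham_max_iter: int = 100000
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("switch_exponents", "kappa_xi_range", "blocks_2d", "blocks_1d"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)
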