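"""Structure and trajectory readers/writers.

GRO and the concatenated multi-frame GRO format (``multi_gro``, the
dependency-free fixture format) are handled natively with fixed-column
parsing; PDB files and XTC/DCD trajectories go through MDAnalysis.
All coordinates are converted to nanometres at this boundary (PDB is
Angstrom on disk, GRO already nm).

Only orthorhombic boxes are supported; triclinic input raises
:class:`~gpianchor.system.UnsupportedBoxError`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .system import (Atom, Frame, Topology, TopologyError, Trajectory,
                     UnsupportedBoxError, _guess_element, resolve_role)


class ParseError(ValueError):
    """Malformed file content; message names the file and line."""


# ---------------------------------------------------------------- GRO native

def _parse_gro_frame(lines: list[str], path: str, start_line: int):
    """Parse one GRO frame (title, natoms, atom lines, box line)."""
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GRO frame at line {start_line}")
    title = lines[0].rstrip("\n")
    try:
        natoms = int(lines[1])
    except ValueError:
        raise ParseError(
            f"{path}:{start_line + 1}: expected atom count, got "
            f"{lines[1].strip()!r}") from None
    if len(lines) < natoms + 3:
        raise ParseError(f"{path}: truncated GRO frame at line {start_line}")
    records = []
    coords = np.empty((natoms, 3))
    for k in range(natoms):
        ln = lines[2 + k]
        lineno = start_line + 2 + k
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            coords[k] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: malformed GRO atom record "
                             f"{ln.rstrip()!r}") from None
        records.append((name, resname, resid))
    box_fields = lines[natoms + 2].split()
    if len(box_fields) not in (3, 9):
        raise ParseError(
            f"{path}:{start_line + natoms + 2}: malformed box line")
    vals = [float(x) for x in box_fields]
    if len(vals) == 9 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise UnsupportedBoxError(
            f"{path}: triclinic box not supported (off-diagonal elements)")
    box = np.array(vals[:3])
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.split("t=")[-1].split()[0])
        except (ValueError, IndexError):
            pass
    return title, records, coords, box, time


def read_gro(path, role_table: Mapping[str, str] | None = None):
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise ParseError(f"{path}: empty GRO file")
    _, records, coords, box, time = _parse_gro_frame(lines, path, 1)
    topology = Topology.from_records(records, role_table=role_table)
    return topology, Frame(coords, box, time=time)


def write_gro(topology: Topology, frame: Frame, path, title: str = "gpianchor") -> None:
    frame.check(topology)
    with open(path, "w") as fh:
        _write_gro_frame(fh, topology, frame, title)


def _write_gro_frame(fh, topology: Topology, frame: Frame, title: str) -> None:
    fh.write(f"{title} t= {frame.time:.4f}\n")
    fh.write(f"{topology.n_atoms:5d}\n")
    for a, (x, y, z) in zip(topology.atoms, frame.coordinates):
        # GRO columns are 5 wide; ids wrap at 100000 as in GROMACS
        fh.write(f"{a.residue_id % 100000:5d}{a.residue_name:<5.5s}"
                 f"{a.name:>5.5s}{(a.index + 1) % 100000:5d}"
                 f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def read_multi_gro(path, topology: Topology | None = None,
                   role_table: Mapping[str, str] | None = None,
                   stride: int = 1, start: int = 0, stop: int | None = None):
    """Read a concatenated multi-frame GRO file as a Trajectory.

    If ``topology`` is given, every frame's atom count is checked against
    it; otherwise the topology is built from the first frame.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()
    frames = []
    top = topology
    i = 0
    iframe = 0
    while i < len(lines):
        if not lines[i].strip() and i + 1 >= len(lines):
            break
        _, records, coords, box, time = _parse_gro_frame(lines[i:], path, i + 1)
        natoms = len(records)
        if top is None:
            top = Topology.from_records(records, role_table=role_table)
        elif natoms != top.n_atoms:
            raise TopologyError(
                f"{path}: frame {iframe} has {natoms} atoms, expected "
                f"{top.n_atoms}")
        if iframe >= start and (stop is None or iframe < stop) \
                and (iframe - start) % stride == 0:
            frames.append(Frame(coords, box, time=time))
        iframe += 1
        i += natoms + 3
    if not frames:
        raise ParseError(f"{path}: no frames found in trajectory file")
    return Trajectory(top, frames)


def write_multi_gro(traj: Trajectory, path, title: str = "gpianchor") -> None:
    with open(path, "w") as fh:
        for frame in traj:
            _write_gro_frame(fh, traj.topology, frame, title)


# ------------------------------------------------------------ PDB via MDAnalysis

def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _check_orthorhombic(dimensions, path):
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        raise ParseError(f"{path}: no box information; supply a box explicitly")
    angles = np.asarray(dimensions)[3:6]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"{path}: triclinic box (angles {angles}) not supported")
    return np.asarray(dimensions)[:3] / 10.0  # A -> nm


def read_pdb(path, role_table: Mapping[str, str] | None = None,
             box: Sequence[float] | None = None):
    path = str(path)
    mda = _mda()
    try:
        u = mda.Universe(path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise ParseError(f"{path}: failed to parse PDB ({exc})") from exc
    ag = u.atoms
    elements = None
    if hasattr(ag, "elements"):
        elements = [e if e else _guess_element(n)
                    for e, n in zip(ag.elements, ag.names)]
    records = [(n, rn, int(ri)) for n, rn, ri in
               zip(ag.names, ag.resnames, ag.resids)]
    topology = Topology.from_records(records, role_table=role_table,
                                     elements=elements)
    if box is not None:
        box_nm = np.asarray(box, dtype=float)
    else:
        box_nm = _check_orthorhombic(u.dimensions, path)
    return topology, Frame(ag.positions / 10.0, box_nm, time=0.0)


def write_pdb(topology: Topology, frame: Frame, path,
              bfactors: np.ndarray | None = None) -> None:
    """Write a single-frame PDB; optional per-atom scalars go to the
    B-factor column (used for structure colouring by contact frequency)."""
    frame.check(topology)
    mda = _mda()
    resids_seq = []
    resnames_seq = []
    atom_resindex = []
    for a in topology.atoms:
        key = (a.residue_id, a.residue_name)
        if not resids_seq or key != (resids_seq[-1], resnames_seq[-1]):
            resids_seq.append(a.residue_id)
            resnames_seq.append(a.residue_name)
        atom_resindex.append(len(resids_seq) - 1)
    u = mda.Universe.empty(topology.n_atoms, n_residues=len(resids_seq),
                           atom_resindex=atom_resindex, trajectory=True)
    u.add_TopologyAttr("names", list(topology.names))
    u.add_TopologyAttr("resnames", resnames_seq)
    u.add_TopologyAttr("resids", resids_seq)
    u.add_TopologyAttr("elements", list(topology.elements))
    u.add_TopologyAttr("tempfactors",
                       np.zeros(topology.n_atoms) if bfactors is None
                       else np.asarray(bfactors, dtype=float))
    u.atoms.positions = frame.coordinates * 10.0
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                    90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_mda_trajectory(path, topology: Topology, fmt: str,
                        stride: int = 1, start: int = 0,
                        stop: int | None = None) -> Trajectory:
    """Read an XTC or DCD trajectory through the MDAnalysis adapter."""
    mda = _mda()
    path = str(path)
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        u.load_new(path, format=fmt)
    except Exception as exc:
        raise ParseError(f"{path}: failed to read {fmt} trajectory ({exc})") from exc
    if u.trajectory.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"{path}: trajectory has {u.trajectory.n_atoms} atoms, "
            f"topology {topology.n_atoms}")
    frames = []
    for ts in u.trajectory[start:stop:stride]:
        box_nm = _check_orthorhombic(ts.dimensions, path)
        frames.append(Frame(ts.positions / 10.0, box_nm, time=float(ts.time)))
    if not frames:
        raise ParseError(f"{path}: no frames found in trajectory file")
    return Trajectory(topology, frames)


# ----------------------------------------------------------------- dispatch

def read_structure(path, format: str | None = None,
                   role_table: Mapping[str, str] | None = None,
                   box: Sequence[float] | None = None):
    """Read a structure file, returning ``(Topology, Frame)``.

    ``format`` is ``"gro"`` or ``"pdb"``; inferred from the suffix when
    omitted.
    """
    fmt = (format or Path(str(path)).suffix.lstrip(".")).lower()
    if fmt == "gro":
        return read_gro(path, role_table=role_table)
    if fmt == "pdb":
        return read_pdb(path, role_table=role_table, box=box)
    raise ValueError(f"unknown structure format {fmt!r}")


def write_structure(topology: Topology, frame: Frame, path,
                    format: str | None = None) -> None:
    fmt = (format or Path(str(path)).suffix.lstrip(".")).lower()
    if fmt == "gro":
        write_gro(topology, frame, path)
    elif fmt == "pdb":
        write_pdb(topology, frame, path)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")


def read_trajectory(path, topology: Topology | None = None,
                    format: str | None = None, stride: int = 1,
                    start: int = 0, stop: int | None = None,
                    role_table: Mapping[str, str] | None = None) -> Trajectory:
    """Read a trajectory (``multi_gro``, ``xtc`` or ``dcd``).

    ``multi_gro`` can infer its topology from the first frame; XTC/DCD
    require an explicit topology.
    """
    fmt = (format or Path(str(path)).suffix.lstrip(".")).lower()
    if fmt in ("multi_gro", "gro", "mgro"):
        return read_multi_gro(path, topology=topology, stride=stride,
                              start=start, stop=stop, role_table=role_table)
    if fmt in ("xtc", "dcd"):
        if topology is None:
            raise TopologyError(f"{fmt} trajectories require a topology")
        return read_mda_trajectory(path, topology, fmt, stride=stride,
                                   start=start, stop=stop)
    raise ValueError(f"unknown trajectory format {fmt!r}")
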