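"""Core data model: atoms, topologies, frames, trajectories and atom sets.

Internal conventions
--------------------
* Lengths are nanometres everywhere; file readers convert at the boundary.
* Atom indices are 0-based internally; residue ids are 1-based, as in the
  source files.
* Boxes are orthorhombic. Triclinic input raises :class:`UnsupportedBoxError`.
* Every atom carries a ``role`` tag (lipid, water, ion, glycan, protein,
  linker) assigned from a user-editable residue-name table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

ROLES = ("lipid", "water", "ion", "glycan", "protein", "linker")

#: Default residue-name -> role table. Keys are matched case-insensitively.
#: Users may pass their own table to :func:`assign_roles`.
DEFAULT_ROLE_TABLE: dict[str, str] = {
    # common bilayer lipids
    "dmpc": "lipid", "popc": "lipid", "dppc": "lipid", "dopc": "lipid",
    "pope": "lipid", "lip": "lipid",
    # water models
    "sol": "water", "wat": "water", "hoh": "water",
    "tip3": "water", "tip3p": "water", "tip5": "water", "tip5p": "water",
    "spc": "water", "spce": "water",
    # monatomic ions
    "na": "ion", "na+": "ion", "cl": "ion", "cl-": "ion", "k": "ion",
    "k+": "ion", "mg": "ion", "ca": "ion",
    # GPI glycan residues (5-char truncations included for GRO files)
    "ino": "glycan", "glcn": "glycan",
    "man1": "glycan", "man2": "glycan", "man3": "glycan",
    "pgl": "glycan",
    "galnac": "glycan", "galna": "glycan",
    "glcnac": "glycan", "glcna": "glycan",
    "glc": "glycan", "gal": "glycan",
    # phosphoethanolamine linkers
    "tpetn": "linker", "mpetn": "linker", "petn": "linker",
    # synthetic fixture residues
    "rod": "protein",
    "don": "glycan", "acc": "water",
    "gpa": "glycan", "gpb": "protein",
}

_AMINO_ACIDS = {
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
    "hie", "hid", "hip", "cyx", "ash", "glh", "lyn", "ace", "nme", "nma",
}


class TopologyError(ValueError):
    """Raised for inconsistent or unresolvable topology information."""


class UnsupportedBoxError(ValueError):
    """Raised when a non-orthorhombic box is encountered."""


def resolve_role(residue_name: str,
                 table: Mapping[str, str] | None = None) -> str:
    """Map a residue name to a role tag.

    Unknown residues fall back to ``protein`` when amino-acid-named,
    otherwise a :class:`TopologyError` is raised so silent mis-tagging
    cannot occur.
    """
    tab = DEFAULT_ROLE_TABLE if table is None else table
    key = residue_name.strip().lower()
    if key in tab:
        role = tab[key]
        if role not in ROLES:
            raise TopologyError(
                f"role table maps {residue_name!r} to unknown role {role!r}")
        return role
    if key in _AMINO_ACIDS:
        return "protein"
    raise TopologyError(
        f"residue name {residue_name!r} has no role; extend the role table")


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass(frozen=True)
class Atom:
    """A single atom with bookkeeping metadata (coordinates live in Frame)."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    molecule_id: int
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise TopologyError(f"unknown role {self.role!r}")


class Topology:
    """An ordered collection of atoms with residue/molecule bookkeeping."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise TopologyError(f"duplicate atom index {a.index}")
            seen.add(a.index)
        if self.atoms and [a.index for a in self.atoms] != list(range(len(self.atoms))):
            raise TopologyError("atom indices must be 0..n-1 in order")
        # cached per-atom arrays for fast selection
        self.names = np.array([a.name for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=int)
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=int)
        self.elements = np.array([a.element for a in self.atoms])
        self.roles = np.array([a.role for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, int]],
                     role_table: Mapping[str, str] | None = None,
                     elements: Sequence[str] | None = None) -> "Topology":
        """Build a Topology from ``(atom_name, residue_name, residue_id)``
        records, assigning elements, molecule ids and roles.

        Molecule ids are assigned per residue (each residue its own
        molecule); multi-residue molecules only matter to analyses that
        receive explicit bond lists, which carry their own connectivity.
        """
        atoms = []
        mol = 0
        prev = None
        for i, (name, resname, resid) in enumerate(records):
            if prev is not None and (resid, resname) != prev:
                mol += 1
            prev = (resid, resname)
            elem = elements[i] if elements is not None else _guess_element(name)
            atoms.append(Atom(index=i, name=name, element=elem,
                              residue_name=resname, residue_id=int(resid),
                              molecule_id=mol,
                              role=resolve_role(resname, role_table)))
        return cls(atoms)

    def residue_atom_indices(self, residue_id: int) -> np.ndarray:
        return np.nonzero(self.residue_ids == residue_id)[0]


@dataclass
class Frame:
    """Coordinates (nm) for one time point plus the orthorhombic box."""

    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray          # (3,) nm
    time: float = 0.0        # ps

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if not np.all(self.box > 0):
            raise ValueError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def check(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"frame has {self.n_atoms} atoms, topology {topology.n_atoms}")


class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    def __init__(self, topology: Topology, frames: Sequence[Frame],
                 dt: float | None = None):
        frames = list(frames)
        for f in frames:
            f.check(topology)
        times = [f.time for f in frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")
        self.topology = topology
        self.frames = frames
        self.dt = dt  # ps per saved frame (metadata; never inferred)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.topology, self.frames[i], dt=self.dt)
        return self.frames[i]

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.topology, self.frames[::stride], dt=self.dt)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frame coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass
class AtomSet:
    """A sorted, de-duplicated set of atom indices against one topology."""

    topology: Topology
    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.topology.n_atoms):
            raise TopologyError("atom index out of range for topology")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices.tolist())

    def positions(self, frame: Frame) -> np.ndarray:
        return frame.coordinates[self.indices]

    def union(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(self.topology,
                       np.union1d(self.indices, other.indices),
                       label=self.label)

    def intersection(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(self.topology,
                       np.intersect1d(self.indices, other.indices),
                       label=self.label)
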