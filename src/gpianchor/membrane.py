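"""Bilayer reference frame: mid-plane, leaflet assignment, depth profiles.

The bilayer normal is fixed to the box z-axis (the systems of interest are
planar patches assembled normal to z); the mid-plane is the mean z of the
headgroup phosphorus atoms, and lipids are assigned to the top or bottom
leaflet by the side of the mid-plane their phosphorus falls on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import AtomSet, Frame, Trajectory

logger = logging.getLogger(__name__)


class MembraneError(ValueError):
    pass


def _unwrapped_z(frame: Frame, atom_set: AtomSet) -> np.ndarray:
    """z of the set's atoms, unwrapped across the z boundary relative to
    the first atom so a leaflet split by the boundary stays contiguous."""
    z = frame.coordinates[atom_set.indices, 2]
    lz = frame.box[2]
    dz = z - z[0]
    dz -= lz * np.ceil(dz / lz - 0.5)
    return z[0] + dz


def bilayer_midplane(frame: Frame, phosphorus_set: AtomSet) -> float:
    """Mean z (nm) of the headgroup phosphorus atoms, unwrapped in z."""
    if len(phosphorus_set) == 0:
        raise MembraneError("phosphorus set is empty")
    return float(np.mean(_unwrapped_z(frame, phosphorus_set)))


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels plus the mid-plane that produced them."""

    leaflet: dict[int, str]   # molecule_id -> "top" | "bottom"
    midplane_z: float         # nm

    @property
    def n_top(self) -> int:
        return sum(1 for v in self.leaflet.values() if v == "top")

    @property
    def n_bottom(self) -> int:
        return sum(1 for v in self.leaflet.values() if v == "bottom")

    def molecules(self, which: str) -> list[int]:
        return sorted(m for m, v in self.leaflet.items() if v == which)


def assign_leaflets(frame: Frame, phosphorus_set: AtomSet,
                    midplane_z: float | None = None) -> LeafletAssignment:
    """Assign each lipid molecule to the top or bottom leaflet.

    A lipid is "top" iff the signed minimum-image z-offset of its
    phosphorus from the mid-plane is positive; an exactly-zero offset is
    assigned top with a logged warning.
    """
    if len(phosphorus_set) == 0:
        raise MembraneError("phosphorus set is empty")
    if midplane_z is None:
        midplane_z = bilayer_midplane(frame, phosphorus_set)
    mol_ids = phosphorus_set.topology.molecule_ids[phosphorus_set.indices]
    z = frame.coordinates[phosphorus_set.indices, 2]
    dz = z - midplane_z
    lz = frame.box[2]
    dz = dz - lz * np.ceil(dz / lz - 0.5)
    leaflet: dict[int, str] = {}
    for mol, offset in zip(mol_ids, dz):
        if offset == 0.0:
            logger.warning("lipid molecule %d phosphorus exactly at the "
                           "mid-plane; assigned to top leaflet", mol)
        leaflet[int(mol)] = "top" if offset >= 0 else "bottom"
    return LeafletAssignment(leaflet=leaflet, midplane_z=float(midplane_z))


def leaflet_phosphate_plane(frame: Frame, phosphorus_set: AtomSet,
                            assignment: LeafletAssignment,
                            which: str) -> float:
    """Mean z (nm) of one leaflet's phosphorus atoms."""
    mols = set(assignment.molecules(which))
    mask = np.array([m in mols for m in
                     phosphorus_set.topology.molecule_ids[phosphorus_set.indices]])
    if not mask.any():
        raise MembraneError(f"no phosphorus atoms in {which} leaflet")
    sub = AtomSet(phosphorus_set.topology, phosphorus_set.indices[mask])
    return float(np.mean(_unwrapped_z(frame, sub)))


def depth_profile(traj: Trajectory, residue_set: AtomSet,
                  phosphorus_set: AtomSet, bin_width: float = 0.02,
                  z_range: tuple[float, float] = (-3.0, 3.0)) -> pd.DataFrame:
    """Distribution of the signed z-distance of a residue's centroid from
    its own leaflet's phosphate plane, over a trajectory.

    Sign is positive toward the solvent (up for the top leaflet, down for
    the bottom). Returns a DataFrame with ``bin_center`` and ``density``
    columns; the density integrates to one over the sampled range.
    """
    if traj.n_frames == 0:
        raise MembraneError("empty trajectory")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    distances = np.empty(traj.n_frames)
    for k, frame in enumerate(traj):
        assignment = assign_leaflets(frame, phosphorus_set)
        centroid_z = float(np.mean(_unwrapped_z(frame, residue_set)))
        lz = frame.box[2]
        off = centroid_z - assignment.midplane_z
        off -= lz * np.ceil(off / lz - 0.5)
        which = "top" if off >= 0 else "bottom"
        plane = leaflet_phosphate_plane(frame, phosphorus_set, assignment, which)
        d = centroid_z - plane
        d -= lz * np.ceil(d / lz - 0.5)
        distances[k] = d if which == "top" else -d
    edges = np.arange(z_range[0], z_range[1] + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    total = counts.sum()
    if total == 0:
        raise MembraneError("all depth samples fall outside z_range")
    density = counts / (total * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "density": density})
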