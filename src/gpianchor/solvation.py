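"""Hydrogen bonds, hydration numbers, and contact statistics under PBC.

All distance criteria are inclusive (<=) at the boundary, matching the
"within a radius/cutoff" semantics, and every distance is a minimum-image
distance in the orthorhombic box.

Neighbour searches use a periodic KD-tree to pre-select candidate pairs
(with a slightly inflated radius) and then confirm every candidate with
the same minimum-image arithmetic the definitions use, so results are
identical to a brute-force double loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import minimum_image_displacement
from .system import AtomSet, Frame, Trajectory

#: Default geometric hydrogen-bond criterion: donor-acceptor distance and
#: hydrogen-donor-acceptor angle. The de-facto standard of the major MD
#: analysis tools; override via :class:`HBondCriterion`.
DEFAULT_HBOND_DISTANCE = 0.35   # nm
DEFAULT_HBOND_ANGLE = 30.0      # degrees

#: Default hydration radius (water oxygens within this distance of any
#: residue atom are counted).
HYDRATION_CUTOFF = 0.3          # nm

#: Default heavy-atom contact cutoff for residue-residue contact maps.
CONTACT_CUTOFF = 0.5            # nm

#: Lipid headgroup atom names per lipid type: phosphate, choline and
#: glycerol-ester oxygens. User-editable (pass your own to selections).
HEADGROUP_ATOM_NAMES = {
    "DMPC": ["P", "O11", "O12", "O13", "O14", "N", "C13", "C14", "C15",
             "O21", "O22", "O31", "O32"],
    "POPC": ["P", "O11", "O12", "O13", "O14", "N", "C13", "C14", "C15",
             "O21", "O22", "O31", "O32"],
}


class SolvationError(ValueError):
    pass


def _candidate_pairs(pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray,
                     cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into pos_a, pos_b) of pairs possibly within ``cutoff``.

    Uses a periodic KD-tree with an inflated radius; callers must confirm
    with exact minimum-image distances. Falls back to the full cross
    product for small inputs.
    """
    na, nb = len(pos_a), len(pos_b)
    if na * nb <= 4096:
        ia, ib = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
        return ia.ravel(), ib.ravel()
    wrapped_a = np.mod(pos_a, box)
    wrapped_b = np.mod(pos_b, box)
    # guard against coordinates == box edge after fp rounding
    wrapped_a = np.where(wrapped_a >= box, 0.0, wrapped_a)
    wrapped_b = np.where(wrapped_b >= box, 0.0, wrapped_b)
    tree_a = cKDTree(wrapped_a, boxsize=box)
    tree_b = cKDTree(wrapped_b, boxsize=box)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff * (1.0 + 1e-9) + 1e-9)
    ia = np.concatenate([[i] * len(js) for i, js in enumerate(pairs)]) \
        if any(pairs) else np.empty(0, dtype=int)
    ib = np.concatenate([np.asarray(js, dtype=int) for js in pairs]) \
        if any(pairs) else np.empty(0, dtype=int)
    return ia.astype(int), ib.astype(int)


def _pairs_within(frame: Frame, set_a: np.ndarray, set_b: np.ndarray,
                  cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) atom-index pairs with minimum-image distance <= cutoff."""
    pos_a = frame.coordinates[set_a]
    pos_b = frame.coordinates[set_b]
    ia, ib = _candidate_pairs(pos_a, pos_b, frame.box, cutoff)
    if ia.size == 0:
        return ia, ib
    d = minimum_image_displacement(pos_a[ia], pos_b[ib], frame.box)
    keep = np.einsum("ij,ij->i", d, d) <= cutoff * cutoff
    return set_a[ia[keep]], set_b[ib[keep]]


# ------------------------------------------------------------- hydrogen bonds

@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    A donor D (with covalently bonded hydrogen H) and acceptor A form a
    bond iff dist(D, A) <= ``distance_cutoff`` and the H-D-A angle
    (at the donor) <= ``angle_cutoff``.
    """

    distance_cutoff: float = DEFAULT_HBOND_DISTANCE   # nm
    angle_cutoff: float = DEFAULT_HBOND_ANGLE         # degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


def find_hbonds(frame: Frame, donors: AtomSet,
                hydrogens: Mapping[int, Sequence[int]],
                acceptors: AtomSet,
                criterion: HBondCriterion | None = None) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the criterion.

    ``hydrogens`` maps each donor atom index to its covalently bonded
    hydrogen indices (connectivity is supplied explicitly, not guessed).
    Pairs within the same residue are excluded.
    """
    crit = criterion or HBondCriterion()
    top = donors.topology
    for d in donors.indices:
        if int(d) not in hydrogens or len(hydrogens[int(d)]) == 0:
            raise SolvationError(
                f"donor atom {int(d)} ({top.names[d]}) has no declared hydrogen")
    di, ai = _pairs_within(frame, donors.indices, acceptors.indices,
                           crit.distance_cutoff)
    triples: list[tuple[int, int, int]] = []
    resids = top.residue_ids
    for d, a in zip(di.tolist(), ai.tolist()):
        if d == a or resids[d] == resids[a]:
            continue
        vec_da = minimum_image_displacement(frame.coordinates[d],
                                            frame.coordinates[a], frame.box)
        nda = np.linalg.norm(vec_da)
        for h in hydrogens[d]:
            vec_dh = minimum_image_displacement(frame.coordinates[d],
                                                frame.coordinates[h], frame.box)
            ndh = np.linalg.norm(vec_dh)
            if ndh < 1e-12 or nda < 1e-12:
                continue
            cosang = np.clip(np.dot(vec_da, vec_dh) / (nda * ndh), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) <= crit.angle_cutoff:
                triples.append((d, int(h), a))
    return sorted(triples)


def hbond_count_distribution(traj: Trajectory, residue: AtomSet,
                             partner: AtomSet, donors: AtomSet,
                             hydrogens: Mapping[int, Sequence[int]],
                             acceptors: AtomSet,
                             criterion: HBondCriterion | None = None) -> pd.DataFrame:
    """Distribution of the per-frame number of H-bonds between a residue
    and a partner group (lipid headgroups or water), counting both
    donor->acceptor directions.

    Returns columns ``count`` and ``probability`` (summing to one).
    """
    if len(partner) == 0:
        raise SolvationError("partner atom set is empty")
    if traj.n_frames == 0:
        raise SolvationError("empty trajectory")
    res_set = set(residue.indices.tolist())
    par_set = set(partner.indices.tolist())
    counts = np.zeros(traj.n_frames, dtype=int)
    for k, frame in enumerate(traj):
        n = 0
        for d, _h, a in find_hbonds(frame, donors, hydrogens, acceptors,
                                    criterion):
            if (d in res_set and a in par_set) or (d in par_set and a in res_set):
                n += 1
        counts[k] = n
    values, freq = np.unique(counts, return_counts=True)
    return pd.DataFrame({"count": values,
                         "probability": freq / freq.sum()})


# ----------------------------------------------------------------- hydration

def hydration_number(frame: Frame, residue: AtomSet, water_oxygens: AtomSet,
                     cutoff: float = HYDRATION_CUTOFF) -> int:
    """Number of water oxygens within ``cutoff`` of ANY atom of the
    residue; each oxygen counted once regardless of how many residue
    atoms it neighbours."""
    if np.intersect1d(residue.indices, water_oxygens.indices).size:
        raise SolvationError("residue and water sets overlap")
    _ri, oi = _pairs_within(frame, residue.indices, water_oxygens.indices,
                            cutoff)
    return int(np.unique(oi).size)


# ------------------------------------------------------------------ contacts

@dataclass
class ContactMap:
    """Residue-by-residue fraction of frames in contact."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray        # (n_rows, n_cols) in [0, 1]
    cutoff: float             # nm
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


def _frame_contact(frame: Frame, a_idx: np.ndarray, b_idx: np.ndarray,
                   cutoff: float) -> bool:
    ia, _ib = _pairs_within(frame, a_idx, b_idx, cutoff)
    return ia.size > 0


def contact_map(traj: Trajectory, group_a: Sequence[AtomSet],
                group_b: Sequence[AtomSet],
                cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Cell (i, j) = fraction of frames in which residues A_i and B_j have
    at least one atom pair within ``cutoff`` (minimum image)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not group_a or not group_b:
        raise SolvationError("contact groups must be non-empty")
    if traj.n_frames == 0:
        raise SolvationError("empty trajectory")
    hits = np.zeros((len(group_a), len(group_b)), dtype=int)
    for frame in traj:
        for i, sa in enumerate(group_a):
            for j, sb in enumerate(group_b):
                if _frame_contact(frame, sa.indices, sb.indices, cutoff):
                    hits[i, j] += 1
    return ContactMap(row_labels=[s.label or f"A{i}" for i, s in enumerate(group_a)],
                      col_labels=[s.label or f"B{j}" for j, s in enumerate(group_b)],
                      values=hits / traj.n_frames, cutoff=cutoff,
                      n_frames=traj.n_frames)


def atom_contact_frequency(traj: Trajectory, target: AtomSet, probe: AtomSet,
                           cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Per-target-atom fraction of frames with >= 1 probe atom within
    ``cutoff``. Suitable for export into the B-factor column of a PDB for
    structure colouring (see :func:`gpianchor.io.write_pdb`)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames == 0:
        raise SolvationError("empty trajectory")
    hits = np.zeros(len(target), dtype=int)
    pos_map = {int(a): k for k, a in enumerate(target.indices)}
    for frame in traj:
        ti, _pi = _pairs_within(frame, target.indices, probe.indices, cutoff)
        for t in np.unique(ti):
            hits[pos_map[int(t)]] += 1
    return hits / traj.n_frames
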