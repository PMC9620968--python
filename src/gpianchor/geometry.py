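"""PBC-aware vector geometry: minimum image, angles, dihedrals, Kabsch.

All routines take coordinates in nm and orthorhombic box lengths in nm.
Angles are reported in degrees. Dihedrals follow the IUPAC sign convention
and are mapped to [0, 360) for rotamer work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Degenerate geometry (coincident points, collinear fit atoms...)."""


def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Displacement b - a shifted by integer box multiples to its shortest
    image; every component lies in (-L/2, L/2].

    Broadcasts: ``a`` and ``b`` may be (..., 3) arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if not np.all(box > 0):
        raise ValueError(f"box lengths must be positive, got {box}")
    d = b - a
    # ceil(d/L - 1/2) keeps the +L/2 boundary and maps -L/2 to +L/2
    return d - box * np.ceil(d / box - 0.5)


def minimum_image_distance(a, b, box) -> np.ndarray:
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


def angle_deg(v1, v2) -> np.ndarray:
    """Angle between two vectors (broadcasting over leading axes)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise GeometryError("zero-length vector in angle computation")
    cosang = np.clip(np.sum(v1 * v2, axis=-1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def dihedral(p1, p2, p3, p4, box=None) -> np.ndarray:
    """Dihedral angle of four points, in degrees in [0, 360).

    IUPAC sign convention (positive clockwise viewed from p2 towards p3),
    mapped to [0, 360). When ``box`` is given each consecutive displacement
    is taken under the minimum image convention, which makes the result
    correct for bonded quadruples straddling the periodic boundary.
    Broadcasts over leading axes.
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    if box is None:
        b1 = pts[1] - pts[0]
        b2 = pts[2] - pts[1]
        b3 = pts[3] - pts[2]
    else:
        b1 = minimum_image_displacement(pts[0], pts[1], box)
        b2 = minimum_image_displacement(pts[1], pts[2], box)
        b3 = minimum_image_displacement(pts[2], pts[3], box)
    for k, b in enumerate((b1, b2, b3)):
        if np.any(np.linalg.norm(b, axis=-1) < 1e-10):
            raise GeometryError(f"coincident points on bond {k + 1}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-12) or \
            np.any(np.linalg.norm(n2, axis=-1) < 1e-12):
        raise GeometryError("collinear bonds: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = -np.degrees(np.arctan2(y, x))   # IUPAC sign (matches MDAnalysis)
    return np.mod(ang, 360.0)


@dataclass
class SuperpositionResult:
    """Least-squares rigid-body fit of a mobile structure onto a reference.

    ``transform`` maps mobile coordinates onto the reference:
    ``x' = (x - mobile_centroid) @ rotation.T + reference_centroid``.
    """

    rotation: np.ndarray      # (3, 3), proper (det = +1)
    translation: np.ndarray   # (3,) nm: reference_centroid - R @ mobile_centroid
    rmsd: float               # nm, over the measure set

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _check_fit_coords(coords: np.ndarray, what: str) -> None:
    if coords.shape[0] < 3:
        raise GeometryError(f"need >= 3 fit atoms, got {coords.shape[0]} ({what})")
    centered = coords - coords.mean(axis=0)
    # collinear points have covariance rank < 2
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1e-30) or s[0] < 1e-12:
        raise GeometryError(f"fit atoms are collinear or coincident ({what})")


def kabsch_superpose(mobile, reference, fit_indices: Sequence[int] | None = None,
                     measure_indices: Sequence[int] | None = None,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    The transform minimises the weighted least-squares deviation over the
    fit atoms; the reported RMSD is evaluated over ``measure_indices``
    (default: the fit set) after applying the transform. Reflections are
    excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError("mobile and reference shapes differ")
    fit = np.arange(mobile.shape[0]) if fit_indices is None \
        else np.asarray(fit_indices, dtype=int)
    mob_fit = mobile[fit]
    ref_fit = reference[fit]
    _check_fit_coords(mob_fit, "mobile")
    _check_fit_coords(ref_fit, "reference")
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is None:
        mob_c = mob_fit.mean(axis=0)
        ref_c = ref_fit.mean(axis=0)
    else:
        mob_c = np.average(mob_fit, axis=0, weights=w)
        ref_c = np.average(ref_fit, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(ref_fit - ref_c, mob_fit - mob_c,
                                    weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    measure = fit if measure_indices is None else np.asarray(measure_indices, int)
    moved = mobile[measure] @ R.T + t
    diff = moved - reference[measure]
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def make_whole(coordinates: np.ndarray, box, bonds: Iterable[tuple[int, int]]) -> np.ndarray:
    """Unwrap molecules across periodic boundaries by bond-graph traversal.

    Starting from the lowest-index atom of each connected component, each
    bonded neighbour is placed at its minimum-image position relative to
    its already-placed parent. Atoms without bonds are left untouched.
    """
    coords = np.array(coordinates, dtype=float)
    box = np.asarray(box, dtype=float)
    n = coords.shape[0]
    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(int(i), []).append(int(j))
        adj.setdefault(int(j), []).append(int(i))
    visited = np.zeros(n, dtype=bool)
    for root in sorted(adj):
        if visited[root]:
            continue
        visited[root] = True
        stack = [root]
        while stack:
            parent = stack.pop()
            for child in adj[parent]:
                if visited[child]:
                    continue
                coords[child] = coords[parent] + minimum_image_displacement(
                    coords[parent], coords[child], box)
                visited[child] = True
                stack.append(child)
    return coords
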