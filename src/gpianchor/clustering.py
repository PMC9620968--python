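"""Conformational clustering by the neighbour-count (GROMOS/Daura)
algorithm on a pairwise-RMSD matrix.

The algorithm: compute RMSD between every pair of structures (after
least-squares superposition on a fit set); count, for each structure, its
neighbours within the cutoff; the structure with the most neighbours
becomes a cluster center and it plus its neighbours are removed from the
pool; repeat until the pool is empty. A structure is its own neighbour
(distance 0 <= cutoff). Ties in the neighbour count are broken by the
lowest structure index, which makes the procedure fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .geometry import GeometryError, _check_fit_coords
from .system import AtomSet, Frame

#: Default RMSD cutoff (nm) for glycan conformational clustering; looser
#: than the ~0.1 nm customary for proteins because carbohydrates are far
#: more flexible.
CLUSTER_RMSD_CUTOFF = 0.3


@dataclass
class Cluster:
    center: int
    members: list[int]   # sorted, includes the center

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Disjoint clusters ordered by decreasing size (ties: lower center
    index first). ``n_structures`` is retained through filtering so size
    distributions can stay normalised to the full ensemble."""

    clusters: list[Cluster]
    rmsd_cutoff: float
    n_structures: int
    min_members: int | None = None   # set by filter_clusters

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def validate(self) -> None:
        all_members: list[int] = []
        for c in self.clusters:
            if c.center not in c.members:
                raise ValueError(f"center {c.center} not in its member list")
            all_members.extend(c.members)
        if len(all_members) != len(set(all_members)):
            raise ValueError("clusters are not disjoint")
        if self.min_members is None and sorted(all_members) != list(range(self.n_structures)):
            raise ValueError("clusters do not cover all structures")
        if any(s2 > s1 for s1, s2 in zip(self.sizes, self.sizes[1:])):
            raise ValueError("cluster sizes not non-increasing")

    def to_json(self, path=None) -> str:
        payload = {
            "rmsd_cutoff_nm": self.rmsd_cutoff,
            "n_structures": self.n_structures,
            "min_members": self.min_members,
            "clusters": [{"rank": k + 1, "center": c.center,
                          "size": c.size, "members": c.members}
                         for k, c in enumerate(self.clusters)],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def pairwise_rmsd_matrix(ensemble, fit_set: AtomSet | np.ndarray,
                         measure_set: AtomSet | np.ndarray | None = None,
                         chunk: int = 2048) -> np.ndarray:
    """Symmetric matrix of least-squares-superposed RMSDs (nm).

    Entry (i, j) is the RMSD over the measure set after superposing
    structure j onto structure i over the fit set. ``ensemble`` is a list
    of Frames or an (n_structures, n_atoms, 3) array. Coordinates are
    plain (non-mass-weighted).
    """
    if isinstance(ensemble, np.ndarray):
        coords = np.asarray(ensemble, dtype=float)
    else:
        coords = np.stack([f.coordinates if isinstance(f, Frame) else np.asarray(f)
                           for f in ensemble])
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two structures")
    fit = fit_set.indices if isinstance(fit_set, AtomSet) else np.asarray(fit_set, int)
    if measure_set is None:
        measure = fit
    else:
        measure = measure_set.indices if isinstance(measure_set, AtomSet) \
            else np.asarray(measure_set, int)
    for k in range(n):
        try:
            _check_fit_coords(coords[k][fit], f"structure {k}")
        except GeometryError as exc:
            raise GeometryError(f"degenerate fit set: {exc}") from exc

    cfit = coords[:, fit, :].mean(axis=1, keepdims=True)          # (n,1,3)
    A = coords[:, fit, :] - cfit                                  # (n,F,3)
    B = coords[:, measure, :] - cfit                              # (n,M,3)

    ii, jj = np.triu_indices(n, k=1)
    rmsd = np.zeros((n, n))
    for s in range(0, ii.size, chunk):
        i = ii[s:s + chunk]
        j = jj[s:s + chunk]
        # cross-covariance per pair; rotation R maps structure j onto i
        H = np.einsum("pfa,pfb->pab", A[j], A[i])                 # (p,3,3)
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(np.einsum("pab,pbc->pac", U, Vt)))
        U[:, :, 2] *= d[:, None]
        R = np.einsum("pab,pbc->pac", U, Vt)                      # (p,3,3)
        moved = np.einsum("pma,pab->pmb", B[j], R)                # (p,M,3)
        diff = moved - B[i]
        rmsd_vals = np.sqrt(np.einsum("pma,pma->p", diff, diff) / len(measure))
        rmsd[i, j] = rmsd_vals
        rmsd[j, i] = rmsd_vals
    return rmsd


def gromos_cluster(matrix: np.ndarray,
                   cutoff: float = CLUSTER_RMSD_CUTOFF) -> ClusterResult:
    """Neighbour-count clustering of a pairwise RMSD matrix.

    Repeatedly extracts the unassigned structure with the largest number
    of unassigned neighbours within ``cutoff`` (self included) as a
    center, together with those neighbours, until the pool is empty.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.ndim != 2 or matrix.shape[1] != n:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adjacency = matrix <= cutoff
    np.fill_diagonal(adjacency, True)   # a structure neighbours itself
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (adjacency & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))   # argmax takes the lowest index on ties
        members = np.nonzero(adjacency[center] & unassigned)[0]
        clusters.append(Cluster(center=center, members=members.tolist()))
        unassigned[members] = False
    clusters.sort(key=lambda c: (-c.size, c.center))
    result = ClusterResult(clusters=clusters, rmsd_cutoff=float(cutoff),
                           n_structures=n)
    result.validate()
    return result


def filter_clusters(result: ClusterResult, min_members: int) -> ClusterResult:
    """Keep only clusters with STRICTLY more than ``min_members`` members
    ("more than 40 members" semantics). Total structure count metadata is
    retained for normalisation."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    kept = [Cluster(c.center, list(c.members)) for c in result.clusters
            if c.size > min_members]
    return ClusterResult(clusters=kept, rmsd_cutoff=result.rmsd_cutoff,
                         n_structures=result.n_structures,
                         min_members=min_members)


def cluster_size_distribution(result: ClusterResult) -> pd.DataFrame:
    """Table of cluster number (1..K, decreasing population) vs size."""
    if not result.clusters:
        raise ValueError("empty cluster result")
    return pd.DataFrame({
        "cluster": np.arange(1, len(result.clusters) + 1),
        "size": result.sizes,
        "center": [c.center for c in result.clusters],
    })
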