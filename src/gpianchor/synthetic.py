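"""Synthetic membrane/glycan/protein systems with known ground truth.

Microsecond-scale membrane trajectories are too expensive to regenerate,
so every analysis stage in this package is validated against synthetic
systems whose statistical structure is planted by construction:

* a two-leaflet pseudo-lipid bilayer on a jittered lattice with a known
  mid-plane and leaflet assignment;
* a rigid pseudo-glycan whose glycosidic torsions are set exactly via
  internal-coordinate (NeRF) construction, so planted dihedral series are
  reproduced to numerical precision;
* circular (von Mises mixture) torsion sampling with prescribed rotamer
  weights, drawn by inverse-CDF on a fine grid so seeds reproduce across
  platforms;
* water shells realising exact per-residue hydration counts;
* conformer ensembles with planted cluster membership;
* rigid-rod trajectories following a prescribed AR(1) tilt-angle process.

The pseudo-molecules are geometrically, not chemically, faithful: the
analyses under test are purely geometric/statistical, so simplified
fixtures are sufficient and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clustering import pairwise_rmsd_matrix
from .system import Frame, Topology, Trajectory
from .torsions import LinkageSpec


class SyntheticError(ValueError):
    pass


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


# ------------------------------------------------------------------ bilayer

@dataclass
class BilayerSpec:
    """A two-leaflet pseudo-lipid patch on a jittered lattice."""

    nx: int = 8
    ny: int = 8
    # box z is generous so the two phosphate planes stay within half a
    # box length of each other (minimum-image unwrapping stays unambiguous)
    box: tuple[float, float, float] = (6.4, 6.4, 10.0)  # nm
    midplane_z: float = 3.25                            # nm
    leaflet_offset: float = 1.75   # phosphate plane distance from mid-plane
    jitter_xy: float = 0.05        # nm, lattice jitter
    jitter_z: float = 0.05         # nm, phosphate z noise
    resname: str = "DMPC"

    @property
    def n_lipids(self) -> int:
        return 2 * self.nx * self.ny


def build_bilayer_lattice(spec: BilayerSpec, seed: int = 0):
    """Build the bilayer, returning ``(Topology, Frame, ground_truth)``.

    Each pseudo-lipid is a phosphorus head atom plus two tail beads
    pointing toward the mid-plane. ``ground_truth`` records the planted
    mid-plane and the leaflet of every lipid molecule id.
    """
    sx = spec.box[0] / spec.nx
    sy = spec.box[1] / spec.ny
    if sx < 0.3 or sy < 0.3:
        raise SyntheticError(
            f"box too small for {spec.nx}x{spec.ny} lattice "
            f"(spacing {sx:.2f} x {sy:.2f} nm)")
    if spec.midplane_z - spec.leaflet_offset - 1.0 < 0 or \
            spec.midplane_z + spec.leaflet_offset + 1.0 > spec.box[2]:
        raise SyntheticError("bilayer does not fit in the box in z")
    rng = _rng(seed)
    records = []
    coords = []
    leaflets: dict[int, str] = {}
    resid = 0
    for sign, leaflet in ((+1, "top"), (-1, "bottom")):
        for i in range(spec.nx):
            for j in range(spec.ny):
                resid += 1
                x = (i + 0.5) * sx + rng.normal(0.0, spec.jitter_xy)
                y = (j + 0.5) * sy + rng.normal(0.0, spec.jitter_xy)
                zp = spec.midplane_z + sign * spec.leaflet_offset \
                    + rng.normal(0.0, spec.jitter_z)
                records.append(("P", spec.resname, resid))
                coords.append((x, y, zp))
                for k, dz in enumerate((0.5, 1.0), start=1):
                    records.append((f"C{k}", spec.resname, resid))
                    coords.append((x, y, zp - sign * dz))
                leaflets[resid - 1] = leaflet   # molecule_id is 0-based
    topology = Topology.from_records(records)
    frame = Frame(np.array(coords), np.array(spec.box), time=0.0)
    ground_truth = {"midplane_z": spec.midplane_z, "leaflets": leaflets}
    return topology, frame, ground_truth


# -------------------------------------------------- circular torsion sampling

@dataclass
class VonMisesMixture:
    """Three-component circular mixture over [0, 360) degrees.

    Defaults plant the omega-rotamer conditions used throughout: gg/gt/tg
    basins at 300/60/180 degrees with weights 0.70/0.25/0.05 and
    concentration kappa = 20.
    """

    centers: tuple[float, ...] = (300.0, 60.0, 180.0)
    kappas: tuple[float, ...] = (20.0, 20.0, 20.0)
    weights: tuple[float, ...] = (0.70, 0.25, 0.05)

    def __post_init__(self):
        if not (len(self.centers) == len(self.kappas) == len(self.weights)):
            raise SyntheticError("mixture component lists differ in length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise SyntheticError("mixture weights must sum to 1")
        if any(k <= 0 for k in self.kappas):
            raise SyntheticError("kappa must be positive")

    def pdf(self, theta_deg: np.ndarray) -> np.ndarray:
        """Unnormalised mixture density on [0, 360)."""
        t = np.radians(np.asarray(theta_deg, dtype=float))
        out = np.zeros_like(t)
        for mu, kappa, w in zip(self.centers, self.kappas, self.weights):
            from scipy.special import i0
            out += w * np.exp(kappa * np.cos(t - np.radians(mu))) / \
                (2 * np.pi * i0(kappa))
        return out


#: grid resolution for inverse-CDF circular sampling (points over 360 deg)
_CDF_GRID = 36001


def sample_dihedral_series(mixture: VonMisesMixture, n: int,
                           seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. angles (degrees in [0, 360)) from the mixture.

    Sampling is inverse-CDF on a fine fixed grid, so a given seed
    reproduces the identical series on any platform.
    """
    grid = np.linspace(0.0, 360.0, _CDF_GRID)
    pdf = mixture.pdf(grid)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    u = _rng(seed).random(n)
    return np.mod(np.interp(u, cdf, grid), 360.0)


# -------------------------------------------------------- pseudo-glycan NeRF

@dataclass
class ZAtom:
    """One internal-coordinate entry of a pseudo-molecule template.

    ``torsion`` is either a fixed value in degrees, or a tuple
    ``(linkage_name, angle_name)`` marking a settable glycosidic torsion.
    Settable torsions enter the chain in reversed quadruple order, so the
    z-matrix torsion is the negative of the assigned angle; the builder
    handles the sign.
    """

    name: str
    resname: str
    resid: int
    refs: tuple[int, int, int] | None   # (a, b, c) indices; None = seed atom
    bond: float = 0.15                  # nm, c-self
    angle: float = 109.47               # degrees, b-c-self
    torsion: float | tuple[str, str] = 180.0


@dataclass
class GlycanTemplate:
    atoms: list[ZAtom]
    linkages: list[LinkageSpec]

    @property
    def settable(self) -> list[tuple[str, str]]:
        return [a.torsion for a in self.atoms if isinstance(a.torsion, tuple)]

    def topology(self) -> Topology:
        return Topology.from_records(
            [(a.name, a.resname, a.resid) for a in self.atoms])


def gpi_core_template() -> GlycanTemplate:
    """Pseudo-glycan for the conserved glycolipid core.

    Residues PGL-Ino-GlcN-Man1-Man2-Man3 as a bonded pseudo-chain whose
    atom names realise the torsion quadruples of the four core linkages
    (phi/psi everywhere, omega on Man2-a16-Man1) plus the tilt endpoints
    Ino C6 and Man3 C4. Bond lengths/angles are idealised; only the named
    glycosidic torsions are settable.
    """
    # coarse pseudo-bond lengths: each bead stands for a few heavy atoms,
    # so the chain spans roughly the extent of the real hexasaccharide
    CC, CO = 0.24, 0.22
    A = 109.47
    atoms = [
        ZAtom("C1", "PGL", 1, None),
        ZAtom("C2", "PGL", 1, None),
        ZAtom("C3", "PGL", 1, None),
        ZAtom("P", "PGL", 1, (0, 1, 2), CO, A, 180.0),
        ZAtom("C4", "Ino", 2, (1, 2, 3), CO, A, 160.0),
        ZAtom("C5", "Ino", 2, (2, 3, 4), CC, A, 200.0),
        ZAtom("C6", "Ino", 2, (3, 4, 5), CC, A, 180.0),
        ZAtom("O6", "Ino", 2, (4, 5, 6), CO, A, 170.0),
        ZAtom("C1", "GlcN", 3, (5, 6, 7), CO, A, ("GlcN-a16-Ino", "psi")),
        ZAtom("C2", "GlcN", 3, (6, 7, 8), CC, A, ("GlcN-a16-Ino", "phi")),
        ZAtom("C5", "GlcN", 3, (7, 8, 9), CC, A, 190.0),
        ZAtom("C4", "GlcN", 3, (8, 9, 10), CC, A, 170.0),
        ZAtom("O4", "GlcN", 3, (9, 10, 11), CO, A, 180.0),
        ZAtom("C1", "Man1", 4, (10, 11, 12), CO, A, ("Man1-a14-GlcN", "psi")),
        ZAtom("C2", "Man1", 4, (11, 12, 13), CC, A, ("Man1-a14-GlcN", "phi")),
        ZAtom("O5", "Man1", 4, (12, 13, 14), CO, A, 200.0),
        ZAtom("C5", "Man1", 4, (13, 14, 15), CO, A, 170.0),
        ZAtom("C6", "Man1", 4, (14, 15, 16), CC, A, 185.0),
        ZAtom("O6", "Man1", 4, (15, 16, 17), CO, A, ("Man2-a16-Man1", "omega")),
        ZAtom("C1", "Man2", 5, (16, 17, 18), CO, A, ("Man2-a16-Man1", "psi")),
        ZAtom("C2", "Man2", 5, (17, 18, 19), CC, A, ("Man2-a16-Man1", "phi")),
        ZAtom("C3", "Man2", 5, (18, 19, 20), CC, A, 175.0),
        ZAtom("O2", "Man2", 5, (19, 21, 20), CO, A, 60.0),
        ZAtom("C1", "Man3", 6, (21, 20, 22), CO, A, ("Man3-a12-Man2", "psi")),
        ZAtom("C2", "Man3", 6, (20, 22, 23), CC, A, ("Man3-a12-Man2", "phi")),
        ZAtom("C4", "Man3", 6, (22, 23, 24), CC, A, 165.0),
    ]
    from .torsions import load_linkage_library
    linkages = load_linkage_library()["gpi0"]
    return GlycanTemplate(atoms=atoms, linkages=linkages)


def _nerf_place(A, B, C, bond, angle_deg, torsion_deg):
    """Place D with |CD| = bond, angle(B,C,D) and dihedral(A,B,C,D) as
    given (degrees). Vectorised over leading axes."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    b2 = C - B
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    n = np.cross(B - A, b2)
    nu = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(nu, b2u)
    bond = np.broadcast_to(np.asarray(bond, dtype=float), theta.shape) \
        if np.ndim(theta) else bond
    d = (-np.cos(theta))[..., None] * b2u \
        + (np.sin(theta) * np.cos(chi))[..., None] * m \
        + (np.sin(theta) * np.sin(chi))[..., None] * nu
    return C + np.asarray(bond)[..., None] * d


def build_glycan_conformers(template: GlycanTemplate,
                            assignments: Mapping[str, Mapping[str, np.ndarray]],
                            box: Sequence[float] = (6.0, 6.0, 6.0),
                            time_step: float = 1.0) -> Trajectory:
    """Build one frame per assignment row, with the named glycosidic
    torsions set exactly to the assigned values (degrees).

    ``assignments`` maps linkage name -> {angle name -> (n,) array}. All
    settable torsions of the template must be assigned, with equal
    lengths. Heavy-atom internal coordinates are otherwise rigid, so two
    frames with identical assignments are identical.
    """
    needed = template.settable
    n = None
    for link, angle in needed:
        try:
            vals = np.asarray(assignments[link][angle], dtype=float)
        except KeyError:
            raise SyntheticError(
                f"missing assignment for torsion {angle} of {link}") from None
        if n is None:
            n = len(vals)
        elif len(vals) != n:
            raise SyntheticError("assignment series lengths differ")
    if n is None or n == 0:
        raise SyntheticError("no conformers requested")
    natoms = len(template.atoms)
    pos = np.empty((n, natoms, 3))
    center = np.asarray(box, dtype=float) / 2.0
    for k, za in enumerate(template.atoms):
        if za.refs is None:
            if k == 0:
                pos[:, 0] = center
            elif k == 1:
                pos[:, 1] = center + np.array([za.bond, 0.0, 0.0])
            elif k == 2:
                theta = np.radians(za.angle)
                pos[:, 2] = pos[:, 1] + za.bond * np.array(
                    [-np.cos(theta), np.sin(theta), 0.0])
            else:
                raise SyntheticError("only the first 3 atoms may be seeds")
            continue
        a, b, c = za.refs
        if isinstance(za.torsion, tuple):
            link, angle_name = za.torsion
            # the NeRF frame places D with dihedral(A,B,C,D) = chi under
            # the IUPAC convention, and the signed dihedral is invariant
            # under quadruple reversal, so the assignment passes through
            chi = np.mod(np.asarray(assignments[link][angle_name], float),
                         360.0)
        else:
            chi = np.full(n, float(za.torsion))
        pos[:, k] = _nerf_place(pos[:, a], pos[:, b], pos[:, c],
                                za.bond, np.full(n, za.angle), chi)
    topology = template.topology()
    frames = [Frame(pos[i], np.asarray(box, float), time=i * time_step)
              for i in range(n)]
    return Trajectory(topology, frames, dt=time_step)


# ------------------------------------------------------------------- waters

def place_waters(topology: Topology, frame: Frame,
                 hydration_targets: Mapping[int, int],
                 total_waters: int, seed: int,
                 cutoff: float = 0.3, exclusion: float = 0.4,
                 max_tries: int = 20000):
    """Append water oxygens realising exact per-residue hydration counts.

    For each ``residue_id -> k`` target, exactly ``k`` oxygens are placed
    within ``cutoff`` (minimum image) of that residue's atoms and farther
    than ``cutoff`` from every other residue; remaining oxygens (up to
    ``total_waters``) are placed at least ``exclusion`` from all solute
    atoms. Raises :class:`SyntheticError` when packing is infeasible.

    Returns ``(topology, frame)`` including the waters.
    """
    rng = _rng(seed)
    box = frame.box
    solute_n = topology.n_atoms
    n_targeted = sum(hydration_targets.values())
    if n_targeted > total_waters:
        raise SyntheticError("hydration targets exceed the total water count")
    resids = topology.residue_ids
    coords = frame.coordinates
    placed: list[np.ndarray] = []

    def min_image_dist(p, pts):
        d = pts - p
        d -= box * np.ceil(d / box - 0.5)
        return np.sqrt(np.einsum("ij,ij->i", d, d))

    for rid, k in sorted(hydration_targets.items()):
        own = coords[resids == rid]
        others = coords[resids != rid]
        if own.size == 0:
            raise SyntheticError(f"residue id {rid} not in topology")
        for _ in range(k):
            for attempt in range(max_tries):
                anchor = own[rng.integers(len(own))]
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                r = rng.uniform(0.75 * cutoff, 0.97 * cutoff)
                p = np.mod(anchor + r * v, box)
                if min_image_dist(p, own).min() > cutoff:
                    continue
                if others.size and min_image_dist(p, others).min() <= cutoff * 1.05:
                    continue
                if placed and min_image_dist(p, np.array(placed)).min() < 0.05:
                    continue
                placed.append(p)
                break
            else:
                raise SyntheticError(
                    f"infeasible packing: cannot hydrate residue {rid}")
    for _ in range(total_waters - n_targeted):
        for attempt in range(max_tries):
            p = rng.uniform(0.0, 1.0, size=3) * box
            if min_image_dist(p, coords).min() < exclusion * 1.05:
                continue
            if placed and min_image_dist(p, np.array(placed)).min() < 0.05:
                continue
            placed.append(p)
            break
        else:
            raise SyntheticError("infeasible packing: box too crowded for water")
    records = [(a.name, a.residue_name, a.residue_id) for a in topology.atoms]
    next_rid = int(resids.max()) + 1 if solute_n else 1
    for w, p in enumerate(placed):
        records.append(("OW", "SOL", next_rid + w))
    new_top = Topology.from_records(records)
    new_coords = np.vstack([coords] + [np.array(placed)]) if placed \
        else coords.copy()
    return new_top, Frame(new_coords, box, time=frame.time)


# --------------------------------------------------------- cluster ensembles

def random_templates(k: int, n_atoms: int, spread: float, seed: int) -> np.ndarray:
    """K random rigid templates, each a cloud of points with pairwise
    (superposed) RMSD pushed apart by ``spread`` (nm)."""
    rng = _rng(seed)
    return rng.normal(scale=spread, size=(k, n_atoms, 3))


def generate_clustered_ensemble(templates: np.ndarray, sigma: float,
                                counts: Sequence[int], seed: int,
                                cutoff: float = 0.3,
                                fit_indices=None, measure_indices=None):
    """Perturbed copies of K templates with known membership.

    Preconditions enforced: every pair of templates must differ by more
    than ``2 * cutoff`` RMSD (over the measure set, after superposition
    on the fit set) and ``sigma < cutoff / 6``, otherwise ground truth
    would be ambiguous and a :class:`SyntheticError` is raised.

    Returns ``(ensemble, labels)`` with ``ensemble`` an (n, n_atoms, 3)
    array and ``labels`` the planted template index per structure.
    """
    templates = np.asarray(templates, dtype=float)
    k, n_atoms, _ = templates.shape
    if len(counts) != k:
        raise SyntheticError("one count per template required")
    if sigma < 0:
        raise SyntheticError("sigma must be non-negative")
    if sigma >= cutoff / 6.0:
        raise SyntheticError(f"sigma {sigma} too large for cutoff {cutoff}")
    if k > 1:
        fit = fit_indices if fit_indices is not None else np.arange(n_atoms)
        dmat = pairwise_rmsd_matrix(templates, fit, measure_indices)
        off = dmat[np.triu_indices(k, 1)]
        if off.min() <= 2.0 * cutoff:
            raise SyntheticError(
                f"templates too close (min RMSD {off.min():.3f} nm <= "
                f"2 x cutoff {cutoff} nm): membership would be ambiguous")
    rng = _rng(seed)
    ensemble = np.empty((int(sum(counts)), n_atoms, 3))
    labels = np.empty(int(sum(counts)), dtype=int)
    pos = 0
    for t, c in enumerate(counts):
        noise = rng.normal(scale=sigma, size=(int(c), n_atoms, 3)) if sigma > 0 \
            else 0.0
        ensemble[pos:pos + int(c)] = templates[t][None] + noise
        labels[pos:pos + int(c)] = t
        pos += int(c)
    return ensemble, labels


# ------------------------------------------------------------ tilt processes

@dataclass
class TiltProcess:
    """Stationary AR(1) angle process in degrees."""

    mean: float = 80.0
    sd: float = 10.0
    rho: float = 0.5     # lag-1 autocorrelation

    def sample(self, n: int, seed: int) -> np.ndarray:
        if not (0.0 < self.mean < 180.0):
            raise SyntheticError("mean tilt must lie in (0, 180)")
        if not (-1.0 < self.rho < 1.0):
            raise SyntheticError("AR(1) rho must lie in (-1, 1)")
        if self.mean - 3 * self.sd <= 0 or self.mean + 3 * self.sd >= 180:
            raise SyntheticError(
                "sd too large: process would hit the [0, 180] boundary")
        rng = _rng(seed)
        eps = rng.normal(size=n)
        out = np.empty(n)
        out[0] = self.mean + self.sd * eps[0]
        innov_sd = self.sd * np.sqrt(1.0 - self.rho ** 2)
        for t in range(1, n):
            out[t] = self.mean + self.rho * (out[t - 1] - self.mean) \
                + innov_sd * eps[t]
        return np.clip(out, 1e-6, 180.0 - 1e-6)


def generate_tilt_trajectory(process: TiltProcess, n_frames: int, seed: int,
                             n_rod_atoms: int = 5, rod_length: float = 2.0,
                             box: Sequence[float] = (6.0, 6.0, 12.0),
                             leaflet_sign: int = 1):
    """A rigid rod re-oriented each frame to the planted tilt process.

    The rod's tail->head vector makes exactly the drawn angle with
    ``leaflet_sign * z`` each frame (azimuth drawn uniformly; it does not
    affect the tilt). Returns ``(Trajectory, true_angles_deg)``.
    """
    angles = process.sample(n_frames, seed)
    rng = _rng(seed + 1)
    azimuth = rng.uniform(0.0, 2 * np.pi, size=n_frames)
    box = np.asarray(box, dtype=float)
    records = [(f"R{i + 1}", "ROD", 1) for i in range(n_rod_atoms)]
    topology = Topology.from_records(records)
    spacing = rod_length / (n_rod_atoms - 1)
    base = box / 2.0
    frames = []
    theta = np.radians(angles)
    for t in range(n_frames):
        u = np.array([np.sin(theta[t]) * np.cos(azimuth[t]),
                      np.sin(theta[t]) * np.sin(azimuth[t]),
                      leaflet_sign * np.cos(theta[t])])
        coords = base[None, :] + spacing * np.arange(n_rod_atoms)[:, None] * u
        frames.append(Frame(coords, box, time=float(t)))
    return Trajectory(topology, frames, dt=1.0), angles
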