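"""Tilt-angle observables for membrane-anchored molecules.

A tilt angle is the angle between a molecule-fixed position vector (tail
atom -> head atom, taken under the minimum image convention) and the
bilayer normal, which is the box z-axis. Three named observables are used
for anchored glycolipids and their carrier protein:

* ``theta_z`` — glycan-core tilt, inositol C6 to Man3 C4;
* ``zeta_z``  — side-branch tilt, inositol C6 to the terminal Glc/Gal C4;
* ``chi_z``   — protein-barrel tilt, e.g. the CA atoms of GLN76 and HIE135
  of GFP.

Molecules in the bottom leaflet are measured against the -z normal
(``leaflet_sign = -1``) so both leaflets share one convention and can be
pooled; a tilt near 90 degrees is the "flopped-down" limit in either case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, minimum_image_displacement
from .selections import select_one
from .system import Frame, Topology, Trajectory


@dataclass
class TiltSpec:
    """Definition of one tilt observable.

    ``selector_a`` / ``selector_b`` are selection expressions that must
    each resolve to exactly one atom (tail end, head end).
    """

    label: str                 # e.g. "theta_z", "zeta_z", "chi_z", or custom
    selector_a: str
    selector_b: str
    leaflet_sign: int = 1      # +1 top leaflet, -1 bottom

    def resolve(self, topology: Topology) -> tuple[int, int]:
        return (select_one(topology, self.selector_a),
                select_one(topology, self.selector_b))


@dataclass
class TiltSeries:
    spec: TiltSpec
    values: np.ndarray   # degrees per frame, in [0, 180]
    times: np.ndarray    # ps

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times,
                             "angle_deg": self.values})


def tilt_angle(frame: Frame, spec: TiltSpec, topology: Topology,
               _resolved: tuple[int, int] | None = None) -> float:
    """Tilt of the a->b vector against ``leaflet_sign * z``, in [0, 180]."""
    ia, ib = spec.resolve(topology) if _resolved is None else _resolved
    d = minimum_image_displacement(frame.coordinates[ia],
                                   frame.coordinates[ib], frame.box)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise GeometryError(
            f"tilt endpoints coincide for {spec.label!r}")
    cosang = np.clip(spec.leaflet_sign * d[2] / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def tilt_series(traj: Trajectory, spec: TiltSpec) -> TiltSeries:
    """One tilt value per frame, in trajectory order."""
    resolved = spec.resolve(traj.topology)
    values = np.empty(traj.n_frames)
    times = np.empty(traj.n_frames)
    for k, frame in enumerate(traj):
        try:
            values[k] = tilt_angle(frame, spec, traj.topology,
                                   _resolved=resolved)
        except GeometryError as exc:
            raise GeometryError(f"frame {k}: {exc}") from exc
        times[k] = frame.time
    return TiltSeries(spec=spec, values=values, times=times)


def angle_distribution(series: TiltSeries | np.ndarray,
                       bin_width: float = 2.5) -> pd.DataFrame:
    """Normalised probability density of a tilt series over [0, 180].

    ``bin_width`` (degrees) must divide 180. The returned density
    satisfies ``sum(density) * bin_width == 1``.
    """
    values = series.values if isinstance(series, TiltSeries) else np.asarray(series)
    if values.size == 0:
        raise ValueError("empty tilt series")
    nbins = 180.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 180")
    edges = np.linspace(0.0, 180.0, int(round(nbins)) + 1)
    counts, edges = np.histogram(np.clip(values, 0.0, 180.0), bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "density": density})


# The paper-equivalent observables, expressed in the selection language.
CORE_TILT = TiltSpec("theta_z", "resname Ino and name C6",
                     "resname Man3 and name C4")
BRANCH_TILT = TiltSpec("zeta_z", "resname Ino and name C6",
                       "(resname Glc or resname Gal) and name C4")
PROTEIN_TILT = TiltSpec("chi_z", "resname GLN and resid 76 and name CA",
                        "resname HIE and resid 135 and name CA")
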