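"""Glycosidic torsions, Boltzmann-inversion free-energy surfaces and
omega-rotamer populations.

A glycosidic linkage between two sugar residues is parameterised by the
torsions phi(C2, C1, Ox', Cx') and psi(C1, Ox', Cx', Cy'); (1->6) linkages
carry the additional exocyclic torsion Omega(O6', C6', C5', O5') about the
C5'-C6' bond. Omega visits three staggered rotamers:

* ``gt``: [0, 120) degrees
* ``tg``: [120, 240)
* ``gg``: [240, 360)

(half-open, lower-inclusive windows; the boundary is a measure-zero set).

Free-energy surfaces are plain Boltzmann inversions of the empirical
two-dimensional torsion histogram, F = -kB * T * ln P, shifted so the
minimum over visited bins is zero; unvisited bins are masked, never set
to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import dihedral
from .selections import select_one
from .system import Topology, Trajectory

#: Boltzmann constant in kJ/(mol K).
KB_KJ_PER_MOL_K = 0.0083145

#: Default simulation temperature (K) for free-energy surfaces.
DEFAULT_TEMPERATURE = 303.0

LINKAGE_CLASSES = ("1->2", "1->3", "1->4", "1->6")


@dataclass
class LinkageSpec:
    """Atom quadruples defining one glycosidic linkage's torsions.

    Each quadruple is four selection expressions, each resolving to
    exactly one atom. ``omega_atoms`` must be present iff the linkage
    class is 1->6.
    """

    name: str
    linkage_class: str
    phi_atoms: tuple[str, str, str, str]
    psi_atoms: tuple[str, str, str, str]
    omega_atoms: tuple[str, str, str, str] | None = None

    def __post_init__(self):
        if self.linkage_class not in LINKAGE_CLASSES:
            raise ValueError(f"unknown linkage class {self.linkage_class!r}")
        if self.omega_atoms is not None and self.linkage_class != "1->6":
            raise ValueError(
                f"{self.name}: omega quadruple only defined for 1->6 linkages")
        # A 1->6 linkage normally carries omega; the exception is a
        # carbocyclic acceptor (inositol), whose 6-position is a ring
        # carbon with no exocyclic O5 ring oxygen, hence no omega.


@dataclass
class TorsionSeries:
    linkage: LinkageSpec
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None

    def __post_init__(self):
        if len(self.phi) != len(self.psi):
            raise ValueError("phi and psi series lengths differ")
        if self.omega is not None and len(self.omega) != len(self.phi):
            raise ValueError("omega series length differs")

    def __len__(self) -> int:
        return len(self.phi)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"phi_deg": self.phi, "psi_deg": self.psi}
        if self.omega is not None:
            data["omega_deg"] = self.omega
        return pd.DataFrame(data)


def _resolve_quad(topology: Topology, quad: Sequence[str],
                  linkage_name: str) -> list[int]:
    try:
        return [select_one(topology, s) for s in quad]
    except Exception as exc:
        raise ValueError(
            f"linkage {linkage_name!r}: cannot resolve quadruple "
            f"{tuple(quad)}: {exc}") from exc


def extract_torsions(traj: Trajectory, linkage: LinkageSpec) -> TorsionSeries:
    """Per-frame phi/psi(/omega) dihedrals for one linkage, in [0, 360).

    Consecutive atoms in each quadruple are bonded, so each displacement
    is taken under the minimum image convention; this unwraps quadruples
    that straddle the periodic boundary without needing a bond graph.
    """
    quads = {"phi": _resolve_quad(traj.topology, linkage.phi_atoms, linkage.name),
             "psi": _resolve_quad(traj.topology, linkage.psi_atoms, linkage.name)}
    if linkage.omega_atoms is not None:
        quads["omega"] = _resolve_quad(traj.topology, linkage.omega_atoms,
                                       linkage.name)
    coords = traj.coordinate_array()
    boxes = np.stack([f.box for f in traj])
    out = {}
    for key, (i, j, k, l) in quads.items():
        out[key] = dihedral(coords[:, i], coords[:, j], coords[:, k],
                            coords[:, l], box=boxes)
    return TorsionSeries(linkage=linkage, phi=out["phi"], psi=out["psi"],
                         omega=out.get("omega"))


@dataclass
class FreeEnergySurface:
    """Boltzmann-inverted 2-D torsion landscape in kJ/mol.

    ``values`` is a masked array: masked entries are bins never visited by
    the sampling (their free energy is unknown, not zero). The minimum
    over visited bins is shifted to zero.
    """

    x_label: str
    y_label: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ma.MaskedArray   # kJ/mol
    counts: np.ndarray
    temperature: float          # K
    kB: float = KB_KJ_PER_MOL_K

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_dataframe(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xs, ys = np.meshgrid(xc, yc, indexing="ij")
        vals = self.values.filled(np.nan)
        return pd.DataFrame({self.x_label: xs.ravel(),
                             self.y_label: ys.ravel(),
                             "free_energy_kJ_mol": vals.ravel(),
                             "count": self.counts.ravel()})


def free_energy_surface(x: np.ndarray, y: np.ndarray, bin_width: float = 5.0,
                        temperature: float = DEFAULT_TEMPERATURE,
                        x_label: str = "phi_deg",
                        y_label: str = "psi_deg") -> FreeEnergySurface:
    """F(x, y) = -kB T ln P(x, y) from the periodic 2-D angle histogram.

    Angles are taken modulo 360; ``bin_width`` (degrees) must divide 360.
    F is invariant under any positive rescaling of the counts, and
    exp(-F / kB T) renormalised over visited bins reproduces P.
    """
    x = np.mod(np.asarray(x, dtype=float), 360.0)
    y = np.mod(np.asarray(y, dtype=float), 360.0)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty angle series")
    if x.shape != y.shape:
        raise ValueError("angle series lengths differ")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    nbins = 360.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 360")
    edges = np.linspace(0.0, 360.0, int(round(nbins)) + 1)
    counts, xe, ye = np.histogram2d(x, y, bins=(edges, edges))
    p = counts / counts.sum()
    mask = counts == 0
    logp = np.log(np.where(mask, 1.0, p))
    f = np.where(mask, 0.0, -KB_KJ_PER_MOL_K * temperature * logp)
    fm = np.ma.MaskedArray(f, mask=mask)
    fm = fm - fm.min()
    return FreeEnergySurface(x_label=x_label, y_label=y_label, x_edges=xe,
                             y_edges=ye, values=fm, counts=counts,
                             temperature=temperature)


ROTAMER_STATES = ("gg", "gt", "tg")


def classify_rotamer(omega) -> np.ndarray | str:
    """Classify omega (degrees in [0, 360)) into gg/gt/tg.

    Windows are half-open and lower-inclusive: gt [0,120), tg [120,240),
    gg [240,360). Scalar in, scalar out; array in, array out.
    """
    arr = np.mod(np.asarray(omega, dtype=float), 360.0)
    labels = np.where(arr < 120.0, "gt", np.where(arr < 240.0, "tg", "gg"))
    if np.isscalar(omega) or getattr(omega, "shape", None) == ():
        return str(labels)
    return labels


def rotamer_populations(series: TorsionSeries | np.ndarray) -> dict[str, float]:
    """Percentage of frames in each omega rotamer; sums to 100."""
    omega = series.omega if isinstance(series, TorsionSeries) else np.asarray(series)
    if omega is None or len(omega) == 0:
        raise ValueError("empty omega series: linkage has no 1->6 torsion?")
    labels = classify_rotamer(omega)
    n = len(labels)
    return {state: 100.0 * float(np.sum(labels == state)) / n
            for state in ROTAMER_STATES}


def rotamer_table(rows: dict[str, dict[str, float]],
                  decimals: int = 1) -> pd.DataFrame:
    """Assemble per-linkage/condition rotamer populations into a table.

    ``rows`` maps a row label (e.g. "Man2-a16-Man1 / DMPC") to the dict
    returned by :func:`rotamer_populations`.
    """
    df = pd.DataFrame.from_dict(rows, orient="index")[list(ROTAMER_STATES)]
    return df.round(decimals)


def load_linkage_library(path=None) -> dict[str, list[LinkageSpec]]:
    """Load the shipped (user-editable) glycosidic-linkage library.

    The library enumerates, per glycolipid variant, each linkage's class
    and the residue/atom names of its torsion quadruples. Returns a map
    variant name -> list of LinkageSpec.
    """
    if path is None:
        src = resources.files("gpianchor").joinpath("data/linkages.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    library: dict[str, list[LinkageSpec]] = {}
    for variant, entries in raw["variants"].items():
        specs = []
        for e in entries:
            specs.append(LinkageSpec(
                name=e["name"], linkage_class=e["class"],
                phi_atoms=tuple(e["phi"]), psi_atoms=tuple(e["psi"]),
                omega_atoms=tuple(e["omega"]) if "omega" in e else None))
        library[variant] = specs
    return library
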