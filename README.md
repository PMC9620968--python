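# gpianchor

Conformational analysis of membrane-anchored glycolipids and their
carrier proteins, for structural bioinformaticians working with
molecular-dynamics trajectories of GPI
(glycosylphosphatidylinositol)-containing bilayers.

GPI anchors tether proteins to the outer leaflet of cell membranes
through a conserved glycan core (Man3–Man2–Man1–GlcN–inositol on a lipid
tail). Whether the glycan stands upright or flops down onto the membrane
surface, and how its side branches meet water and the attached protein,
are questions answered from trajectories via a standard battery of
geometric observables. This package implements that battery as a tested,
reusable library:

* **Tilt angles** — the angle between a molecule-fixed vector (e.g.
  inositol C6 → Man3 C4 for the glycan core, θ_z) and the bilayer normal
  (box z-axis), per frame and as normalised distributions; bottom-leaflet
  molecules are measured against −z so both leaflets pool.
* **Glycosidic torsion landscapes** — φ(C2, C1, Ox′, Cx′),
  ψ(C1, Ox′, Cx′, Cy′) and, for 1→6 linkages, Ω(O6′, C6′, C5′, O5′),
  binned into Ramachandran-like surfaces by Boltzmann inversion,
  F = −k_B·T·ln P, with unvisited bins masked and the minimum shifted
  to 0 (T = 303 K by default).
* **Rotamer populations** — Ω classified into gt [0°, 120°),
  tg [120°, 240°), gg [240°, 360°) and tabulated as percentages.
* **Solvation statistics** — hydrogen bonds against a geometric
  criterion (donor–acceptor ≤ 0.35 nm, H–donor–acceptor ≤ 30°),
  hydration numbers (water oxygens within 0.3 nm of any residue atom),
  and residue depth profiles relative to the leaflet phosphate plane.
* **Contact maps** — the fraction of frames in which two residues have
  any atom pair within 0.5 nm, plus per-atom contact frequencies
  exportable into the PDB B-factor column for structure colouring.
* **Conformational clustering** — the neighbour-count (GROMOS/Daura)
  algorithm on a pairwise superposed-RMSD matrix at a 0.3 nm cutoff,
  with center extraction, minimum-membership filtering ("more than 40
  members") and size distributions.

Because μs-scale membrane trajectories are expensive and rarely
deposited, the package ships a first-class **synthetic-system
generator**: pseudo-bilayers with planted mid-planes, pseudo-glycans
whose torsions are set exactly by internal-coordinate construction,
circular (von Mises) torsion mixtures with prescribed rotamer weights,
water shells with exact hydration counts, conformer ensembles with
planted cluster membership, and rigid rods following prescribed AR(1)
tilt processes. Every analysis stage is validated against this planted
ground truth.

## Worked example

```python
import numpy as np
from gpianchor import (VonMisesMixture, build_glycan_conformers,
                       extract_torsions, gpi_core_template,
                       rotamer_populations, sample_dihedral_series)

n = 20000
tpl = gpi_core_template()
assign = {}
for link, ang in tpl.settable:
    assign.setdefault(link, {})[ang] = np.full(n, 180.0)
assign["Man2-a16-Man1"]["omega"] = sample_dihedral_series(
    VonMisesMixture(weights=(0.70, 0.25, 0.05)), n, seed=7)

traj = build_glycan_conformers(tpl, assign)
link = next(l for l in tpl.linkages if l.name == "Man2-a16-Man1")
print(rotamer_populations(extract_torsions(traj, link)))
```

prints

```
{'gg': 70.0, 'gt': 24.8, 'tg': 5.2}
```

— the planted 70/25/5 rotamer mixture of the flexible Man2-α(1→6)-Man1
linkage, recovered purely from conformer coordinates (sampling noise of
a few tenths of a percent at n = 20,000). The `examples/` directory has
one short script per capability (tilt distributions, free-energy
surfaces, hydration and H-bonds, contact maps, clustering, and the full
pipeline); each prints the numbers it computes and what they mean.

## Command line

The analysis battery also runs from a shell, driven by a YAML/JSON
config (see `examples/synthetic_config.yaml`):

```bash
gpianchor analyze all --config examples/synthetic_config.yaml --out out/
gpianchor analyze tilt --config my_run.yaml --out out/ --seed 3
gpianchor validate --config my_run.yaml
gpianchor synth --spec examples/synthetic_config.yaml --out synth/
```

Outputs are CSV/JSON plus a `manifest.json` recording the config hash,
package version, per-stage status and every documented assumption; the
same config and seed reproduce every CSV byte for byte.

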