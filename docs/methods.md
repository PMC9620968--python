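# Methods

This note documents the models, conventions, numerical choices and
limitations behind `gpianchor`. It is written for users who need to know
exactly what the numbers mean, and for maintainers who need to know why
each open design question was settled the way it was.

## Coordinate model and conventions

Lengths are nanometres everywhere inside the package; PDB Ångström are
converted at the I/O boundary. Atom indices are 0-based internally,
residue ids 1-based as in source files. Only orthorhombic boxes are
supported — the membrane systems this package targets are rectangular
patches — and triclinic input raises an explicit error rather than being
silently mis-wrapped.

Minimum-image displacements are computed per component as
`d − L·ceil(d/L − 1/2)`, which places each component in (−L/2, L/2]. The
tests verify agreement with an exhaustive 27-image search for points in
the box.

Dihedrals follow the IUPAC sign convention (verified against MDAnalysis
to single precision) and are reported in [0°, 360°), the natural range
for rotamer work. The signed dihedral is invariant under reversing the
atom quadruple; this is asserted as a property test. When a box is
supplied, consecutive displacements within the quadruple are taken under
the minimum image convention, which unwraps bonded quadruples straddling
a boundary without needing a bond graph; a bond-graph `make_whole` is
also provided for callers that have explicit connectivity.

Superposition uses the Kabsch algorithm with reflections excluded
(proper rotation, det = +1). RMSDs are non-mass-weighted by default —
the weighting a trajectory tool uses is rarely reported, so the package
defaults to the simplest convention and exposes `weights` for callers
who need mass-weighted fits. Fit sets must contain at least three
non-collinear atoms; violations raise instead of returning a degenerate
fit.

## Membrane reference frame

The bilayer normal is fixed to the box z-axis rather than fitted per
frame: the target systems are planar patches assembled along z, and a
fitted normal would add noise without adding information. The mid-plane
is the mean z of the headgroup phosphorus atoms after unwrapping across
the z boundary (the unwrap is anchored at the first phosphorus, so the
two phosphate planes must lie within half a box length of each other —
true for any sensibly solvated bilayer). Lipids are assigned to the top
leaflet iff their phosphorus sits above the mid-plane; an exact tie goes
to the top leaflet with a logged warning, so assignment is deterministic.

Depth profiles report the signed z-distance of a residue centroid from
the phosphate plane of **its own leaflet**, positive toward the solvent.
Measuring from the per-leaflet phosphate plane (rather than the
mid-plane or a headgroup centroid) was chosen because insertion depth is
discussed relative to the headgroup region; the reference is a config
choice for users who want another convention.

## Tilt observables

A tilt spec names two single-atom selections (tail, head); the observable
is the angle between their minimum-image displacement and
`leaflet_sign · ẑ`, in [0°, 180°]. Bottom-leaflet molecules use
`leaflet_sign = −1` so that both leaflets share one convention and can
be pooled — flipping the sign maps α to 180° − α exactly, which is
asserted in the tests. Angular distributions default to 2.5° bins: fine
enough to resolve peaks in the 70–80° ("flopped-down") region without
starving bins at realistic frame counts. The protein-barrel tilt spec
defaults to the α-carbons of the two anchor residues, since only the
residues, not the atoms, are conventionally specified.

## Torsions, free-energy surfaces, rotamers

Glycosidic torsions are φ(C2, C1, Ox′, Cx′), ψ(C1, Ox′, Cx′, Cy′) and,
for 1→6 linkages, Ω(O6′, C6′, C5′, O5′). The shipped linkage library
(`src/gpianchor/data/linkages.yaml`) encodes these quadruples per
glycolipid variant with Cy′ = C(x+1) (C5 for 1→6); the file is data, not
code, and is meant to be edited to match a force field's atom naming.
One chemical subtlety: a 1→6 attachment onto myo-inositol has no Ω
torsion because inositol is a carbocycle without the O5 ring oxygen, so
that linkage carries φ/ψ only.

Free-energy surfaces are plain Boltzmann inversions of the empirical
2-D periodic histogram: F = −k_B·T·ln P with k_B = 0.0083145 kJ/(mol·K)
and T defaulting to 303 K (the bilayer-fluid-phase temperature the
target simulations use). Bins never visited are **masked**, not set to
zero: an unvisited bin has unknown, not zero, free energy, and a
pseudo-count would fabricate data support. The minimum over visited bins
is shifted to 0. Default bin width is 5° (72×72 grids); F is invariant
under rescaling the counts, and exp(−F/k_B T) renormalised over visited
bins reproduces P to machine precision (both tested).

Ω rotamers use half-open, lower-inclusive windows gt [0°, 120°),
tg [120°, 240°), gg [240°, 360°). Open windows would leave the boundary
points unassigned; the half-open convention is deterministic and the
boundary set has measure zero. Populations are reported as percentages
summing to 100.

## Solvation and contacts

All distance criteria are inclusive (≤) at the boundary — "within a
radius r" includes r — and every distance is a minimum-image distance.

The hydrogen-bond criterion defaults to donor–acceptor ≤ 0.35 nm with
H–donor–acceptor angle ≤ 30°, the de-facto geometric standard of the
major MD analysis tools; it is configurable because published analyses
rarely state their exact criterion. Donor→hydrogen connectivity is
supplied explicitly (the package does not parse force-field topologies);
a donor without a declared hydrogen is an error, not a silent skip.
Intra-residue pairs are excluded. The "lipid headgroup region" is
defined by a shipped, user-editable atom-name list (phosphate + choline
+ glycerol-ester oxygens).

Hydration number counts water **oxygens** within 0.3 nm of any atom of a
residue, each oxygen once. Contact maps report, per residue pair, the
fraction of frames with at least one inter-atomic distance ≤ 0.5 nm;
per-atom contact frequencies are the same quantity per target atom, and
can be written into the PDB B-factor column for structure colouring.

Neighbour searches use a periodic KD-tree only to pre-select candidate
pairs with a slightly inflated radius; every candidate is then confirmed
with the same minimum-image arithmetic the definition uses. The
acceleration therefore cannot change any result, and the tests assert
exact equality with O(N²) brute-force evaluation, including planted
boundary separations at exactly 0.3/0.35/0.5 nm.

## Clustering

The neighbour-count algorithm: from the pool of unassigned structures,
the one with the most unassigned neighbours within the RMSD cutoff
(itself included, since its self-distance 0 ≤ cutoff) becomes a center;
it and its neighbours are removed; repeat until the pool is empty. Ties
in the neighbour count go to the lowest structure index, making the
procedure fully deterministic; the implementation is asserted equal to
an independently coded brute-force version on random matrices.

The RMSD matrix superposes each structure pair on a fit set (defaulting
to the rigid base residues GlcN–Ino–PGL of an anchored glycan) and
measures RMSD over a separate measure set (defaulting to all glycan
heavy atoms); both are configurable, since published cluster analyses
rarely state their exact fit/measure sets or hydrogen handling. The
default cutoff is 0.3 nm — looser than the ~0.1 nm customary for
proteins, because carbohydrate ensembles are far more diffuse.
Reporting keeps clusters with **strictly more than** `min_members`
members (the "more than 40 members" rule; 40 for free glycolipids, 30
for protein-anchored ones, both config values), while the total
structure count is retained so size distributions stay normalised.
Ensembles can be subsampled by uniform stride to the customary 5,000
(free) or 2,500 (protein-bound) structures.

## Synthetic systems and what they do (not) show

Each generator plants the ground truth its consumer analysis recovers:

* **Bilayer lattice** — two leaflets of pseudo-lipids (P head + two tail
  beads) on a jittered 8×8 lattice per leaflet, phosphate planes at
  ±1.75 nm about a planted mid-plane (z-noise σ = 0.05 nm). Recovery of
  the mid-plane to < 0.02 nm and of every leaflet label is tested.
* **Circular sampling** — torsions are drawn from three-component von
  Mises mixtures by inverse-CDF on a fixed 36,001-point grid, so a seed
  reproduces the identical series on any platform. The default mixture
  plants gg/gt/tg = 70/25/5 (%) with basins at 300°/60°/180° and
  κ = 20, the regime of a flexible 1→6 linkage.
* **Pseudo-glycan conformers** — a coarse bead chain
  (PGL–Ino–GlcN–Man1–Man2–Man3, bead spacing 0.22–0.24 nm so the chain
  spans roughly a real hexasaccharide's extent) built by NeRF
  internal-coordinate placement. The named glycosidic torsions are set
  exactly: measured-back dihedrals agree with assignments to ~1e-13°.
* **Water placement** — exact per-residue hydration targets: each
  targeted water sits within 0.3 nm of its residue and beyond 0.3 nm of
  every other; spares sit beyond 0.4 nm of all solute. Infeasible
  packings raise rather than silently under-delivering.
* **Cluster ensembles** — perturbed copies of K templates; the generator
  enforces its own validity conditions (pairwise template RMSD > 2×
  cutoff, σ < cutoff/6) and errors when ground truth would be ambiguous.
* **Tilt processes** — stationary AR(1) in angle (default mean 80°,
  sd 10°, lag-1 correlation ρ = 0.5 — a moderate persistence chosen once
  as representative of nanosecond-scale orientational memory). The rod
  is re-oriented so the measured tilt equals the drawn value to ~1e-9°.

These fixtures are geometrically faithful and statistically controlled,
but chemically simplified: no force-field energetics, no water
structure, no lipid dynamics, no protein internal motion. Passing tests
therefore demonstrate that the **analysis machinery** is correct —
extraction, binning, inversion, counting, clustering — not that any
particular real system behaves like the planted processes.

## Pipeline, determinism, problem sizes

The pipeline derives every stage's seed from the single config seed via
SHA-256, writes CSVs with fixed float formatting, and hashes the config
into the manifest, so identical config + seed ⇒ byte-identical outputs
(tested). In synthetic mode each stage generates its stage-matched
system and records a recovered-vs-planted check in the manifest; the
tilt check uses 4-standard-error AR(1) bounds at the configured frame
count, so it is an honest statistical test for any seed. The shipped
config runs 2,000 tilt frames, 20,000 torsion conformers, 500
solvation/depth frames and a 150-structure cluster ensemble — sizes
chosen so the full battery completes in seconds while keeping sampling
errors well inside the checked bounds; `scripts/acceptance.py` uses
5,000 tilt frames, 50,000 torsion samples and 10⁶ histogram samples, the
sizes at which the documented recovery tolerances (±1.5 percentage
points per rotamer class, 0.5° on the tilt mean, 0.05 kJ/mol on the
two-level free-energy gap) hold.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* The bilayer normal is never fitted; curved or undulating membranes
  are out of scope, as are lipid flip-flop detection and orientational
  order parameters/autocorrelation times.
* Hydrogen-bond analysis needs explicit donor–hydrogen lists; nothing
  is inferred from element patterns.
* Free-energy surfaces are plain inversions of unbiased sampling — no
  reweighting of biased (metadynamics/umbrella) data.
* The multi-frame GRO fixture format stores 0.001 nm coordinates;
  round-tripped angles inherit errors of order 0.01°.
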