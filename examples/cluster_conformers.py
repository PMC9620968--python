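"""Conformational clustering with the neighbour-count (GROMOS) algorithm.

Generates an ensemble from three well-separated glycan conformer
templates (distinct torsions at every linkage) with small intra-template
noise, computes the pairwise superposed-RMSD matrix, clusters at the
0.3 nm cutoff and applies the 'more than 40 members' reporting filter.
The planted membership is recovered perfectly.
"""

import numpy as np

from gpianchor import (build_glycan_conformers, cluster_size_distribution,
                       filter_clusters, generate_clustered_ensemble,
                       gpi_core_template, gromos_cluster,
                       pairwise_rmsd_matrix, select)

tpl = gpi_core_template()
top = tpl.topology()

omegas, psis, phis = (300.0, 60.0, 180.0), (120.0, 250.0, 10.0), \
    (75.0, 200.0, 320.0)
templates = []
for i in range(3):
    assign = {}
    for link, ang in tpl.settable:
        v = {"omega": omegas[i], "psi": psis[i], "phi": phis[i]}[ang]
        assign.setdefault(link, {})[ang] = np.array([v])
    templates.append(build_glycan_conformers(tpl, assign)[0].coordinates)

# superpose on the rigid base residues, measure RMSD over all atoms
fit = select(top, "resname GlcN or resname Ino or resname PGL")
measure = select(top, "all")
ensemble, labels = generate_clustered_ensemble(
    np.stack(templates), sigma=0.02, counts=(60, 50, 40), seed=5,
    cutoff=0.3, fit_indices=fit.indices, measure_indices=measure.indices)

matrix = pairwise_rmsd_matrix(ensemble, fit, measure)
result = gromos_cluster(matrix, cutoff=0.3)

print(cluster_size_distribution(result).to_string(index=False))
pure = all(len(set(labels[c.members])) == 1 for c in result.clusters)
print(f"planted membership recovered exactly: {pure}")

kept = filter_clusters(result, min_members=40)
print(f"clusters with more than 40 members: {len(kept.clusters)} "
      f"(sizes {kept.sizes}) out of {result.n_structures} structures")
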