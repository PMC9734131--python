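"""Pairwise-RMSD Ward clustering of a mixed conformational ensemble.

Mixes reference bundles of the two toy conformations, computes the
mobile-segment pairwise-RMSD matrix (after superposing on the rigid
core) and lets Ward clustering with automatic cluster-number selection
separate the states; also reports the per-residue RMSF profile.
"""

import numpy as np

from lidex.ensemble_geometry import (
    ConformerEnsemble,
    Selection,
    pairwise_rmsd_matrix,
    rmsf_profile,
    ward_cluster,
)
from lidex.synthetic_data import gen_reference_ensemble, gen_toy_system

system = gen_toy_system(seed=0)
ens_a = gen_reference_ensemble(system, "A", n_models=10, coord_noise=0.3, seed=1)
ens_b = gen_reference_ensemble(system, "B", n_models=10, coord_noise=0.3, seed=2)
mixed = ConformerEnsemble(system.atoms,
                          np.concatenate([ens_a.coords, ens_b.coords]))

n_core = len(system.core_resids)
fit = Selection(((1, n_core),), "backbone")
measure = Selection(((n_core + 1, n_core + len(system.mobile_resids)),),
                    "backbone")

mat = pairwise_rmsd_matrix(mixed, fit, measure)
print(f"pairwise RMSD over {mixed.n_models} models: "
      f"min {mat[mat > 0].min():.2f} A, max {mat.max():.2f} A")

res = ward_cluster(mat)
print(f"automatic cluster number: {res.n_clusters}")
for c in range(res.n_clusters):
    members = np.flatnonzero(res.labels == c)
    print(f"  cluster {c}: {len(members)} members, medoid model "
          f"{res.centroids[c]}, spread {res.spreads[c]:.2f} A")

prof = rmsf_profile(mixed, fit)
core_rmsf = prof.loc[: n_core].mean()
mobile_rmsf = prof.loc[n_core + 1:].mean()
print(f"mean RMSF: core {core_rmsf:.2f} A, mobile segment {mobile_rmsf:.2f} A")
print()
print("Two clusters with ~10 members each and a mobile-segment RMSF far")
print("above the core's reproduce the two-state picture built into the")
print("generator: a rigid scaffold carrying a mobile element.")
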