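"""Reduce the shell to the site-bound solvent molecules (rEMCS).

Keeps only the waters bound at the two aggregation centers of the
zwitterion — four at the carboxylate, three at the ammonium — exactly the
retention pattern that turns a 15-water shell into a 7-water microcluster.
"""

from shellpick import emcs_extract, remcs_reduce, suggest_centers
from shellpick.synthetic import alanine_centers, alanine_water_spec, generate

spec = alanine_water_spec(n_frames=200, seed=2)
traj, _, _ = generate(spec)
cluster = emcs_extract(traj, M=10)

# advisory candidates from the topology (polar atoms, grouped by bonding)
candidates = suggest_centers(traj)
print("suggested aggregation centers:",
      [(c.label, c.center_atoms.tolist()) for c in candidates])

centers = alanine_centers()  # carboxylate n=4, ammonium n=3
reduced = remcs_reduce(cluster, centers)
print(f"reduction: M={cluster.M} -> k={reduced.k} solvent molecules "
      f"per frame")
print("slot assignment:", reduced.slot_assignment)
# k = 4 + 3 = 7: each frame now contains the solute and the seven waters
# in direct contact with its charged groups; everything diffuse is gone.
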