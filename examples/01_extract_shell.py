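"""Extract a fixed-composition solvation-shell cluster (EMCS).

Builds a small synthetic trajectory of a solvated alanine-like zwitterion,
fits the padded ellipsoid to the solute at every frame, counts the solvent
molecules inside it and extracts the M nearest ones per frame.
"""

from shellpick import build_ellipsoid, determine_M, emcs_extract
from shellpick.synthetic import alanine_water_spec, generate

spec = alanine_water_spec(n_frames=500, seed=1)
traj, labels, names = generate(spec)
print(f"trajectory: {traj.n_frames} frames, {traj.n_solvent} solvent "
      f"molecules around a {len(traj.solute_indices)}-atom solute")

e = build_ellipsoid(traj.coordinates[0][traj.solute_indices], padding=3.0)
print(f"frame-0 ellipsoid semi-axes (padded): "
      f"{[round(float(s + e.padding), 2) for s in e.semi_axes]} A")

m = determine_M(traj, padding=3.0, statistic="median")
print(f"median in-ellipsoid solvent count -> M = {m}")

cluster = emcs_extract(traj, M=10)
print(f"extracted cluster: {cluster.M} solvent slots per frame "
      f"({traj.n_solvent} -> {cluster.M})")
# Every frame now holds the solute plus exactly M solvent molecules,
# ranked by how deep they sit inside the solute-fitting ellipsoid —
# a fixed-composition subtrajectory ready for covariance analysis.
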