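"""Frozen-coordinate specification for constrained QM minimization.

For one representative cluster frame, emits the internal coordinates that
must stay frozen so the minimized structure keeps its sampled
conformation: solute torsions, each water's center of mass in spherical
coordinates about the solute, three rigid-body orientation torsions per
water, and (for solvents that have them) internal torsions.
"""

from shellpick import WATER, build_constraints, emcs_extract, remcs_reduce
from shellpick.synthetic import alanine_centers, alanine_water_spec, generate

spec = alanine_water_spec(n_frames=20, seed=4)
traj, _, _ = generate(spec)
reduced = remcs_reduce(emcs_extract(traj, M=10), alanine_centers())

constraints = build_constraints(
    reduced,
    frame_index=0,
    solute_torsions=[(0, 4, 10, 11)],  # N-CA-C-O backbone torsion
    solvent_template=WATER,
)
n_orient = sum(t.kind == "orientation" for t in constraints.frozen_torsions)
print(f"{len(constraints.frozen_spherical)} spherical (r, theta, phi) "
      f"triples (one per water)")
print(f"{n_orient} orientation torsions (three per water), "
      f"0 water-internal torsions")
print()
print("\n".join(constraints.format_text().splitlines()[:12]))
# Each line is one frozen coordinate; a QM engine's constrained optimizer
# relaxes everything else (bond lengths, angles) while the solvation
# geometry that defines the conformer stays put.
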