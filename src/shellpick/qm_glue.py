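"""Constraint specifications for constrained quantum-chemistry
minimizations, plus stick-spectrum parsing.

Before a representative cluster is handed to a quantum-chemistry engine
for constrained minimization and VCD evaluation, the solute-solvent
internal coordinates that define the conformation must be frozen: (i) the
solute torsion angles, (ii) each solvent molecule's center of mass in
spherical coordinates relative to the solute center of mass, (iii) three
torsions per solvent molecule fixing its rigid-body orientation relative
to the solute, and (iv) the solvent molecules' internal torsions, if any.
This module emits that list as a neutral commented text specification;
writing engine-specific input decks is out of scope.

Spherical convention (stated in the output header): physics convention,
theta polar from the +z of the solute principal frame, phi azimuthal from
+x, computed in the mass-weighted solute principal frame so the values are
reproducible across frames of a frozen-solute trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .emcs import ClusterTrajectory
from .errors import FormatError, SpectrumError, TopologyError
from .spectra import StickSpectrum

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "Na": 22.990,
    "Mg": 24.305, "Ca": 40.078, "Zn": 65.38, "Fe": 55.845,
}


def _masses(elements) -> np.ndarray:
    try:
        return np.array([ATOMIC_MASS[e] for e in elements])
    except KeyError as exc:
        raise TopologyError(f"no atomic mass for element {exc}") from exc


@dataclass
class SolventTemplate:
    """Per-species solvent declaration: atom names/elements in slot order
    and internal torsions as 4-tuples of local (within-molecule) atom
    indices."""

    name: str
    atom_names: list[str]
    elements: list[str]
    internal_torsions: list[tuple[int, int, int, int]] = field(
        default_factory=list
    )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


WATER = SolventTemplate(
    name="water",
    atom_names=["OW", "HW1", "HW2"],
    elements=["O", "H", "H"],
    internal_torsions=[],  # a rigid triatomic has no torsion
)

# dimethyl sulfoxide: the two methyl rotations are the internal torsions
DMSO = SolventTemplate(
    name="dmso",
    atom_names=["S", "O", "C1", "H11", "H12", "H13", "C2", "H21", "H22", "H23"],
    elements=["S", "O", "C", "H", "H", "H", "C", "H", "H", "H"],
    internal_torsions=[(1, 0, 2, 3), (1, 0, 6, 7)],
)


@dataclass
class TorsionConstraint:
    kind: str  # solute | orientation | solvent_internal
    atoms: tuple[int, int, int, int]


@dataclass
class SphericalConstraint:
    """Frozen solvent center of mass: slot index and (r, theta, phi) in
    Angstrom / radians, physics convention, solute principal frame."""

    slot: int
    r: float
    theta: float
    phi: float


@dataclass
class ConstraintSpec:
    frozen_torsions: list[TorsionConstraint]
    frozen_spherical: list[SphericalConstraint]
    solute_com: np.ndarray
    principal_axes: np.ndarray  # rows are the frame's unit axes

    def __post_init__(self):
        seen = set()
        for t in self.frozen_torsions:
            if t.atoms in seen:
                raise TopologyError(f"duplicate torsion {t.atoms}")
            seen.add(t.atoms)

    def format_text(self) -> str:
        lines = [
            "# shellpick constraint specification",
            "# spherical convention: physics; theta polar from +z of the",
            "# solute principal frame, phi azimuthal from +x; r in Angstrom,",
            "# angles in radians; atom indices are 0-based cluster indices",
        ]
        for t in self.frozen_torsions:
            lines.append(
                f"torsion {t.kind} " + " ".join(str(i) for i in t.atoms)
            )
        for s in self.frozen_spherical:
            lines.append(
                f"spherical slot={s.slot} r={s.r:.6f} "
                f"theta={s.theta:.6f} phi={s.phi:.6f}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.format_text())


def solute_principal_frame(
    solute_coords: np.ndarray, elements
) -> tuple[np.ndarray, np.ndarray]:
    """(center of mass, principal axes as rows) of one solute
    conformation, mass-weighted, deterministically signed."""
    m = _masses(elements)
    com = (solute_coords * m[:, None]).sum(axis=0) / m.sum()
    centered = solute_coords - com
    cov = (centered * m[:, None]).T @ centered / m.sum()
    _, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1].T  # rows, descending variance
    lead = np.argmax(np.abs(axes), axis=1)
    signs = np.sign(axes[np.arange(3), lead])
    axes *= np.where(signs == 0, 1.0, signs)[:, None]
    if np.linalg.det(axes) < 0:
        axes[2] *= -1  # right-handed frame
    return com, axes


def cartesian_to_spherical(v: np.ndarray) -> tuple[float, float, float]:
    r = float(np.linalg.norm(v))
    if r == 0:
        return 0.0, 0.0, 0.0
    theta = float(np.arccos(np.clip(v[2] / r, -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    return r, theta, phi


def spherical_to_cartesian(r: float, theta: float, phi: float) -> np.ndarray:
    return np.array(
        [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        ]
    )


def build_constraints(
    cluster: ClusterTrajectory,
    frame_index: int,
    solute_torsions: list[tuple[int, int, int, int]] | None = None,
    solvent_template: SolventTemplate | None = None,
) -> ConstraintSpec:
    """Frozen-coordinate specification for one representative frame.

    Atom indices refer to the concatenated cluster frame (solute first,
    then solvent slots).  The two solute anchor atoms of each solvent
    molecule's orientation torsions are the two solute atoms nearest its
    center of mass (a deterministic choice).
    """
    solute = cluster.solute_coords[frame_index]
    solv = cluster.solvent_coords[frame_index]
    solute_elems = [a.element for a in cluster.solute_topology]
    if solvent_template is None:
        solvent_template = SolventTemplate(
            name="solvent",
            atom_names=[a.name for a in cluster.solvent_template],
            elements=[a.element for a in cluster.solvent_template],
        )
    if solvent_template.n_atoms != cluster.atoms_per_solvent:
        raise TopologyError(
            f"solvent template has {solvent_template.n_atoms} atoms, "
            f"cluster solvent has {cluster.atoms_per_solvent}"
        )
    if cluster.atoms_per_solvent < 2:
        raise TopologyError(
            "solvent molecules need at least 2 atoms to define "
            "orientation torsions"
        )
    com, axes = solute_principal_frame(solute, solute_elems)
    n_solute = len(cluster.solute_topology)
    apm = cluster.atoms_per_solvent
    solvent_masses = _masses(solvent_template.elements)

    torsions: list[TorsionConstraint] = [
        TorsionConstraint("solute", tuple(int(i) for i in t))
        for t in (solute_torsions or [])
    ]
    spherical: list[SphericalConstraint] = []
    for slot in range(cluster.M):
        mol = solv[slot]
        mol_com = (mol * solvent_masses[:, None]).sum(axis=0) / solvent_masses.sum()
        r, theta, phi = cartesian_to_spherical(axes @ (mol_com - com))
        spherical.append(SphericalConstraint(slot, r, theta, phi))
        # anchors: the two solute atoms nearest the solvent center of mass
        d = np.linalg.norm(solute - mol_com, axis=1)
        a1, a2 = np.argsort(d, kind="stable")[:2]
        v1 = n_solute + slot * apm
        v2 = v1 + 1
        torsions.extend(
            TorsionConstraint("orientation", t)
            for t in (
                (int(a2), int(a1), v1, v2),
                (int(a2), int(a1), v2, v1),
                (int(a1), int(a2), v1, v2),
            )
        )
        torsions.extend(
            TorsionConstraint(
                "solvent_internal",
                tuple(v1 + int(i) for i in tor),
            )
            for tor in solvent_template.internal_torsions
        )
    return ConstraintSpec(torsions, spherical, com, axes)


def reconstruct_solvent_com(
    spec: ConstraintSpec, slot: int
) -> np.ndarray:
    """Cartesian solvent center of mass recovered from the frozen
    spherical triple (laboratory frame)."""
    s = next(x for x in spec.frozen_spherical if x.slot == slot)
    local = spherical_to_cartesian(s.r, s.theta, s.phi)
    return spec.solute_com + spec.principal_axes.T @ local


# ---------------------------------------------------------------------------
# stick-spectrum parsing
# ---------------------------------------------------------------------------

def _parse_rows(path, expect_label: bool):
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least "
                                  "two columns")
            try:
                nu, r = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from exc
            if nu <= 0:
                raise SpectrumError(
                    f"{path}:{lineno}: wavenumber must be positive"
                )
            label = parts[2] if expect_label and len(parts) > 2 else ""
            rows.append((nu, r, label))
    return rows


def parse_sticks(path, dialect: str = "two_column") -> StickSpectrum:
    """Read one stick spectrum from delimited text.

    ``two_column``: wavenumber and rotational strength; ``labeled``: a
    third conformer-label column that must be uniform (use
    :func:`parse_stick_sets` for multi-conformer files).  Lines are
    returned sorted by wavenumber; ``#`` comments are skipped.
    """
    if dialect not in ("two_column", "labeled"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = _parse_rows(path, dialect == "labeled")
    if not rows:
        import warnings

        warnings.warn(f"{path}: empty stick spectrum")
        return StickSpectrum(np.empty((0, 2)))
    labels = {r[2] for r in rows}
    if dialect == "labeled" and len(labels) > 1:
        raise FormatError(
            f"{path}: multiple conformer labels {sorted(labels)}; "
            "use parse_stick_sets"
        )
    lines = np.array([(nu, r) for nu, r, _ in rows])
    lines = lines[np.argsort(lines[:, 0], kind="stable")]
    return StickSpectrum(lines, next(iter(labels)) if labels else "")


def parse_stick_sets(path) -> list[StickSpectrum]:
    """Read a labeled multi-conformer stick file into one StickSpectrum
    per label (label order of first appearance)."""
    rows = _parse_rows(path, True)
    by_label: dict[str, list] = {}
    for nu, r, label in rows:
        by_label.setdefault(label, []).append((nu, r))
    out = []
    for label, entries in by_label.items():
        lines = np.array(entries)
        lines = lines[np.argsort(lines[:, 0], kind="stable")]
        out.append(StickSpectrum(lines, label))
    return out
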