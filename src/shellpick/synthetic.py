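"""Synthetic solvated trajectories and stick spectra with known ground
truth.

The generator emulates the configurational structure the extraction
pipeline is designed to resolve: a rigid solute carrying a few interaction
sites, a tightly bound solvent population that hops among a small catalog
of site-bound arrangements with prescribed statistical weights, and a
diffuse bulk population scattered in a shell outside the solute.  Frames
are independent draws (no dynamics): the selection, covariance and basin
machinery under test is purely configurational, so i.i.d. sampling with a
known arrangement label per frame is exactly what is needed to verify
recovered basin weights against the truth.

The stock fixture is an L-alanine-like zwitterion in water: a carboxylate
site holding four waters and an ammonium site holding three (seven bound
molecules), four bound arrangements with weights 0.15 / 0.25 / 0.40 /
0.20, positional noise of 0.15 A, and eight bulk waters — fifteen solvent
molecules in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError
from .remcs import AggregationCenter
from .spectra import StickSpectrum
from .trajectory_io import SOLUTE, SOLVENT, AtomRecord, Trajectory

MIN_ANCHOR_SEPARATION = 0.5  # Angstrom


@dataclass
class SoluteTemplate:
    """A rigid solute: atom names/elements/coordinates plus named
    interaction sites (atom index arrays)."""

    names: list[str]
    elements: list[str]
    coords: np.ndarray
    sites: dict[str, np.ndarray] = field(default_factory=dict)
    resname: str = "MOL"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise TopologyError("solute template coords/names mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class SiteArrangement:
    """One bound-solvent arrangement: anchor positions (one per bound
    molecule, the solvent reference-atom target), optional per-molecule
    orientation matrices applied to the solvent template, and the target
    weight."""

    label: str
    anchors: np.ndarray
    weight: float
    orientations: np.ndarray | None = None  # (k, 3, 3) rotations

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(-1, 3)
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            if self.orientations.shape != (self.anchors.shape[0], 3, 3):
                raise TopologyError(
                    f"arrangement {self.label!r}: orientations must be "
                    "(k, 3, 3)"
                )
        if self.anchors.shape[0]:
            d = np.linalg.norm(
                self.anchors[:, None] - self.anchors[None], axis=2
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_ANCHOR_SEPARATION:
                raise TopologyError(
                    f"arrangement {self.label!r}: anchors closer than "
                    f"{MIN_ANCHOR_SEPARATION} A"
                )


@dataclass
class SyntheticSpec:
    """Full description of one synthetic study; the seed is mandatory."""

    solute: SoluteTemplate
    solvent_names: list[str]
    solvent_elements: list[str]
    solvent_coords: np.ndarray  # local, reference atom first at origin
    arrangements: list[SiteArrangement]
    n_bulk: int
    n_frames: int
    seed: int
    sigma: float = 0.15  # positional noise on bound solvent atoms, A
    bulk_shell: tuple[float, float] = (7.0, 11.0)
    solvent_resname: str = "SOL"

    def __post_init__(self):
        self.solvent_coords = np.asarray(self.solvent_coords, dtype=float)
        if self.seed is None:
            raise ValueError("a seed is mandatory; unseeded generation is "
                             "not supported")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        w = np.array([a.weight for a in self.arrangements])
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"arrangement weights sum to {w.sum()}, not 1")
        sizes = {a.anchors.shape[0] for a in self.arrangements}
        if len(sizes) != 1:
            raise ValueError("all arrangements must bind the same number "
                             "of solvent molecules")

    @property
    def n_bound(self) -> int:
        return self.arrangements[0].anchors.shape[0]

    @property
    def n_solvent(self) -> int:
        return self.n_bound + self.n_bulk


def _topology(spec: SyntheticSpec) -> list[AtomRecord]:
    records = []
    for i, (name, el) in enumerate(zip(spec.solute.names,
                                       spec.solute.elements)):
        records.append(AtomRecord(i, el, name, 0, SOLUTE,
                                  spec.solute.resname, 1))
    apm = len(spec.solvent_names)
    base = spec.solute.n_atoms
    for m in range(spec.n_solvent):
        for k in range(apm):
            records.append(
                AtomRecord(base + m * apm + k, spec.solvent_elements[k],
                           spec.solvent_names[k], m + 1, SOLVENT,
                           spec.solvent_resname, m + 2)
            )
    return records


def generate(spec: SyntheticSpec) -> tuple[Trajectory, np.ndarray, list[str]]:
    """Draw the trajectory; returns (trajectory, per-frame arrangement
    index, arrangement labels).

    Per frame an arrangement is drawn by its weight; each bound solvent
    molecule is placed with its reference atom at the corresponding
    anchor, template orientation, plus isotropic Gaussian noise of
    ``sigma`` on every atom; bulk molecules are scattered uniformly in the
    spherical shell ``bulk_shell`` around the solute center.
    """
    rng = np.random.default_rng(spec.seed)
    f = spec.n_frames
    apm = len(spec.solvent_names)
    weights = np.array([a.weight for a in spec.arrangements])
    labels = rng.choice(len(spec.arrangements), size=f, p=weights)
    anchors = np.stack([a.anchors for a in spec.arrangements])  # (n_arr,k,3)
    template = spec.solvent_coords - spec.solvent_coords[0]
    k = spec.n_bound
    oriented = np.empty((len(spec.arrangements), k, template.shape[0], 3))
    for ai, arr in enumerate(spec.arrangements):
        if arr.orientations is None:
            oriented[ai] = np.broadcast_to(template, (k, *template.shape))
        else:
            oriented[ai] = np.einsum("kij,aj->kai", arr.orientations, template)
    bound = anchors[labels][:, :, None, :] + oriented[labels]
    bound = bound + rng.normal(0.0, spec.sigma, bound.shape) \
        if spec.sigma > 0 else bound
    center = spec.solute.coords.mean(axis=0)
    n_b = spec.n_bulk
    if n_b:
        u = rng.normal(size=(f, n_b, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        r_in, r_out = spec.bulk_shell
        radii = np.cbrt(
            rng.uniform(r_in**3, r_out**3, size=(f, n_b))
        )
        bulk_ref = center + u * radii[:, :, None]
        bulk = bulk_ref[:, :, None, :] + template[None, None]
        solvent = np.concatenate([bound, bulk], axis=1)
    else:
        solvent = bound
    coords = np.concatenate(
        [
            np.broadcast_to(
                spec.solute.coords, (f, spec.solute.n_atoms, 3)
            ),
            solvent.reshape(f, spec.n_solvent * apm, 3),
        ],
        axis=1,
    )
    traj = Trajectory(_topology(spec), coords)
    return traj, labels, [a.label for a in spec.arrangements]


# ---------------------------------------------------------------------------
# stock fixture: L-alanine-like zwitterion in water
# ---------------------------------------------------------------------------

ALANINE_NAMES = ["N", "H1", "H2", "H3", "CA", "HA", "CB", "HB1", "HB2",
                 "HB3", "C", "O", "OXT"]
ALANINE_ELEMENTS = ["N", "H", "H", "H", "C", "H", "C", "H", "H", "H",
                    "C", "O", "O"]
ALANINE_COORDS = np.array(
    [
        [-0.51, 1.36, 0.00],   # N  (ammonium)
        [-1.52, 1.40, 0.08],
        [-0.18, 2.02, 0.70],
        [-0.22, 1.66, -0.93],
        [0.00, 0.00, 0.00],    # CA
        [-0.36, -0.51, 0.89],
        [-0.55, -0.74, -1.22],  # CB
        [-1.64, -0.70, -1.20],
        [-0.22, -1.78, -1.22],
        [-0.21, -0.25, -2.14],
        [1.53, 0.02, 0.01],    # C
        [2.15, 1.08, 0.15],    # O  (carboxylate)
        [2.12, -1.08, -0.11],  # OXT
    ]
)
ALANINE_SITES = {"COO": np.array([11, 12]), "NH3": np.array([0])}

WATER_NAMES = ["OW", "HW1", "HW2"]
WATER_ELEMENTS = ["O", "H", "H"]
WATER_COORDS = np.array(
    [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.24, 0.9266, 0.0]]
)


def alanine_solute() -> SoluteTemplate:
    return SoluteTemplate(
        names=list(ALANINE_NAMES),
        elements=list(ALANINE_ELEMENTS),
        coords=ALANINE_COORDS.copy(),
        sites={k: v.copy() for k, v in ALANINE_SITES.items()},
        resname="ALA",
    )


def alanine_centers(
    n_carboxylate: int = 4, n_ammonium: int = 3
) -> list[AggregationCenter]:
    """The aqueous-alanine aggregation centers: the carboxylate oxygen
    pair holding four waters and the ammonium nitrogen holding three."""
    return [
        AggregationCenter(ALANINE_SITES["COO"], n_carboxylate, "COO"),
        AggregationCenter(ALANINE_SITES["NH3"], n_ammonium, "NH3"),
    ]


def _cone_direction(
    outward: np.ndarray, tilt_deg: float, azimuth_deg: float
) -> np.ndarray:
    """Unit vector on a cone of half-angle ``tilt`` around ``outward``."""
    u = outward / np.linalg.norm(outward)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    tilt = np.deg2rad(tilt_deg)
    beta = np.deg2rad(azimuth_deg)
    return (
        np.cos(tilt) * u
        + np.sin(tilt) * (np.cos(beta) * e1 + np.sin(beta) * e2)
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
    )
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def alanine_water_spec(
    n_frames: int,
    seed: int,
    weights: tuple[float, ...] = (0.15, 0.25, 0.40, 0.20),
    sigma: float = 0.15,
    n_bulk: int = 8,
    rotation_step_deg: float = 30.0,
) -> SyntheticSpec:
    """The stock four-arrangement aqueous-alanine fixture.

    The base bound complex places two waters on each carboxylate oxygen
    and three on the ammonium nitrogen, on staggered distance ladders
    (0.8-0.9 A apart) with every water's hydrogens pointing away from its
    site atom.  The staggering and the outward orientation make the
    distance-based slot ranking of the reduction step deterministic
    against the positional noise, so slot identities do not permute
    between frames.  Arrangement a rotates every bound water azimuthally
    by a * ``rotation_step_deg`` about its own site's outward axis, which
    leaves each water's distance to its site atom (and hence the ladder
    margins) exactly unchanged.  Because all waters share one rotation
    angle, each atom's position is affine in (cos, sin) of that angle, so
    the four arrangement mean structures lie exactly in a
    two-dimensional plane of configuration space and the conformational
    transition is carried by two essential eigenvectors, as in the
    systems this fixture emulates.  Defaults: weights
    0.15/0.25/0.40/0.20, noise 0.15 A, 8 bulk waters -> 15 solvent
    molecules in total.
    """
    solute = alanine_solute()
    coords = solute.coords
    ca, c_carboxyl = coords[4], coords[10]
    o_atom, oxt_atom, n_atom = coords[11], coords[12], coords[0]
    cog = coords.mean(axis=0)
    bisector = WATER_COORDS[1] + WATER_COORDS[2] - 2 * WATER_COORDS[0]
    # (site atom, outward axis, distance ladder value, cone azimuth)
    placements = [
        (o_atom, o_atom - c_carboxyl, 2.0, 0.0),
        (oxt_atom, oxt_atom - c_carboxyl, 2.8, 0.0),
        (o_atom, o_atom - c_carboxyl, 3.6, 180.0),
        (oxt_atom, oxt_atom - c_carboxyl, 4.4, 180.0),
        (n_atom, n_atom - ca, 2.2, 0.0),
        (n_atom, n_atom - ca, 3.1, 120.0),
        (n_atom, n_atom - ca, 4.0, 240.0),
    ]
    arrangements = []
    for a, w in enumerate(weights):
        delta = a * rotation_step_deg
        anchors = []
        orients = []
        for site, outward, dist, az in placements:
            direction = _cone_direction(outward, 35.0, az + delta)
            anchors.append(site + dist * direction)
            orients.append(_rotation_between(bisector, direction))
        arrangements.append(
            SiteArrangement(
                f"arr{a}", np.array(anchors), float(w), np.array(orients)
            )
        )
    return SyntheticSpec(
        solute=solute,
        solvent_names=list(WATER_NAMES),
        solvent_elements=list(WATER_ELEMENTS),
        solvent_coords=WATER_COORDS.copy(),
        arrangements=arrangements,
        n_bulk=n_bulk,
        n_frames=n_frames,
        seed=seed,
        sigma=sigma,
        bulk_shell=(9.0, 13.0),
    )


def generate_sticks(
    n_conformers: int,
    lines_per_conformer: int,
    nu_range: tuple[float, float] = (1200.0, 1500.0),
    seed: int = 0,
    weights=None,
) -> tuple[list[StickSpectrum], np.ndarray]:
    """Reproducible random conformer line lists plus a designated weight
    vector, for weighted-assembly round-trip tests."""
    if nu_range[0] <= 0 or nu_range[1] <= nu_range[0]:
        raise ValueError("invalid wavenumber range")
    rng = np.random.default_rng(seed)
    sticks = []
    for c in range(n_conformers):
        nu = np.sort(rng.uniform(*nu_range, size=lines_per_conformer))
        r = rng.normal(0.0, 1.0, size=lines_per_conformer)
        sticks.append(StickSpectrum(np.column_stack([nu, r]), f"conf{c}"))
    if weights is None:
        w = np.full(n_conformers, 1.0 / n_conformers)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_conformers,):
            raise ValueError("one weight per conformer required")
        w = w / w.sum()
    return sticks, w
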