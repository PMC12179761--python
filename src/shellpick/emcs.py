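"""Ellipsoid-based solvation-shell extraction (EMCS).

At every frame an ellipsoid is fitted to the solute: centered on the solute
geometric center, oriented along the eigenvectors of the solute coordinate
covariance (gyration tensor), with semi-axes proportional to the square
roots of the eigenvalues, expanded so that every solute atom lies inside,
and finally padded outward by a solvation-shell thickness.  Solvent
molecules whose reference point falls inside the padded ellipsoid belong to
the shell; a fixed number M of them (ranked by the ellipsoid metric) is
retained per frame, yielding a fixed-composition solute + M-solvent cluster
subtrajectory suitable for covariance analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyShellError, FrameMismatchError, TopologyError
from .trajectory_io import SOLUTE, SOLVENT, AtomRecord, Trajectory

_DENOM_FLOOR = 1e-12


@dataclass
class EllipsoidSpec:
    """A padded solute-fitting ellipsoid.

    ``axes`` rows are the unit principal directions; ``semi_axes`` are the
    unpadded lengths a >= b >= c (Angstrom).  The in/out metric uses
    ``semi_axes + padding``.
    """

    center: np.ndarray
    axes: np.ndarray
    semi_axes: np.ndarray
    padding: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        if np.any(np.diff(self.semi_axes) > 1e-9):
            raise ValueError("semi_axes must be sorted a >= b >= c")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")


def _batch_ellipsoids(
    solute_coords: np.ndarray, padding: float, scale: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ellipsoid construction for (F, n_solute, 3) coordinates.

    Returns centers (F, 3), axes (F, 3, 3) with rows as directions, and
    unpadded semi-axes (F, 3) sorted descending.
    """
    coords = np.asarray(solute_coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] == 0:
        raise TopologyError("cannot build an ellipsoid from an empty solute")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    centers = coords.mean(axis=1)
    centered = coords - centers[:, None]
    gyration = np.einsum("fni,fnj->fij", centered, centered) / coords.shape[1]
    evals, evecs = np.linalg.eigh(gyration)  # ascending; columns are vectors
    evals = np.clip(evals[:, ::-1], 0.0, None)  # descending
    axes = np.transpose(evecs[:, :, ::-1], (0, 2, 1))  # rows = directions
    # deterministic sign: largest-|component| of each axis made positive
    flat = np.argmax(np.abs(axes), axis=2)
    picked = np.take_along_axis(axes, flat[:, :, None], axis=2)[:, :, 0]
    axes *= np.where(picked < 0, -1.0, 1.0)[:, :, None]
    semi = scale * np.sqrt(evals)
    # expand so every solute atom lies inside the (unpadded) ellipsoid
    local = np.einsum("fni,fji->fnj", centered, axes)
    denom = np.maximum(semi, _DENOM_FLOOR)
    m = np.einsum("fnj->fn", (local / denom[:, None]) ** 2)
    # components along degenerate (zero) axes are themselves zero, so the
    # floor does not inflate m; guard anyway
    m = np.where(np.isfinite(m), m, 0.0)
    factor = np.sqrt(np.maximum(m.max(axis=1), 1.0))
    semi = semi * factor[:, None]
    return centers, axes, semi


def build_ellipsoid(
    solute_coords: np.ndarray, padding: float = 3.0, scale: float = 1.0
) -> EllipsoidSpec:
    """Best-fitting padded ellipsoid of one solute conformation."""
    if padding < 0:
        raise ValueError("padding must be >= 0")
    centers, axes, semi = _batch_ellipsoids(
        np.asarray(solute_coords, dtype=float)[None], padding, scale
    )
    return EllipsoidSpec(centers[0], axes[0], semi[0], padding)


def ellipsoid_metric(point: np.ndarray, e: EllipsoidSpec) -> float | np.ndarray:
    """Ellipsoid coordinate (x'/a')^2 + (y'/b')^2 + (z'/c')^2 of a point
    (or an (N, 3) batch) with padded semi-axes; <= 1 means inside."""
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    local = (np.atleast_2d(p) - e.center) @ e.axes.T
    denom = np.maximum(e.semi_axes + e.padding, _DENOM_FLOOR)
    m = ((local / denom) ** 2).sum(axis=1)
    return float(m[0]) if single else m


@dataclass
class ClusterTrajectory:
    """Fixed-composition solute + M-solvent-slot subtrajectory.

    Slot s of frame f holds the solvent molecule ``solvent_ids[f, s]`` of
    the source trajectory; slots are ordered by ascending ellipsoid metric
    (ties toward the lower molecule id), so slot identity is deterministic
    but the physical molecule occupying it may change between frames.
    """

    solute_topology: list[AtomRecord]
    solvent_template: list[AtomRecord]
    solute_coords: np.ndarray
    solvent_coords: np.ndarray  # (F, M, atoms_per_molecule, 3)
    solvent_ids: np.ndarray  # (F, M)
    boxes: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.solute_coords = np.asarray(self.solute_coords, dtype=float)
        self.solvent_coords = np.asarray(self.solvent_coords, dtype=float)
        self.solvent_ids = np.asarray(self.solvent_ids, dtype=int)
        f, m = self.solvent_ids.shape
        if self.solvent_coords.shape[:2] != (f, m):
            raise FrameMismatchError("solvent coords/ids shape mismatch")
        if self.solute_coords.shape[0] != f:
            raise FrameMismatchError("solute/solvent frame count mismatch")
        for row in self.solvent_ids:
            if len(set(row.tolist())) != m:
                raise FrameMismatchError(
                    "a solvent molecule occupies two slots in one frame"
                )

    @property
    def n_frames(self) -> int:
        return self.solute_coords.shape[0]

    @property
    def M(self) -> int:
        return self.solvent_ids.shape[1]

    @property
    def atoms_per_solvent(self) -> int:
        return len(self.solvent_template)

    @property
    def n_atoms(self) -> int:
        return len(self.solute_topology) + self.M * self.atoms_per_solvent

    def all_coords(self) -> np.ndarray:
        """(F, n_solute + M*apm, 3) concatenated coordinates."""
        f = self.n_frames
        flat_solv = self.solvent_coords.reshape(f, -1, 3)
        return np.concatenate([self.solute_coords, flat_solv], axis=1)

    @property
    def solute_atom_indices(self) -> np.ndarray:
        return np.arange(len(self.solute_topology))

    def to_trajectory(self) -> Trajectory:
        """Materialize as a plain Trajectory (solvent slots renumbered
        1..M) for writing via trajectory_io."""
        topology = [
            AtomRecord(a.atom_index, a.element, a.name, 0, SOLUTE,
                       a.resname or "MOL", 1)
            for a in self.solute_topology
        ]
        n_solute = len(topology)
        apm = self.atoms_per_solvent
        for slot in range(self.M):
            for k, t in enumerate(self.solvent_template):
                topology.append(
                    AtomRecord(
                        n_solute + slot * apm + k, t.element, t.name,
                        slot + 1, SOLVENT, t.resname or "SOL", slot + 2,
                    )
                )
        return Trajectory(topology, self.all_coords(), self.boxes)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        import h5py

        def top_doc(records):
            return json.dumps(
                [
                    {"element": a.element, "name": a.name,
                     "resname": a.resname, "molecule_id": a.molecule_id}
                    for a in records
                ]
            )

        with h5py.File(path, "w") as h5:
            h5.create_dataset("solute_coords", data=self.solute_coords)
            h5.create_dataset("solvent_coords", data=self.solvent_coords)
            h5.create_dataset("solvent_ids", data=self.solvent_ids)
            if self.boxes is not None:
                h5.create_dataset("boxes", data=self.boxes)
            h5.attrs["solute_topology"] = top_doc(self.solute_topology)
            h5.attrs["solvent_template"] = top_doc(self.solvent_template)
            h5.attrs["provenance"] = json.dumps(self.provenance)
            h5.attrs["kind"] = type(self).__name__

    @classmethod
    def load(cls, path) -> "ClusterTrajectory":
        import h5py

        with h5py.File(path, "r") as h5:
            def records(key, role):
                docs = json.loads(h5.attrs[key])
                return [
                    AtomRecord(i, d["element"], d["name"], d["molecule_id"],
                               role, d["resname"])
                    for i, d in enumerate(docs)
                ]

            kwargs = dict(
                solute_topology=records("solute_topology", SOLUTE),
                solvent_template=records("solvent_template", SOLVENT),
                solute_coords=h5["solute_coords"][()],
                solvent_coords=h5["solvent_coords"][()],
                solvent_ids=h5["solvent_ids"][()],
                boxes=h5["boxes"][()] if "boxes" in h5 else None,
                provenance=json.loads(h5.attrs["provenance"]),
            )
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# selection machinery
# ---------------------------------------------------------------------------

def _solvent_layout(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(mol_ids (N,), atom index matrix (N, apm)); homogeneous solvent only."""
    mols = traj.solvent_molecules
    if not mols:
        raise TopologyError("trajectory has no solvent molecules")
    sizes = {len(v) for v in mols.values()}
    if len(sizes) != 1:
        raise TopologyError(
            f"mixed solvent molecule sizes {sorted(sizes)}; shellpick "
            "requires a homogeneous solvent"
        )
    ids = np.array(sorted(mols), dtype=int)
    idx = np.stack([mols[m] for m in ids])
    return ids, idx


def _solvent_geometry(
    traj: Trajectory,
    centers: np.ndarray,
    reference_point: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame solvent coordinates and reference points, minimum-imaged.

    Returns (mol_ids (N,), solv_coords (F, N, apm, 3), ref_points
    (F, N, 3), atom index matrix).  When the trajectory has a box, every
    solvent molecule is rigidly shifted to the periodic image whose
    geometric center is closest to the frame's ellipsoid center.
    """
    ids, idx = _solvent_layout(traj)
    coords = traj.coordinates[:, idx.reshape(-1)].reshape(
        traj.n_frames, len(ids), idx.shape[1], 3
    )
    cog = coords.mean(axis=2)
    if traj.boxes is not None:
        box = traj.boxes[:, None, :]
        shift = -box * np.round((cog - centers[:, None]) / box)
        coords = coords + shift[:, :, None, :]
        cog = cog + shift
    if reference_point == "cog":
        ref = cog
    elif reference_point == "nearest_atom":
        ref = cog  # per-atom metric handled by caller
    else:
        raise ValueError(f"unknown reference_point {reference_point!r}")
    return ids, coords, ref, idx


def _batch_metric(
    points: np.ndarray, centers: np.ndarray, axes: np.ndarray,
    semi: np.ndarray, padding: float,
) -> np.ndarray:
    """Metric of (F, N, 3) points against per-frame ellipsoids."""
    local = np.einsum("fni,fji->fnj", points - centers[:, None], axes)
    denom = np.maximum(semi + padding, _DENOM_FLOOR)
    return ((local / denom[:, None]) ** 2).sum(axis=2)


def _frame_metrics(
    traj: Trajectory, padding: float, scale: float, reference_point: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    solute_idx = traj.solute_indices
    centers, axes, semi = _batch_ellipsoids(
        traj.coordinates[:, solute_idx], padding, scale
    )
    ids, coords, ref, idx = _solvent_geometry(traj, centers, reference_point)
    if reference_point == "nearest_atom":
        f, n, apm, _ = coords.shape
        per_atom = _batch_metric(
            coords.reshape(f, n * apm, 3), centers, axes, semi, padding
        ).reshape(f, n, apm)
        metrics = per_atom.min(axis=2)
    else:
        metrics = _batch_metric(ref, centers, axes, semi, padding)
    return ids, coords, metrics, idx


def determine_M(
    traj: Trajectory,
    padding: float = 3.0,
    scale: float = 1.0,
    statistic: str = "median",
    reference_point: str = "cog",
) -> int:
    """Fixed solvent count M: the chosen statistic (default median) of the
    per-frame number of solvent molecules inside the padded ellipsoid,
    floored to an integer and clamped to >= 1."""
    _, _, metrics, _ = _frame_metrics(traj, padding, scale, reference_point)
    counts = (metrics <= 1.0).sum(axis=1)
    if counts.max() == 0:
        raise EmptyShellError(
            "no solvent molecule falls inside the ellipsoid in any frame; "
            "increase the padding"
        )
    if statistic == "median":
        value = float(np.median(counts))
    elif statistic == "mode":
        vals, freq = np.unique(counts, return_counts=True)
        value = float(vals[np.argmax(freq)])
    elif statistic == "min":
        value = float(counts.min())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return max(int(np.floor(value)), 1)


def emcs_extract(
    traj: Trajectory,
    M: int | None = None,
    padding: float = 3.0,
    scale: float = 1.0,
    statistic: str = "median",
    reference_point: str = "cog",
) -> ClusterTrajectory:
    """Extract the fixed-composition solute + M-solvent cluster
    subtrajectory.

    Per frame, solvent molecules are ranked by the ellipsoid metric of
    their reference point (ascending, ties toward the lower molecule id)
    and the first M are retained; slots are ordered by that ranking.
    """
    if M is None:
        M = determine_M(traj, padding, scale, statistic, reference_point)
    if M < 1:
        raise ValueError("M must be >= 1")
    if M >= traj.n_solvent:
        raise ValueError(
            f"M={M} must be smaller than the solvent count "
            f"{traj.n_solvent} of the source trajectory"
        )
    ids, coords, metrics, idx = _frame_metrics(
        traj, padding, scale, reference_point
    )
    # ids ascend in the metric arrays' molecule axis, so a stable argsort
    # on the metric breaks ties toward the lower molecule id
    order = np.argsort(metrics, axis=1, kind="stable")[:, :M]
    sel_ids = ids[order]
    sel_coords = np.take_along_axis(
        coords, order[:, :, None, None], axis=1
    )
    mols = traj.solvent_molecules
    template_idx = mols[ids[0]]
    solvent_template = [traj.topology[i] for i in template_idx]
    solute_idx = traj.solute_indices
    solute_topology = [traj.topology[i] for i in solute_idx]
    return ClusterTrajectory(
        solute_topology=solute_topology,
        solvent_template=solvent_template,
        solute_coords=traj.coordinates[:, solute_idx].copy(),
        solvent_coords=sel_coords,
        solvent_ids=sel_ids,
        boxes=None if traj.boxes is None else traj.boxes.copy(),
        provenance={
            "stage": "emcs",
            "M": int(M),
            "padding": float(padding),
            "scale": float(scale),
            "statistic": statistic,
            "reference_point": reference_point,
            "source_n_solvent": int(traj.n_solvent),
        },
    )
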