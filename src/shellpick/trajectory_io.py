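"""Multi-frame structure I/O with an explicit solute/solvent partition.

The in-memory model is deliberately simple: a :class:`Trajectory` is a
topology (a flat list of :class:`AtomRecord`) plus a dense coordinate array
of shape ``(n_frames, n_atoms, 3)`` in Angstrom.  Every atom carries a
``role`` — ``"solute"`` or ``"solvent"`` — assigned at read time from a set
of solvent residue names.  All atoms not matched by the selector are treated
as one rigid solute molecule (``molecule_id == 0``); each solvent molecule
keeps its own ``molecule_id`` (1-based, in file order).

Supported formats:

``pdb``
    Multi-MODEL PDB, read and written through MDAnalysis (residue names are
    preserved verbatim).
``gro``
    Multi-frame GROMACS GRO (concatenated frames in one file).  Parsed with
    an in-package fixed-column reader/writer; coordinates are converted
    between the file's nm and the internal Angstrom.
``xyz``
    Extended XYZ.  Bare XYZ has no molecule information, so a sidecar
    topology file (YAML, see :func:`write_xyz_topology`) declares the solute
    atom count and the solvent residue name / atoms-per-molecule; by default
    it lives next to the coordinate file as ``<path>.top.yml``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .errors import FormatError, FrameMismatchError, TopologyError

SOLUTE = "solute"
SOLVENT = "solvent"

NM_PER_ANGSTROM = 0.1

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "CA", "ZN", "FE", "MN", "CU", "SE", "SI",
}


def guess_element(name: str) -> str:
    """Guess a chemical symbol from an atom name.

    Leading digits are ignored (``1HB`` is hydrogen).  Names that exactly
    match a common two-letter element (CL, NA, ...) map to it; otherwise the
    first letter wins, which is the right call for biomolecular names such
    as CA (alpha carbon) or OXT.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot guess element from atom name {name!r}")
    upper = stripped.upper()
    if upper[:2] in _TWO_LETTER_ELEMENTS and len(stripped) == 2:
        return upper[0] + upper[1].lower()
    return upper[0]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology.

    ``molecule_id`` groups atoms into molecules: 0 is the (single) solute
    molecule, positive ids number the solvent molecules.  ``resname`` and
    ``resid`` retain the source file's residue labelling for faithful
    writing; they do not participate in topology identity.
    """

    atom_index: int
    element: str
    name: str
    molecule_id: int
    role: str
    resname: str = ""
    resid: int = 0

    def __post_init__(self):
        if self.role not in (SOLUTE, SOLVENT):
            raise TopologyError(f"invalid role {self.role!r}")


@dataclass
class Frame:
    """A single-frame view: coordinates in Angstrom, optional box lengths."""

    coordinates: np.ndarray
    frame_index: int
    box: np.ndarray | None = None


@dataclass
class Trajectory:
    """Topology + per-frame coordinates (Angstrom) + optional boxes."""

    topology: list[AtomRecord]
    coordinates: np.ndarray
    boxes: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FrameMismatchError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != len(self.topology):
            raise FrameMismatchError(
                f"coordinate array has {self.coordinates.shape[1]} atoms, "
                f"topology has {len(self.topology)}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise FrameMismatchError("non-finite coordinates")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (self.n_frames, 3):
                raise FrameMismatchError(
                    f"boxes must have shape ({self.n_frames}, 3)"
                )
        roles_by_mol: dict[int, str] = {}
        for a in self.topology:
            prev = roles_by_mol.setdefault(a.molecule_id, a.role)
            if prev != a.role:
                raise TopologyError(
                    f"molecule {a.molecule_id} mixes solute and solvent atoms"
                )
        if not any(a.role == SOLUTE for a in self.topology):
            raise TopologyError("trajectory has no solute atoms")
        solute_mols = {a.molecule_id for a in self.topology if a.role == SOLUTE}
        if len(solute_mols) != 1:
            raise TopologyError(
                f"solute atoms must form exactly one molecule, "
                f"found {len(solute_mols)}"
            )

    # -- derived views ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def solute_indices(self) -> np.ndarray:
        return np.array(
            [a.atom_index for a in self.topology if a.role == SOLUTE], dtype=int
        )

    @property
    def solvent_molecules(self) -> dict[int, np.ndarray]:
        """Mapping solvent molecule_id -> atom index array (file order)."""
        out: dict[int, list[int]] = {}
        for a in self.topology:
            if a.role == SOLVENT:
                out.setdefault(a.molecule_id, []).append(a.atom_index)
        return {m: np.array(idx, dtype=int) for m, idx in out.items()}

    @property
    def n_solvent(self) -> int:
        return len({a.molecule_id for a in self.topology if a.role == SOLVENT})

    def frame(self, i: int) -> Frame:
        box = None if self.boxes is None else self.boxes[i]
        return Frame(self.coordinates[i], i, box)

    @property
    def frames(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(self.n_frames))

    def same_topology(self, other: "Trajectory") -> bool:
        """Topology identity up to residue renumbering."""
        if len(self.topology) != len(other.topology):
            return False
        key = lambda a: (a.element, a.name.strip(), a.molecule_id, a.role,
                         a.resname.strip())
        return all(key(a) == key(b) for a, b in zip(self.topology, other.topology))


# ---------------------------------------------------------------------------
# topology assembly helpers
# ---------------------------------------------------------------------------

def build_topology(
    names: Sequence[str],
    resnames: Sequence[str],
    resids: Sequence[int],
    solvent_selector: Iterable[str],
    elements: Sequence[str] | None = None,
) -> list[AtomRecord]:
    """Assign roles and molecule ids from per-atom residue labels.

    Atoms whose residue name is in ``solvent_selector`` become solvent, one
    molecule per (resname, resid) run; everything else is the single solute
    molecule (id 0).
    """
    selector = {s.strip() for s in solvent_selector}
    records: list[AtomRecord] = []
    mol_id = 0
    next_solvent_id = 1
    last_res_key = None
    current_ids: dict = {}
    for i, (name, resname, resid) in enumerate(zip(names, resnames, resids)):
        rn = resname.strip()
        element = elements[i] if elements is not None else guess_element(name)
        if rn in selector:
            res_key = (rn, resid)
            if res_key != last_res_key or res_key not in current_ids:
                current_ids[res_key] = next_solvent_id
                next_solvent_id += 1
            last_res_key = res_key
            mid, role = current_ids[res_key], SOLVENT
        else:
            last_res_key = None
            mid, role = 0, SOLUTE
        records.append(
            AtomRecord(i, element, name.strip(), mid, role, rn, int(resid))
        )
    return records


# ---------------------------------------------------------------------------
# GRO (in-package fixed-column reader/writer; file unit is nm)
# ---------------------------------------------------------------------------

def _read_gro(path: Path) -> tuple[list, np.ndarray, np.ndarray | None,
                                   list[str], list[str], list[int]]:
    lines = path.read_text().splitlines()
    frames = []
    boxes = []
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    pos = 0
    first = True
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break
        if pos + 1 >= len(lines):
            raise FormatError(f"{path}: truncated frame header at line {pos + 1}")
        try:
            natoms = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: expected atom count at line {pos + 2}, "
                f"got {lines[pos + 1]!r}"
            ) from exc
        atom_lines = lines[pos + 2 : pos + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"{path}: frame at line {pos + 1} is truncated")
        coords = np.empty((natoms, 3))
        for j, line in enumerate(atom_lines):
            lineno = pos + 3 + j
            try:
                if first:
                    resids.append(int(line[0:5]))
                    resnames.append(line[5:10].strip())
                    names.append(line[10:15].strip())
                coords[j, 0] = float(line[20:28])
                coords[j, 1] = float(line[28:36])
                coords[j, 2] = float(line[36:44])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: malformed GRO line {lineno}") from exc
        box_line = lines[pos + 2 + natoms].split()
        try:
            box = np.array([float(x) for x in box_line[:3]])
        except (ValueError, IndexError) as exc:
            raise FormatError(
                f"{path}: malformed box line {pos + 3 + natoms}"
            ) from exc
        if len(frames) and natoms != frames[0].shape[0]:
            raise FrameMismatchError(
                f"{path}: frame {len(frames)} has {natoms} atoms, "
                f"frame 0 has {frames[0].shape[0]}"
            )
        frames.append(coords / NM_PER_ANGSTROM)
        boxes.append(box / NM_PER_ANGSTROM)
        pos += 2 + natoms + 1
        first = False
    if not frames:
        raise FormatError(f"{path}: no frames found")
    boxes_arr: np.ndarray | None = np.array(boxes)
    if np.all(boxes_arr == 0):
        boxes_arr = None
    return frames, np.array(frames), boxes_arr, names, resnames, resids


def _sequential_resids(topology: list[AtomRecord]) -> tuple[list[int], list[str]]:
    """Renumber residues 1.. in atom order (runs of equal residue identity)."""
    resids: list[int] = []
    resnames: list[str] = []
    last_key = None
    rid = 0
    for a in topology:
        key = (a.molecule_id, a.resname, a.resid)
        if key != last_key:
            rid += 1
            last_key = key
        resids.append(rid)
        resnames.append(a.resname or ("SOL" if a.role == SOLVENT else "MOL"))
    return resids, resnames


def _write_gro(traj: Trajectory, path: Path) -> None:
    resids, resnames = _sequential_resids(traj.topology)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"shellpick frame {f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for a in traj.topology:
                x, y, z = traj.coordinates[f, a.atom_index] * NM_PER_ANGSTROM
                fh.write(
                    f"{resids[a.atom_index] % 100000:5d}"
                    f"{resnames[a.atom_index]:<5.5s}"
                    f"{a.name:>5.5s}"
                    f"{(a.atom_index + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            if traj.boxes is not None:
                bx, by, bz = traj.boxes[f] * NM_PER_ANGSTROM
            else:
                bx = by = bz = 0.0
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (via MDAnalysis)
# ---------------------------------------------------------------------------

def _read_pdb(path: Path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - wrap parser errors
            raise FormatError(f"{path}: PDB parse failed ({exc})") from exc
        names = [a.name for a in u.atoms]
        resnames = [a.resname for a in u.atoms]
        resids = [int(a.resid) for a in u.atoms]
        try:
            elements = [
                e.capitalize() if e else guess_element(n)
                for e, n in zip(u.atoms.elements, names)
            ]
        except (mda.exceptions.NoDataError, AttributeError):
            elements = [guess_element(n) for n in names]
        coords = []
        boxes = []
        for ts in u.trajectory:
            coords.append(ts.positions.copy())
            dims = ts.dimensions
            boxes.append(dims[:3].copy() if dims is not None else np.zeros(3))
    coords_arr = np.array(coords)
    boxes_arr: np.ndarray | None = np.array(boxes)
    if np.all(boxes_arr == 0):
        boxes_arr = None
    return coords_arr, boxes_arr, names, resnames, resids, elements


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda

    resids, resnames = _sequential_resids(traj.topology)
    n_res = max(resids)
    resindex = [r - 1 for r in resids]
    res_names: list[str] = [""] * n_res
    for i, r in enumerate(resindex):
        res_names[r] = resnames[i]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            traj.n_atoms, n_residues=n_res, atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in traj.topology])
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
        u.add_TopologyAttr("elements", [a.element for a in traj.topology])
        u.load_new(traj.coordinates.astype(np.float32), order="fac")
        if traj.boxes is not None:
            for ts, box in zip(u.trajectory, traj.boxes):
                ts.dimensions = [*box, 90.0, 90.0, 90.0]
        with mda.Writer(str(path), traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# extended XYZ + sidecar topology
# ---------------------------------------------------------------------------

def xyz_topology_path(path: Path) -> Path:
    return Path(str(path) + ".top.yml")


def write_xyz_topology(traj: Trajectory, path: Path) -> None:
    solv = traj.solvent_molecules
    apm = len(next(iter(solv.values()))) if solv else 0
    solv_resname = next(
        (a.resname or "SOL" for a in traj.topology if a.role == SOLVENT), "SOL"
    )
    doc = {
        "solute": {
            "n_atoms": int(len(traj.solute_indices)),
            "resname": traj.topology[0].resname or "MOL",
            "names": [a.name for a in traj.topology if a.role == SOLUTE],
        },
        "solvent": {
            "resname": solv_resname,
            "atoms_per_molecule": int(apm),
            "names": [
                traj.topology[i].name for i in next(iter(solv.values()))
            ] if solv else [],
        },
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _read_xyz(path: Path, topology_path: Path | None):
    top_path = topology_path or xyz_topology_path(path)
    if not Path(top_path).exists():
        raise TopologyError(
            f"XYZ input needs a sidecar topology file; {top_path} not found"
        )
    doc = yaml.safe_load(Path(top_path).read_text())
    try:
        n_solute = int(doc["solute"]["n_atoms"])
        solv = doc["solvent"]
        apm = int(solv["atoms_per_molecule"])
        solv_resname = str(solv["resname"])
    except (KeyError, TypeError) as exc:
        raise TopologyError(f"{top_path}: invalid sidecar topology") from exc

    lines = Path(path).read_text().splitlines()
    pos = 0
    frames = []
    boxes = []
    elements: list[str] = []
    first = True
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        box = None
        if 'box="' in comment:
            try:
                box = np.array(
                    [float(x) for x in comment.split('box="')[1].split('"')[0].split()]
                )
            except ValueError as exc:
                raise FormatError(f"{path}: malformed box at line {pos + 2}") from exc
        atom_lines = lines[pos + 2 : pos + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"{path}: frame at line {pos + 1} is truncated")
        coords = np.empty((natoms, 3))
        for j, line in enumerate(atom_lines):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed XYZ line {pos + 3 + j}")
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise FormatError(f"{path}: malformed XYZ line {pos + 3 + j}") from exc
            if first:
                elements.append(parts[0])
        if frames and natoms != frames[0].shape[0]:
            raise FrameMismatchError(
                f"{path}: frame {len(frames)} has {natoms} atoms, "
                f"frame 0 has {frames[0].shape[0]}"
            )
        frames.append(coords)
        boxes.append(box if box is not None else np.zeros(3))
        pos += 2 + natoms
        first = False
    if not frames:
        raise FormatError(f"{path}: no frames found")
    coords_arr = np.array(frames)
    natoms = coords_arr.shape[1]
    if apm > 0 and (natoms - n_solute) % apm != 0:
        raise TopologyError(
            f"{path}: {natoms} atoms minus {n_solute} solute not divisible "
            f"by {apm} atoms per solvent molecule"
        )
    solute_names = list(doc["solute"].get("names") or elements[:n_solute])
    solvent_names = list(doc["solvent"].get("names") or [])
    names = []
    resnames = []
    resids = []
    for i in range(n_solute):
        names.append(solute_names[i] if i < len(solute_names) else elements[i])
        resnames.append(str(doc["solute"].get("resname", "MOL")))
        resids.append(1)
    n_mol = (natoms - n_solute) // apm if apm else 0
    for m in range(n_mol):
        for k in range(apm):
            idx = n_solute + m * apm + k
            names.append(
                solvent_names[k] if k < len(solvent_names) else elements[idx]
            )
            resnames.append(solv_resname)
            resids.append(2 + m)
    boxes_arr: np.ndarray | None = np.array(boxes)
    if np.all(boxes_arr == 0):
        boxes_arr = None
    return coords_arr, boxes_arr, names, resnames, resids, elements


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            if traj.boxes is not None:
                b = traj.boxes[f]
                fh.write(f'frame={f} box="{b[0]:.6f} {b[1]:.6f} {b[2]:.6f}"\n')
            else:
                fh.write(f"frame={f}\n")
            for a in traj.topology:
                x, y, z = traj.coordinates[f, a.atom_index]
                fh.write(f"{a.element:<3s} {x:15.6f} {y:15.6f} {z:15.6f}\n")
    write_xyz_topology(traj, xyz_topology_path(path))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_FORMATS = ("pdb", "gro", "xyz")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise FormatError(f"unsupported trajectory format {fmt!r}")
    return fmt


def read_trajectory(
    path,
    format: str | None = None,
    solvent_selector: Iterable[str] = ("SOL", "WAT", "HOH"),
    xyz_topology=None,
) -> Trajectory:
    """Read a multi-frame structure file into a :class:`Trajectory`.

    ``solvent_selector`` is the set of residue names treated as solvent;
    everything else becomes the (single) solute molecule.  For XYZ input the
    partition comes from the sidecar topology and the selector is matched
    against its declared solvent residue name.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = _infer_format(path, format)
    if fmt == "gro":
        _, coords, boxes, names, resnames, resids = _read_gro(path)
        elements = None
    elif fmt == "pdb":
        coords, boxes, names, resnames, resids, elements = _read_pdb(path)
    else:
        coords, boxes, names, resnames, resids, elements = _read_xyz(
            path, xyz_topology
        )
    topology = build_topology(names, resnames, resids, solvent_selector, elements)
    return Trajectory(topology, coords, boxes)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a :class:`Trajectory`; re-reading yields the same topology and
    coordinates within the format's printed precision."""
    if traj.n_frames == 0:
        raise FrameMismatchError("cannot write a trajectory with no frames")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gro":
        _write_gro(traj, path)
    elif fmt == "pdb":
        _write_pdb(traj, path)
    else:
        _write_xyz(traj, path)
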