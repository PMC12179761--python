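"""Essential dynamics: covariance analysis of fitted Cartesian coordinates.

Frames are first roto-translationally fitted onto a reference structure
(removing the external degrees of freedom), then the covariance matrix of
the analyzed atoms' Cartesian coordinates about their mean is built and
diagonalized.  The eigenvectors are the collective fluctuation directions;
the eigenvalues (A^2) their variances; the leading "essential" eigenvectors
serve as generalized internal coordinates for conformational analysis.

Conventions: population (1/N) covariance normalization, so eigenvalue v
equals the variance of the frame projections on eigenvector v exactly; no
mass weighting; eigenvalues below 1e-12 A^2 are clipped to zero; each
eigenvector's largest-magnitude component is made positive for
reproducibility across eigensolvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .emcs import ClusterTrajectory
from .errors import FrameMismatchError
from .superposition import fit_trajectory, mean_reference
from .trajectory_io import Trajectory

EIGENVALUE_FLOOR = 1e-12


@dataclass
class EDResult:
    """Output of :func:`ed_analyze`.

    ``eigenvectors[i]`` is the i-th eigenvector (rows), eigenvalues sorted
    descending; ``projections[f, i]`` is frame f's displacement along
    eigenvector i (Angstrom).  ``reference_coords`` and ``fit_subset``
    record the superposition used, so further structures can be projected
    consistently (:func:`project_structure`).
    """

    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    analyzed_atom_set: np.ndarray
    reference_coords: np.ndarray | None = None
    fit_subset: np.ndarray | None = None

    @property
    def n_atoms_analyzed(self) -> int:
        return self.analyzed_atom_set.size

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def cumulative_fraction(self, d: int) -> float:
        """Fraction of total fluctuation carried by the first d
        eigenvectors."""
        total = self.total_variance
        if total == 0:
            return 0.0
        return float(self.eigenvalues[:d].sum() / total)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            for key in ("mean_coords", "eigenvalues", "eigenvectors",
                        "projections", "analyzed_atom_set"):
                h5.create_dataset(key, data=getattr(self, key))
            if self.reference_coords is not None:
                h5.create_dataset("reference_coords", data=self.reference_coords)
            if self.fit_subset is not None:
                h5.create_dataset("fit_subset", data=self.fit_subset)

    @classmethod
    def load(cls, path) -> "EDResult":
        import h5py

        with h5py.File(path, "r") as h5:
            kwargs = {
                key: h5[key][()]
                for key in ("mean_coords", "eigenvalues", "eigenvectors",
                            "projections", "analyzed_atom_set")
            }
            for key in ("reference_coords", "fit_subset"):
                if key in h5:
                    kwargs[key] = h5[key][()]
        return cls(**kwargs)

    def export_eigenvalue_spectrum(self, path) -> None:
        """Two-column text (index starting at 1, eigenvalue in A^2)."""
        with open(path, "w") as fh:
            fh.write("# eigenvector_index  eigenvalue_A2\n")
            for i, ev in enumerate(self.eigenvalues, start=1):
                fh.write(f"{i:6d}  {ev:.10e}\n")


def _coerce_coords(obj) -> tuple[np.ndarray, np.ndarray]:
    """(F, A, 3) coordinates plus the default (solute) fit subset."""
    if isinstance(obj, ClusterTrajectory):
        return obj.all_coords(), obj.solute_atom_indices
    if isinstance(obj, Trajectory):
        return obj.coordinates, obj.solute_indices
    coords = np.asarray(obj, dtype=float)
    if coords.ndim != 3:
        raise FrameMismatchError(
            "expected a ClusterTrajectory, Trajectory or (F, A, 3) array"
        )
    return coords, np.arange(coords.shape[1])


def ed_analyze(
    cluster,
    fit_subset: np.ndarray | None = None,
    analyze_subset: np.ndarray | None = None,
    reference: str | np.ndarray = "first",
    fit_weights: np.ndarray | None = None,
    superpose: bool = True,
) -> EDResult:
    """Fit frames and diagonalize the coordinate covariance.

    ``cluster`` may be a :class:`ClusterTrajectory` (or reduced), a
    :class:`Trajectory`, or a raw (F, A, 3) array.  ``fit_subset`` defaults
    to the solute atoms (all atoms for raw arrays); ``analyze_subset``
    defaults to all atoms.  ``reference`` is ``"first"`` (frame 0),
    ``"mean"`` (iterated mean structure) or explicit (A, 3) coordinates.
    ``superpose=False`` skips the roto-translational fit entirely, for
    input that is already expressed in a common body frame.
    """
    coords, default_fit = _coerce_coords(cluster)
    if coords.shape[0] < 2:
        raise FrameMismatchError(
            "essential dynamics needs at least 2 frames"
        )
    fit_idx = default_fit if fit_subset is None else np.asarray(fit_subset, int)
    analyze_idx = (
        np.arange(coords.shape[1])
        if analyze_subset is None
        else np.asarray(analyze_subset, int)
    )
    if analyze_idx.size == 0:
        raise FrameMismatchError("analyze_subset must not be empty")
    if not superpose:
        ref = None
        fitted = coords
    else:
        if isinstance(reference, str):
            if reference == "first":
                ref = coords[0]
            elif reference == "mean":
                ref = mean_reference(coords, fit_idx, fit_weights)
            else:
                raise ValueError(f"unknown reference {reference!r}")
        else:
            ref = np.asarray(reference, dtype=float)
        fitted, _ = fit_trajectory(coords, ref, fit_idx, fit_weights)
    x = fitted[:, analyze_idx].reshape(coords.shape[0], -1)
    mean = x.mean(axis=0)
    dev = x - mean
    cov = dev.T @ dev / dev.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evals = np.where(evals < EIGENVALUE_FLOOR, 0.0, evals)
    vectors = evecs[:, order].T  # rows are eigenvectors
    # deterministic sign: largest-|component| positive (ties: first index)
    lead = np.argmax(np.abs(vectors), axis=1)
    signs = np.sign(vectors[np.arange(len(vectors)), lead])
    vectors *= np.where(signs == 0, 1.0, signs)[:, None]
    projections = dev @ vectors.T
    return EDResult(
        mean_coords=mean,
        eigenvalues=evals,
        eigenvectors=vectors,
        projections=projections,
        analyzed_atom_set=analyze_idx,
        reference_coords=ref,
        fit_subset=fit_idx if superpose else None,
    )


def essential_count(ed: EDResult, variance_fraction: float = 0.6) -> int:
    """Smallest d whose cumulative eigenvalue fraction reaches
    ``variance_fraction`` (default 0.6, the usual essential-subspace
    criterion)."""
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    total = ed.total_variance
    if total == 0:
        warnings.warn("zero total variance; no essential eigenvectors")
        return 0
    cum = np.cumsum(ed.eigenvalues) / total
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def project_structure(
    coords: np.ndarray,
    ed: EDResult,
    eigenvector_indices=None,
    prefit: bool = True,
) -> np.ndarray:
    """Project a structure onto selected eigenvectors.

    With ``prefit=True`` the full-frame coordinates are fitted onto the
    stored reference with the stored fit subset — exactly reproducing the
    analysis pipeline, so frames of the analyzed trajectory recover their
    stored projections.  With ``prefit=False`` the coordinates are taken
    as already expressed in the fitted frame (e.g. the mean structure or a
    displacement along an eigenvector) and dotted directly.
    """
    coords = np.asarray(coords, dtype=float)
    if eigenvector_indices is None:
        eigenvector_indices = np.arange(len(ed.eigenvalues))
    idx = np.atleast_1d(np.asarray(eigenvector_indices, dtype=int))
    if np.any(idx < 0) or np.any(idx >= len(ed.eigenvalues)):
        raise IndexError("eigenvector index out of range")
    if prefit and ed.reference_coords is not None:
        fitted, _ = fit_trajectory(coords, ed.reference_coords, ed.fit_subset)
        flat = fitted[ed.analyzed_atom_set].reshape(-1)
    else:
        if coords.ndim == 2:
            if coords.shape[0] == ed.n_atoms_analyzed:
                flat = coords.reshape(-1)
            else:
                flat = coords[ed.analyzed_atom_set].reshape(-1)
        else:
            flat = coords
    if flat.shape[0] != ed.mean_coords.shape[0]:
        raise FrameMismatchError(
            "structure does not conform to the analyzed atom set"
        )
    return (flat - ed.mean_coords) @ ed.eigenvectors[idx].T
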