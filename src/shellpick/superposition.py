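"""Roto-translational least-squares superposition (Kabsch).

Each frame is fitted onto a reference structure so that only internal
degrees of freedom remain before any covariance analysis.  The rotation is
always proper (determinant +1, no reflection) and the optimal transform is
computed over a fit subset of atoms but applied to all atoms of the frame.

Conventions: coordinates are row vectors, so the transform is
``fitted = coords @ rotation + translation``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitDegeneracyError


@dataclass
class FitResult:
    """Optimal rigid transform of one frame onto the reference.

    ``rotation`` is a proper orthogonal 3x3 matrix acting on row vectors;
    ``translation`` is in Angstrom; ``rmsd`` is the weighted RMSD over the
    fit subset after the transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def _check_subset(ref_sub: np.ndarray, weights: np.ndarray) -> None:
    if ref_sub.shape[0] < 3:
        raise FitDegeneracyError(
            f"fit subset has {ref_sub.shape[0]} atoms; need at least 3"
        )
    centered = ref_sub - np.average(ref_sub, axis=0, weights=weights)
    s = np.linalg.svd(centered * np.sqrt(weights[:, None]), compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise FitDegeneracyError("fit subset is collinear (rank < 2)")


def _kabsch_batch(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched proper-rotation Kabsch.

    mobile: (F, n, 3) centered; reference: (n, 3) centered;
    returns rotations (F, 3, 3) for row-vector right-multiplication.
    """
    w = weights[:, None]
    h = np.einsum("fni,nj->fij", mobile * w, reference)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    u[:, :, -1] *= d[:, None]
    return np.einsum("fij,fjk->fik", u, vt), h


def fit_trajectory(
    coords: np.ndarray,
    reference: np.ndarray,
    fit_atom_subset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit every frame of ``coords`` (F, A, 3) onto ``reference`` (A, 3).

    Returns (fitted coordinates (F, A, 3), per-frame RMSD over the fit
    subset).  ``weights`` are per-subset-atom fitting weights (default
    uniform); the transform found on the subset is applied to all atoms.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    if coords.shape[1] != reference.shape[0]:
        raise FitDegeneracyError(
            f"mobile has {coords.shape[1]} atoms, reference has "
            f"{reference.shape[0]}"
        )
    subset = (
        np.arange(reference.shape[0])
        if fit_atom_subset is None
        else np.asarray(fit_atom_subset, dtype=int)
    )
    w = (
        np.ones(len(subset))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w.shape != (len(subset),):
        raise FitDegeneracyError("weights must match the fit subset size")
    w = w / w.sum()
    ref_sub = reference[subset]
    _check_subset(ref_sub, w)
    ref_centroid = np.average(ref_sub, axis=0, weights=w)
    mob_sub = coords[:, subset]
    mob_centroid = np.einsum("fni,n->fi", mob_sub, w)
    rot, _ = _kabsch_batch(
        mob_sub - mob_centroid[:, None], ref_sub - ref_centroid, w
    )
    fitted = np.einsum(
        "fai,fij->faj", coords - mob_centroid[:, None], rot
    ) + ref_centroid
    dev = fitted[:, subset] - ref_sub
    rmsd = np.sqrt(np.einsum("fni,n->f", dev**2, w))
    if single:
        return fitted[0], rmsd[0]
    return fitted, rmsd


def fit_frame(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_atom_subset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[FitResult, np.ndarray]:
    """Fit one frame onto the reference; see :func:`fit_trajectory`.

    Returns the :class:`FitResult` (rotation, translation, rmsd) and the
    transformed coordinates of all atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    fitted, rmsd = fit_trajectory(mobile, reference, fit_atom_subset, weights)
    # recover R, t from three non-degenerate probe points is fragile;
    # recompute directly instead
    subset = (
        np.arange(reference.shape[0])
        if fit_atom_subset is None
        else np.asarray(fit_atom_subset, dtype=int)
    )
    w = (
        np.ones(len(subset))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    w = w / w.sum()
    ref_sub = np.asarray(reference, dtype=float)[subset]
    ref_centroid = np.average(ref_sub, axis=0, weights=w)
    mob_centroid = np.average(mobile[subset], axis=0, weights=w)
    rot, _ = _kabsch_batch(
        (mobile[subset] - mob_centroid)[None], ref_sub - ref_centroid, w
    )
    rotation = rot[0]
    translation = ref_centroid - mob_centroid @ rotation
    return FitResult(rotation, translation, float(rmsd)), fitted


def mean_reference(
    coords: np.ndarray,
    fit_atom_subset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    n_iter: int = 2,
) -> np.ndarray:
    """Iterated mean structure: fit to frame 0, average, re-fit to the mean.

    Two passes are enough in practice for well-behaved trajectories.
    """
    ref = np.asarray(coords[0], dtype=float)
    for _ in range(n_iter):
        fitted, _ = fit_trajectory(coords, ref, fit_atom_subset, weights)
        ref = fitted.mean(axis=0)
    return ref
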