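"""VCD band-shape assembly and spectrum comparison.

Each vibrational transition is a signed stick (wavenumber, rotational
strength).  Sticks are broadened with a Gaussian whose bandwidth Delta is
the half-width at 1/e of peak height,

    I(nu) = sum_lines R * exp(-((nu - nu_line) / Delta)^2),

individual conformer spectra are summed with their statistical weights,
and spectra are compared after normalizing both to a maximum absolute
intensity of 100 — the root-mean-square deviation of the two normalized
curves on a common window is the agreement score.  The broadened intensity
is proportional to R alone; since every comparison runs on normalized
intensities any constant prefactor cancels (a nu-weighted variant is
available behind ``frequency_weighted=True``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, SpectrumError

DEFAULT_BANDWIDTH = 7.0  # cm^-1, Gaussian half-width at 1/e peak height
DEFAULT_SPACING = 1.0  # cm^-1 grid step
NORMALIZATION_SCALE = 100.0


@dataclass
class StickSpectrum:
    """A line list: (wavenumber cm^-1, signed rotational strength)."""

    lines: np.ndarray
    conformer_label: str = ""

    def __post_init__(self):
        self.lines = np.asarray(self.lines, dtype=float).reshape(-1, 2)
        if self.lines.size and np.any(self.lines[:, 0] <= 0):
            raise SpectrumError("wavenumbers must be positive")
        if self.lines.size and not np.all(np.isfinite(self.lines)):
            raise SpectrumError("non-finite stick entries")

    @property
    def n_lines(self) -> int:
        return self.lines.shape[0]

    def scaled(self, frequency_scale: float) -> "StickSpectrum":
        """Uniform harmonic-frequency scaling factor applied to all
        wavenumbers (left to the user's quantum-chemistry convention)."""
        out = self.lines.copy()
        out[:, 0] *= frequency_scale
        return StickSpectrum(out, self.conformer_label)


@dataclass
class Spectrum:
    """A broadened curve on a strictly ascending uniform wavenumber grid."""

    grid: np.ndarray
    intensity: np.ndarray
    bandwidth: float | None = None
    normalized: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise SpectrumError("grid/intensity length mismatch")
        d = np.diff(self.grid)
        if self.grid.size > 1 and (
            np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-8)
        ):
            raise SpectrumError("grid must be strictly ascending and uniform")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# wavenumber_cm-1 intensity\n")
            for nu, i in zip(self.grid, self.intensity):
                fh.write(f"{nu:12.4f} {i:16.8e}\n")

    @classmethod
    def read(cls, path) -> "Spectrum":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1])


def make_grid(
    lo: float, hi: float, spacing: float = DEFAULT_SPACING
) -> np.ndarray:
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def broaden(
    stick: StickSpectrum,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid: np.ndarray | tuple | None = None,
    frequency_weighted: bool = False,
) -> Spectrum:
    """Gaussian broadening with bandwidth = half-width at 1/e peak height.

    By construction ``I(nu0 +- bandwidth) = I(nu0)/e`` for an isolated
    line.  ``grid`` may be an explicit array, a (lo, hi) or (lo, hi,
    spacing) tuple, or None (lines' range extended by 4 bandwidths,
    1 cm^-1 spacing).
    """
    if bandwidth <= 0:
        raise SpectrumError("bandwidth must be > 0")
    if grid is None:
        if stick.n_lines == 0:
            raise SpectrumError(
                "cannot infer a grid for an empty stick spectrum"
            )
        lo = stick.lines[:, 0].min() - 4 * bandwidth
        hi = stick.lines[:, 0].max() + 4 * bandwidth
        grid = make_grid(lo, hi)
    elif isinstance(grid, tuple):
        grid = make_grid(*grid)
    else:
        grid = np.asarray(grid, dtype=float)
    if stick.n_lines == 0:
        warnings.warn("empty stick spectrum; returning a zero spectrum")
        return Spectrum(grid, np.zeros_like(grid), bandwidth)
    nu0 = stick.lines[:, 0]
    amp = stick.lines[:, 1].copy()
    if frequency_weighted:
        amp = amp * nu0
    intensity = np.einsum(
        "l,lg->g", amp, np.exp(-(((grid[None, :] - nu0[:, None]) / bandwidth) ** 2))
    )
    return Spectrum(grid, intensity, bandwidth)


def assemble(
    spectra: list[Spectrum],
    weights,
    renormalize_weights: bool = True,
) -> Spectrum:
    """Probability-weighted sum of conformer spectra on a common grid.

    Weights must be nonnegative; with ``renormalize_weights`` (default)
    they are rescaled to sum to one first.  Grids must match exactly — no
    silent resampling.
    """
    if not spectra:
        raise SpectrumError("no spectra to assemble")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(spectra),):
        raise SpectrumError("one weight per spectrum required")
    if np.any(weights < 0):
        raise SpectrumError("weights must be nonnegative")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != grid.shape or not np.allclose(
            s.grid, grid, rtol=0, atol=1e-9
        ):
            raise GridMismatchError(
                "spectra are not on a common grid; broaden them on a "
                "shared grid first"
            )
    if renormalize_weights:
        total = weights.sum()
        if total > 0:
            weights = weights / total
    intensity = np.einsum(
        "j,jg->g", weights, np.stack([s.intensity for s in spectra])
    )
    bw = spectra[0].bandwidth
    if any(s.bandwidth != bw for s in spectra):
        bw = None
    return Spectrum(grid, intensity, bw)


def normalize(s: Spectrum, mode: str = "max_abs_100") -> Spectrum:
    """Scale so the maximum absolute intensity is 100 (shape and sign
    structure preserved)."""
    if mode != "max_abs_100":
        raise ValueError(f"unknown normalization mode {mode!r}")
    peak = np.abs(s.intensity).max() if s.intensity.size else 0.0
    if peak == 0:
        raise SpectrumError("cannot normalize an all-zero spectrum")
    return Spectrum(
        s.grid, s.intensity * (NORMALIZATION_SCALE / peak), s.bandwidth,
        normalized=True,
    )


def spectrum_rmsd(
    a: Spectrum,
    b: Spectrum,
    range: tuple[float, float] | None = None,
    spacing: float = DEFAULT_SPACING,
) -> float:
    """Agreement score between two spectra on an explicit window.

    Both are linearly resampled to a common uniform grid on the window
    (intersection of the window and both spectral ranges), each normalized
    to max |I| = 100 on that grid, and the RMSD of the two normalized
    curves is returned.  The value depends on the window — restricting it
    to a sub-band is a deliberate, explicit choice.
    """
    lo = max(a.grid[0], b.grid[0])
    hi = min(a.grid[-1], b.grid[-1])
    if range is not None:
        lo, hi = max(lo, range[0]), min(hi, range[1])
    if hi <= lo:
        raise SpectrumError("spectra do not overlap the comparison range")
    grid = make_grid(lo, hi, spacing)
    ia = np.interp(grid, a.grid, a.intensity)
    ib = np.interp(grid, b.grid, b.intensity)
    for name, arr in (("first", ia), ("second", ib)):
        if np.abs(arr).max() == 0:
            raise SpectrumError(
                f"{name} spectrum is all-zero on the comparison range"
            )
    ia *= NORMALIZATION_SCALE / np.abs(ia).max()
    ib *= NORMALIZATION_SCALE / np.abs(ib).max()
    return float(np.sqrt(np.mean((ia - ib) ** 2)))
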