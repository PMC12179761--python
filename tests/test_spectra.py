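"""Band broadening, weighted assembly, normalization and the agreement
RMSD, each checked against hand-coded loops or closed forms."""

import numpy as np
import pytest

from shellpick.errors import GridMismatchError, SpectrumError
from shellpick.spectra import (
    Spectrum,
    StickSpectrum,
    assemble,
    broaden,
    make_grid,
    normalize,
    spectrum_rmsd,
)


def loop_broaden(lines, bandwidth, grid):
    out = np.zeros_like(grid)
    for nu0, r in lines:
        for i, nu in enumerate(grid):
            out[i] += r * np.exp(-(((nu - nu0) / bandwidth) ** 2))
    return out


def test_one_over_e_bandwidth_definition():
    delta = 7.0
    stick = StickSpectrum([[1300.0, 2.0]])
    s = broaden(stick, delta, grid=(1300 - 28, 1300 + 28, 0.5))
    i0 = s.intensity[np.argmin(np.abs(s.grid - 1300.0))]
    iplus = s.intensity[np.argmin(np.abs(s.grid - (1300.0 + delta)))]
    iminus = s.intensity[np.argmin(np.abs(s.grid - (1300.0 - delta)))]
    assert np.isclose(i0, 2.0, atol=1e-12)
    assert np.isclose(iplus, 2.0 / np.e, atol=1e-12)
    assert np.isclose(iminus, 2.0 / np.e, atol=1e-12)


def test_opposite_lines_cancel_exactly():
    stick = StickSpectrum([[1300.0, 1.0], [1300.0, -1.0]])
    s = broaden(stick, 7.0)
    assert np.allclose(s.intensity, 0.0, atol=1e-15)


def test_broaden_matches_loop_oracle(rng):
    lines = np.column_stack(
        [rng.uniform(1250, 1450, 5), rng.normal(size=5)]
    )
    grid = make_grid(1200, 1500, 1.0)
    s = broaden(StickSpectrum(lines), 7.0, grid)
    assert np.allclose(s.intensity, loop_broaden(lines, 7.0, grid),
                       atol=1e-12)


def test_broaden_is_linear_in_the_line_list(rng):
    a = np.column_stack([rng.uniform(1250, 1350, 4), rng.normal(size=4)])
    b = np.column_stack([rng.uniform(1350, 1450, 3), rng.normal(size=3)])
    grid = make_grid(1200, 1500, 1.0)
    sa = broaden(StickSpectrum(a), 7.0, grid)
    sb = broaden(StickSpectrum(b), 7.0, grid)
    sab = broaden(StickSpectrum(np.vstack([a, b])), 7.0, grid)
    assert np.allclose(sab.intensity, sa.intensity + sb.intensity,
                       atol=1e-12)


def test_gaussian_integral_closed_form():
    """Integrated area of one broadened line is R * Delta * sqrt(pi) to
    better than 0.1% at a grid spacing of Delta/10."""
    delta = 7.0
    r = 1.7
    grid = make_grid(1300 - 10 * delta, 1300 + 10 * delta, delta / 10)
    s = broaden(StickSpectrum([[1300.0, r]]), delta, grid)
    area = np.trapezoid(s.intensity, s.grid)
    assert abs(area - r * delta * np.sqrt(np.pi)) / (
        r * delta * np.sqrt(np.pi)
    ) < 1e-3


def test_empty_stick_list_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        s = broaden(StickSpectrum(np.empty((0, 2))), 7.0,
                    make_grid(1200, 1300))
    assert np.allclose(s.intensity, 0.0)


def test_assemble_identity_and_explicit_combination(rng):
    grid = make_grid(1200, 1500)
    spectra = [
        broaden(
            StickSpectrum(
                np.column_stack(
                    [rng.uniform(1250, 1450, 6), rng.normal(size=6)]
                )
            ),
            7.0,
            grid,
        )
        for _ in range(4)
    ]
    one = assemble([spectra[0]], [1.0])
    assert np.allclose(one.intensity, spectra[0].intensity)
    weights = np.array([0.15, 0.25, 0.40, 0.20])
    total = assemble(spectra, weights)
    oracle = np.zeros_like(grid)
    for w, s in zip(weights, spectra):
        oracle = oracle + w * s.intensity
    assert np.allclose(total.intensity, oracle, atol=1e-12)


def test_assemble_zero_weights_without_renormalization(rng):
    grid = make_grid(1200, 1300)
    s = broaden(StickSpectrum([[1250.0, 1.0]]), 7.0, grid)
    out = assemble([s, s], [0.0, 0.0], renormalize_weights=False)
    assert np.allclose(out.intensity, 0.0)


def test_assemble_rejects_mismatched_grids():
    a = Spectrum(make_grid(1200, 1300), np.ones(101))
    b = Spectrum(make_grid(1201, 1301), np.ones(101))
    with pytest.raises(GridMismatchError):
        assemble([a, b], [0.5, 0.5])


def test_normalize_scales_peak_to_100_and_is_idempotent():
    grid = make_grid(1200, 1300)
    intensity = 4.0 * np.sin((grid - 1200) / 10.0)
    s = Spectrum(grid, intensity)
    n1 = normalize(s)
    assert np.isclose(np.abs(n1.intensity).max(), 100.0)
    n2 = normalize(n1)
    assert np.allclose(n1.intensity, n2.intensity)
    # sign structure preserved
    assert (n1.intensity < 0).any() and (n1.intensity > 0).any()


def test_normalize_rejects_all_zero():
    s = Spectrum(make_grid(1200, 1210), np.zeros(11))
    with pytest.raises(SpectrumError):
        normalize(s)


def rmsd_oracle(a, b, lo, hi, spacing=1.0):
    grid = lo + spacing * np.arange(int((hi - lo) / spacing) + 1)
    ia = np.interp(grid, a.grid, a.intensity)
    ib = np.interp(grid, b.grid, b.intensity)
    ia = ia * 100.0 / np.abs(ia).max()
    ib = ib * 100.0 / np.abs(ib).max()
    return np.sqrt(((ia - ib) ** 2).mean())


def _two_spectra(rng):
    grid = make_grid(1200, 1500)
    a = broaden(
        StickSpectrum([[1280.0, 1.0], [1350.0, -0.6], [1420.0, 0.3]]),
        7.0, grid,
    )
    b = broaden(
        StickSpectrum([[1285.0, 0.9], [1355.0, -0.7], [1430.0, 0.2]]),
        7.0, grid,
    )
    return a, b


def test_rmsd_zero_on_identity_and_scale_invariant(rng):
    a, b = _two_spectra(rng)
    assert spectrum_rmsd(a, a) == 0.0
    doubled = Spectrum(a.grid, 2.0 * a.intensity)
    assert spectrum_rmsd(a, doubled) == 0.0
    assert np.isclose(
        spectrum_rmsd(a, b), spectrum_rmsd(Spectrum(a.grid, 5 * a.intensity), b)
    )


def test_rmsd_symmetry_and_oracle(rng):
    a, b = _two_spectra(rng)
    v1 = spectrum_rmsd(a, b, (1250.0, 1450.0))
    v2 = spectrum_rmsd(b, a, (1250.0, 1450.0))
    assert np.isclose(v1, v2, atol=1e-12)
    assert np.isclose(v1, rmsd_oracle(a, b, 1250.0, 1450.0), atol=1e-10)


def test_rmsd_depends_on_the_window(rng):
    a, b = _two_spectra(rng)
    full = spectrum_rmsd(a, b, (1250.0, 1450.0))
    central = spectrum_rmsd(a, b, (1330.0, 1380.0))
    assert not np.isclose(full, central)


def test_rmsd_rejects_empty_overlap():
    a = Spectrum(make_grid(1200, 1300), np.ones(101))
    b = Spectrum(make_grid(1400, 1500), np.ones(101))
    with pytest.raises(SpectrumError):
        spectrum_rmsd(a, b)


def test_grid_must_be_uniform_ascending():
    with pytest.raises(SpectrumError):
        Spectrum(np.array([1.0, 2.0, 4.0]), np.zeros(3))
    with pytest.raises(SpectrumError):
        Spectrum(np.array([2.0, 1.0, 0.0]), np.zeros(3))
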