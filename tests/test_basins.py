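"""Free-energy landscapes, basin detection, weighting, convergence."""

import numpy as np
import pytest

from shellpick.basins import (
    BasinSet,
    build_landscape,
    combine_weights,
    convergence_check,
    detect_basins,
    product_weights,
)


def histogram_oracle(samples, edges_x, edges_y):
    """Explicit double-loop 2-D histogram + Boltzmann inversion."""
    counts = np.zeros((len(edges_x) - 1, len(edges_y) - 1), dtype=int)
    for x, y in samples:
        i = np.searchsorted(edges_x, x, side="right") - 1
        j = np.searchsorted(edges_y, y, side="right") - 1
        if 0 <= i < counts.shape[0] and 0 <= j < counts.shape[1]:
            counts[i, j] += 1
    with np.errstate(divide="ignore"):
        g = -np.log(counts / counts.max())
    return counts, g


def test_uniform_counts_give_flat_landscape():
    # one sample per bin center -> all counts equal -> deltaG == 0
    proj = np.linspace(0.0, 1.0, 8)[:, None]
    fel = build_landscape(proj, dims=(0,), n_bins=8)
    assert fel.counts.sum() == 8
    assert np.allclose(fel.deltaG[fel.counts > 0], 0.0)


def test_closed_form_three_bin_landscape():
    """Counts 60/30/10 give deltaG 0, ln2, ln6 exactly."""
    proj = np.concatenate(
        [np.full(60, 0.5), np.full(30, 1.5), np.full(10, 2.5)]
    )[:, None]
    fel = build_landscape(proj, dims=(0,), n_bins=4)
    occupied = np.sort(fel.deltaG[fel.counts > 0])
    assert np.allclose(occupied, [0.0, np.log(2), np.log(6)], atol=1e-12)


def test_minimum_of_occupied_bins_is_zero(rng):
    proj = rng.normal(size=(500, 2))
    fel = build_landscape(proj, n_bins=16)
    assert np.isclose(fel.deltaG[fel.counts > 0].min(), 0.0)
    assert fel.counts.sum() == 500
    # empty bins carry the finite cap, not infinities
    assert np.isfinite(fel.deltaG).all()


def test_two_gaussian_surface_matches_histogram_oracle(rng):
    n = 10_000
    comp = rng.random(n) < 0.4
    samples = np.where(
        comp[:, None],
        rng.normal([-2.0, 0.0], 0.3, size=(n, 2)),
        rng.normal([2.0, 1.0], 0.3, size=(n, 2)),
    )
    fel = build_landscape(samples, n_bins=32)
    counts, g = histogram_oracle(
        samples, fel.bin_edges[0], fel.bin_edges[1]
    )
    assert np.array_equal(fel.counts, counts)
    occ = counts > 0
    assert np.allclose(fel.deltaG[occ], g[occ], atol=1e-12)


def test_single_gaussian_gives_one_basin(rng):
    proj = rng.normal(0.0, 0.5, size=(5000, 2))
    fel = build_landscape(proj, n_bins=32)
    bs = detect_basins(fel, g_cut=3.0)
    assert len(bs) == 1
    eligible = (fel.counts > 0) & (fel.deltaG <= 3.0)
    expected_p = fel.counts[eligible].sum() / 5000
    assert np.isclose(bs.basins[0].probability, expected_p, atol=1e-12)


def test_two_well_separated_gaussians_recover_weights(rng):
    n = 20_000
    comp = rng.random(n) < 0.3
    samples = np.where(
        comp[:, None],
        rng.normal([4.0, 4.0], 0.25, size=(n, 2)),
        rng.normal([-4.0, -4.0], 0.25, size=(n, 2)),
    )
    fel = build_landscape(samples, n_bins=64)
    bs = detect_basins(fel, g_cut=3.0).renormalize()
    assert len(bs) == 2
    p = np.sort(bs.probabilities)
    assert abs(p[0] - 0.3) < 0.02
    assert abs(p[1] - 0.7) < 0.02


def test_shallow_saddle_basins_merge():
    """Two minima joined by a saddle shallower than min_depth collapse
    into one basin."""
    from shellpick.basins import FreeEnergyLandscape

    # hand-built 1-D landscape: minima at bins 1 and 5, saddle at bin 3
    counts = np.array([5, 100, 60, 55, 70, 90, 5])
    g = -np.log(counts / counts.max())
    edges = [np.linspace(0, 7, 8)]
    frame_bins = np.repeat(np.arange(7), counts)
    proj = (frame_bins + 0.5)[:, None]
    fel = FreeEnergyLandscape(
        dims=(0,), bin_edges=edges, counts=counts, deltaG=g,
        temperature_K=300.0, cap=g.max() + 1, frame_bins=frame_bins,
        frame_projections=proj,
    )
    merged = detect_basins(fel, g_cut=10.0, min_depth=1.0)
    assert len(merged) == 1
    split = detect_basins(fel, g_cut=10.0, min_depth=0.01)
    assert len(split) == 2


def test_no_bin_under_cutoff_gives_empty_set(rng):
    proj = rng.normal(size=(100, 2))
    fel = build_landscape(proj, n_bins=8)
    with pytest.warns(UserWarning):
        bs = detect_basins(fel, g_cut=-1.0)
    assert len(bs) == 0


def test_representative_frame_lies_in_its_basin(rng):
    proj = np.concatenate(
        [rng.normal(-3, 0.3, size=(500, 2)), rng.normal(3, 0.3, size=(500, 2))]
    )
    fel = build_landscape(proj, n_bins=32)
    bs = detect_basins(fel)
    for b in bs:
        assert fel.frame_bins[b.representative_frame] in b.member_bins


def test_combine_weights_identity_and_product():
    import dataclasses

    from shellpick.basins import Basin

    basins = [
        Basin("A", frozenset({0}), 0.6, 0, 0, np.zeros(2)),
        Basin("B", frozenset({1}), 0.3, 1, 1, np.ones(2)),
        Basin("C", frozenset({2}), 0.1, 2, 2, 2 * np.ones(2)),
    ]
    bs = BasinSet(basins, 100, 4.0, 1.0)
    # identity: p_i = 1 leaves the (renormalized) weights unchanged
    conformers = combine_weights(1.0, bs)
    assert np.allclose([c.weight for c in conformers], [0.6, 0.3, 0.1])
    # product measure over three solute states sums to one
    states = {s: (w, bs) for s, w in
              zip("xyz", (0.6, 0.3, 0.1))}
    flat = product_weights(states)
    assert len(flat) == 9
    assert np.isclose(sum(c.weight for c in flat), 1.0, atol=1e-12)


def test_three_by_four_product_gives_twelve_conformers():
    from shellpick.basins import Basin

    basins = [
        Basin(lbl, frozenset({i}), p, i, i, np.array([i, 0.0]))
        for i, (lbl, p) in enumerate(
            zip("ABCD", (0.4, 0.3, 0.2, 0.1))
        )
    ]
    bs = BasinSet(basins, 10, 4.0, 1.0)
    flat = product_weights({"PII": (0.6, bs), "beta": (0.3, bs),
                            "alphaR": (0.1, bs)})
    assert len(flat) == 12
    assert np.isclose(sum(c.weight for c in flat), 1.0)


def test_convergence_single_basin_zero_deviation(rng):
    coords = np.zeros((600, 4, 3))
    base = rng.normal(size=(4, 3)) * 3
    coords[:] = base
    coords += rng.normal(0, 0.05, size=coords.shape)
    # bin count commensurate with 200-frame splits
    report = convergence_check(coords, n_splits=3, dims=(0, 1), n_bins=8)
    assert report.consistent
    assert report.basin_counts == [1, 1, 1]
    assert report.max_deviation < 1e-9  # single basin renormalized to 1


def test_convergence_flags_mismatched_basin_counts(rng):
    # block 1 unimodal, blocks 2-3 bimodal: counts differ -> flagged,
    # never silently paired
    base = rng.normal(size=(4, 3)) * 3.0
    coords = np.repeat(base[None], 600, axis=0)
    coords[np.arange(200, 600, 2), 0] += [6.0, 0.0, 0.0]
    coords = coords + rng.normal(0, 0.05, size=coords.shape)
    report = convergence_check(coords, n_splits=3, dims=(0, 1), n_bins=16)
    assert report.basin_counts[0] != report.basin_counts[1]
    assert not report.consistent
    assert np.isnan(report.max_deviation)
    assert report.probability_table == {}


def test_convergence_requires_enough_frames(rng):
    with pytest.raises(ValueError):
        convergence_check(rng.normal(size=(4, 3, 3)), n_splits=3)
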