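"""Reduction to site-bound solvent: quotas, greedy assignment, oracles."""

import itertools

import numpy as np
import pytest

from shellpick.emcs import emcs_extract
from shellpick.errors import InfeasibleReductionError, TopologyError
from shellpick.remcs import (
    AggregationCenter,
    greedy_assign,
    remcs_reduce,
    suggest_centers,
)
from shellpick.synthetic import (
    ALANINE_COORDS,
    ALANINE_ELEMENTS,
    ALANINE_NAMES,
    alanine_centers,
    alanine_water_spec,
    generate,
)
from shellpick.trajectory_io import SOLUTE, AtomRecord, Trajectory


def naive_greedy(dist, quotas):
    """Independent re-implementation of the global greedy rule: repeatedly
    take the smallest remaining (distance, center, solvent) entry."""
    pairs = sorted(
        (dist[c, s], c, s)
        for c in range(dist.shape[0])
        for s in range(dist.shape[1])
    )
    filled = [[] for _ in quotas]
    taken = set()
    for d, c, s in pairs:
        if s in taken or len(filled[c]) >= quotas[c]:
            continue
        filled[c].append(s)
        taken.add(s)
    return filled


def exhaustive_min_total(dist, quotas):
    """Exhaustive conflict-free assignment minimizing total distance
    (unique-optimum instances only)."""
    m = dist.shape[1]
    best, best_cost = None, np.inf
    for solvents in itertools.permutations(range(m), sum(quotas)):
        pos = 0
        cost = 0.0
        chosen = []
        for c, q in enumerate(quotas):
            sub = solvents[pos : pos + q]
            # within a center, order is irrelevant to the set; canonicalize
            if list(sub) != sorted(sub):
                cost = np.inf
                break
            chosen.append(sub)
            cost += sum(dist[c, s] for s in sub)
            pos += q
        if cost < best_cost:
            best_cost, best = cost, [set(c) for c in chosen]
    return best, best_cost


@pytest.mark.parametrize("seed", range(8))
def test_greedy_matches_independent_reimplementation(seed):
    rng = np.random.default_rng(seed)
    dist = rng.uniform(1, 10, size=(3, 6))
    quotas = [2, 1, 2]
    assert greedy_assign(dist, quotas) == naive_greedy(dist, quotas)


@pytest.mark.parametrize("seed", range(6))
def test_greedy_on_separated_clusters_equals_exhaustive_optimum(seed):
    """When each center has a clearly nearest group, the greedy
    assignment coincides with the exhaustive minimum-total-distance one
    (<= 6 solvent molecules, full enumeration)."""
    rng = np.random.default_rng(100 + seed)
    dist = rng.uniform(8, 10, size=(2, 5))
    # molecules 0,1 near center 0; molecules 2,3 near center 1
    dist[0, [0, 1]] = rng.uniform(1, 2, size=2)
    dist[1, [2, 3]] = rng.uniform(1, 2, size=2)
    quotas = [2, 2]
    greedy_sets = [set(g) for g in greedy_assign(dist, quotas)]
    oracle_sets, _ = exhaustive_min_total(dist, quotas)
    assert greedy_sets == oracle_sets


@pytest.fixture(scope="module")
def alanine_cluster():
    spec = alanine_water_spec(60, seed=5)
    traj, labels, _ = generate(spec)
    return emcs_extract(traj, M=10), labels


def test_alanine_reduction_keeps_seven_waters(alanine_cluster):
    """The aqueous-alanine protocol (4 carboxylate + 3 ammonium waters)
    yields a 7-water cluster in every frame."""
    cluster, _ = alanine_cluster
    reduced = remcs_reduce(cluster, alanine_centers())
    assert reduced.k == 7
    assert reduced.solvent_ids.shape[1] == 7
    labels = [lbl for lbl, _ in reduced.slot_assignment]
    assert labels == ["COO"] * 4 + ["NH3"] * 3


def test_zero_quota_center_gives_solute_only_frames(alanine_cluster):
    cluster, _ = alanine_cluster
    center = AggregationCenter(np.array([11, 12]), 0, "COO")
    reduced = remcs_reduce(cluster, [center])
    assert reduced.k == 0
    assert reduced.all_coords().shape[1] == len(cluster.solute_topology)


def test_reduction_is_a_restriction(alanine_cluster):
    cluster, _ = alanine_cluster
    reduced = remcs_reduce(cluster, alanine_centers())
    for f in range(cluster.n_frames):
        assert set(reduced.solvent_ids[f]) <= set(cluster.solvent_ids[f])


def test_retained_set_invariant_under_solvent_permutation(alanine_cluster):
    cluster, _ = alanine_cluster
    reduced = remcs_reduce(cluster, alanine_centers())
    # permute the EMCS slot listing of every frame
    rng = np.random.default_rng(0)
    perm = rng.permutation(cluster.M)
    import dataclasses

    shuffled = dataclasses.replace(
        cluster,
        solvent_coords=cluster.solvent_coords[:, perm],
        solvent_ids=cluster.solvent_ids[:, perm],
    )
    reduced2 = remcs_reduce(shuffled, alanine_centers())
    for f in range(cluster.n_frames):
        assert set(reduced.solvent_ids[f]) == set(reduced2.solvent_ids[f])


def test_quota_increase_keeps_previous_assignments(alanine_cluster):
    """Greedy stability: raising one quota by 1 does not evict molecules
    retained for the other center."""
    cluster, _ = alanine_cluster
    small = remcs_reduce(cluster, alanine_centers(3, 3))
    grown = remcs_reduce(cluster, alanine_centers(4, 3))
    for f in range(cluster.n_frames):
        nh3_small = {m for m, (lbl, _) in
                     zip(small.solvent_ids[f], small.slot_assignment)
                     if lbl == "NH3"}
        nh3_grown = {m for m, (lbl, _) in
                     zip(grown.solvent_ids[f], grown.slot_assignment)
                     if lbl == "NH3"}
        assert nh3_small <= nh3_grown | nh3_small  # sets exist
        assert nh3_small == nh3_grown


def test_infeasible_quota_rejected(alanine_cluster):
    cluster, _ = alanine_cluster
    with pytest.raises(InfeasibleReductionError):
        remcs_reduce(cluster, alanine_centers(8, 3))


def test_center_outside_solute_rejected(alanine_cluster):
    cluster, _ = alanine_cluster
    with pytest.raises(TopologyError):
        remcs_reduce(cluster, [AggregationCenter(np.array([99]), 1, "bad")])


def _records(names, elements):
    return [
        AtomRecord(i, el, nm, 0, SOLUTE, "MOL", 1)
        for i, (nm, el) in enumerate(zip(names, elements))
    ]


def test_suggest_centers_alanine_zwitterion():
    """With coordinates, the two carboxylate oxygens group into one
    candidate center and the ammonium nitrogen into another."""
    records = _records(ALANINE_NAMES, ALANINE_ELEMENTS)
    centers = suggest_centers(records, ALANINE_COORDS)
    groups = {frozenset(c.center_atoms.tolist()) for c in centers}
    assert frozenset({11, 12}) in groups  # O + OXT share the carboxyl C
    assert frozenset({0}) in groups  # N
    assert len(centers) == 2


def test_suggest_centers_all_carbon_solute():
    records = _records(["C1", "C2", "C3"], ["C", "C", "C"])
    assert suggest_centers(records, np.zeros((3, 3))) == []


def test_suggest_centers_hydroxyl_and_amino_groups():
    """An amino-indanol-like pattern: hydroxyl O and amino N on different
    carbons give two separate centers."""
    names = ["C1", "C2", "O1", "N1"]
    elements = ["C", "C", "O", "N"]
    coords = np.array(
        [[0.0, 0, 0], [1.5, 0, 0], [-0.7, 1.2, 0], [2.2, 1.2, 0]]
    )
    centers = suggest_centers(_records(names, elements), coords)
    groups = {frozenset(c.center_atoms.tolist()) for c in centers}
    assert groups == {frozenset({2}), frozenset({3})}
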