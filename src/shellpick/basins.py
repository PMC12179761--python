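"""Free-energy landscapes on essential-eigenvector projections, basin
detection and statistical weighting of cluster conformations.

The landscape is the Boltzmann inversion of the projection histogram,
Delta G(bin) = -ln(count / count_max) in kT units, so the most populated
bin sits at zero.  Basins are found by steepest descent on the bin grid:
every occupied bin below a free-energy cutoff descends to its lowest
neighbor until a local minimum is reached; shallow minima (depth below the
lowest connecting saddle smaller than ``min_depth``) are merged.  Each
basin's statistical weight is the fraction of trajectory frames falling in
its bins; its representative conformation is the frame whose projection
lies nearest the basin's mode bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .essential_dynamics import EDResult, ed_analyze


@dataclass
class FreeEnergyLandscape:
    """Histogram-based Delta G surface on 1 or 2 eigenvector projections.

    ``deltaG`` is in kT units; empty bins carry the finite ``cap`` value
    (max occupied Delta G + 1), never an infinity.  ``frame_bins`` holds
    each frame's flat bin index, ``frame_projections`` the projections the
    landscape was built from.
    """

    dims: tuple[int, ...]
    bin_edges: list[np.ndarray]
    counts: np.ndarray
    deltaG: np.ndarray
    temperature_K: float
    cap: float
    frame_bins: np.ndarray
    frame_projections: np.ndarray

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def n_frames(self) -> int:
        return self.frame_projections.shape[0]

    def bin_center(self, flat_index: int) -> np.ndarray:
        idx = np.unravel_index(flat_index, self.shape)
        return np.array(
            [
                0.5 * (self.bin_edges[d][i] + self.bin_edges[d][i + 1])
                for d, i in enumerate(idx)
            ]
        )

    def export_text(self, path) -> None:
        """Gridded text export: bin-center coordinates and Delta G (kT)."""
        with open(path, "w") as fh:
            cols = " ".join(f"proj_ev{d}" for d in self.dims)
            fh.write(f"# {cols} deltaG_kT\n")
            for flat in range(self.counts.size):
                center = self.bin_center(flat)
                g = self.deltaG.reshape(-1)[flat]
                fh.write(
                    " ".join(f"{c:12.5f}" for c in center) + f" {g:12.6f}\n"
                )


def build_landscape(
    projections,
    dims: tuple[int, ...] = (0, 1),
    n_bins: int = 64,
    temperature_K: float = 300.0,
) -> FreeEnergyLandscape:
    """Boltzmann-inverted histogram of projections on 1 or 2 eigenvectors.

    ``projections`` may be an :class:`EDResult` or an array; ``dims``
    selects the eigenvector columns.  The histogram range per dimension is
    the data range expanded by 5%.
    """
    if isinstance(projections, EDResult):
        data = projections.projections
    else:
        data = np.asarray(projections, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
        dims = tuple(dims[:1]) if dims else (0,)
    dims = tuple(int(d) for d in dims)
    if not 1 <= len(dims) <= 2:
        raise ValueError("landscapes support 1 or 2 dimensions")
    if n_bins < 4:
        raise ValueError("need at least 4 bins per dimension")
    sel = data[:, list(dims)] if data.shape[1] > 1 or dims != (0,) else data
    edges = []
    for d in range(sel.shape[1]):
        lo, hi = sel[:, d].min(), sel[:, d].max()
        span = hi - lo
        if span == 0:
            warnings.warn(
                "all projections identical along one dimension; "
                "degenerate single-bin landscape"
            )
            span = 1.0
        pad = 0.025 * span
        edges.append(np.linspace(lo - pad, hi + pad, n_bins + 1))
    counts, _ = np.histogramdd(sel, bins=edges)
    counts = counts.astype(int)
    cmax = counts.max()
    with np.errstate(divide="ignore"):
        deltaG = np.where(counts > 0, -np.log(counts / cmax), np.nan)
    cap = float(np.nanmax(deltaG) + 1.0)
    deltaG = np.where(np.isnan(deltaG), cap, deltaG)
    per_dim = [
        np.clip(np.digitize(sel[:, d], edges[d]) - 1, 0, n_bins - 1)
        for d in range(sel.shape[1])
    ]
    frame_bins = np.ravel_multi_index(per_dim, counts.shape)
    return FreeEnergyLandscape(
        dims=dims[: sel.shape[1]],
        bin_edges=edges,
        counts=counts,
        deltaG=deltaG,
        temperature_K=float(temperature_K),
        cap=cap,
        frame_bins=frame_bins,
        frame_projections=sel.copy(),
    )


@dataclass
class Basin:
    """One free-energy basin: member bins (flat indices), its statistical
    weight, the mode bin and the representative frame."""

    label: str
    member_bins: frozenset
    probability: float
    representative_frame: int
    mode_bin: int
    mode_center: np.ndarray = field(default=None, repr=False)
    min_deltaG: float = 0.0


@dataclass
class BasinSet:
    """Basins of one landscape.  Probabilities are member-frame fractions
    of all frames; frames above the cutoff stay unassigned, so the sum is
    the retained-frame fraction (<= 1).  ``renormalize()`` rescales the
    weights to sum to one before spectrum assembly."""

    basins: list[Basin]
    total_frames: int
    g_cut: float
    min_depth: float
    renormalized: bool = False

    def __len__(self) -> int:
        return len(self.basins)

    def __iter__(self):
        return iter(self.basins)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([b.probability for b in self.basins])

    @property
    def retained_fraction(self) -> float:
        return float(self.probabilities.sum())

    def renormalize(self) -> "BasinSet":
        total = self.retained_fraction
        if total == 0:
            return self
        basins = [
            replace(b, probability=b.probability / total) for b in self.basins
        ]
        return BasinSet(basins, self.total_frames, self.g_cut,
                        self.min_depth, renormalized=True)

    def report(self) -> dict:
        return {
            "n_basins": len(self.basins),
            "g_cut_kT": self.g_cut,
            "min_depth_kT": self.min_depth,
            "retained_fraction": self.retained_fraction,
            "renormalized": self.renormalized,
            "basins": [
                {
                    "label": b.label,
                    "probability": b.probability,
                    "representative_frame": int(b.representative_frame),
                    "mode_bin": int(b.mode_bin),
                    "mode_center": [float(x) for x in b.mode_center],
                }
                for b in self.basins
            ],
        }


def _neighbors(shape: tuple[int, ...]):
    """Flat-index neighbor offsets: +-1 in 1D, the 8-neighborhood in 2D."""
    if len(shape) == 1:
        deltas = [(-1,), (1,)]
    else:
        deltas = [d for d in product((-1, 0, 1), repeat=2) if d != (0, 0)]
    return deltas


def _descend(fel: FreeEnergyLandscape, eligible: np.ndarray) -> np.ndarray:
    """Steepest-descent root (flat bin index) of every eligible bin.

    Each bin moves to the neighbor with the lowest (Delta G, flat index)
    pair if that is lower than its own — the lexicographic tie-break
    resolves plateaus toward the lower bin index deterministically.
    """
    shape = fel.shape
    g = fel.deltaG.reshape(-1)
    deltas = _neighbors(shape)
    roots = np.full(g.size, -1, dtype=int)
    flat_eligible = np.flatnonzero(eligible.reshape(-1))

    def best_step(flat: int) -> int:
        idx = np.unravel_index(flat, shape)
        best = (g[flat], flat)
        for d in deltas:
            nidx = tuple(i + o for i, o in zip(idx, d))
            if any(i < 0 or i >= s for i, s in zip(nidx, shape)):
                continue
            nflat = int(np.ravel_multi_index(nidx, shape))
            if not eligible.reshape(-1)[nflat]:
                continue
            cand = (g[nflat], nflat)
            if cand < best:
                best = cand
        return best[1]

    for start in flat_eligible:
        path = []
        cur = int(start)
        while roots[cur] == -1:
            path.append(cur)
            nxt = best_step(cur)
            if nxt == cur:
                roots[cur] = cur
                break
            cur = nxt
        root = roots[cur]
        for p in path:
            roots[p] = root
    return roots


def _saddles(
    fel: FreeEnergyLandscape, roots: np.ndarray, eligible: np.ndarray
) -> dict[tuple[int, int], float]:
    """Lowest connecting saddle between each pair of adjacent basins:
    min over adjacent cross-basin bin pairs of max(Delta G_a, Delta G_b)."""
    shape = fel.shape
    g = fel.deltaG.reshape(-1)
    deltas = _neighbors(shape)
    saddles: dict[tuple[int, int], float] = {}
    for flat in np.flatnonzero(eligible.reshape(-1)):
        idx = np.unravel_index(flat, shape)
        for d in deltas:
            nidx = tuple(i + o for i, o in zip(idx, d))
            if any(i < 0 or i >= s for i, s in zip(nidx, shape)):
                continue
            nflat = int(np.ravel_multi_index(nidx, shape))
            if not eligible.reshape(-1)[nflat]:
                continue
            ra, rb = roots[flat], roots[nflat]
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            h = max(g[flat], g[nflat])
            if key not in saddles or h < saddles[key]:
                saddles[key] = h
    return saddles


def detect_basins(
    fel: FreeEnergyLandscape,
    g_cut: float = 4.0,
    min_depth: float = 1.0,
    min_population: float = 0.01,
) -> BasinSet:
    """Grid steepest-descent basin detection with shallow-minimum merging.

    Occupied bins with Delta G <= ``g_cut`` are assigned to the local
    minimum reached by steepest descent; a basin whose depth below its
    lowest connecting saddle is smaller than ``min_depth`` is merged into
    the basin across that saddle (ties toward the deeper one).  A basin
    with no connecting saddle through eligible bins can only be left at
    the cutoff level, so its effective saddle is ``g_cut``; if that
    leaves it shallower than ``min_depth`` it merges into the nearest
    deeper basin — this absorbs the sampling speckle that sparse
    histograms produce near the cutoff.  Finally, basins holding less
    than ``min_population`` of the frames (default 1%) are folded into
    their nearest deeper neighbor: Boltzmann inversion of low-count bins
    produces spurious single-frame minima that no depth rule can
    distinguish from real ones.  Basin labels A, B, ... follow
    descending probability.
    """
    eligible = (fel.counts > 0) & (fel.deltaG <= g_cut)
    if not eligible.any():
        warnings.warn("no bin below g_cut; returning an empty basin set")
        return BasinSet([], fel.n_frames, g_cut, min_depth)
    roots = _descend(fel, eligible)
    g = fel.deltaG.reshape(-1)

    # merge shallow basins until every remaining basin is deep enough
    while True:
        saddles = _saddles(fel, roots, eligible)
        basin_roots = sorted({int(r) for r in roots[roots >= 0]})
        if len(basin_roots) <= 1:
            break
        lowest: dict[int, tuple[float, int]] = {}
        for (ra, rb), h in saddles.items():
            for own, other in ((ra, rb), (rb, ra)):
                # tie-break toward the deeper partner, then lower index
                cand = (h, g[other], other)
                if own not in lowest or cand < (
                    lowest[own][0], g[lowest[own][1]], lowest[own][1]
                ):
                    lowest[own] = (h, other)
        for r in basin_roots:
            if r in lowest:
                continue
            # isolated basin: escape is only possible at the cutoff;
            # partner is the nearest deeper basin by root-bin distance
            partners = [
                (np.linalg.norm(fel.bin_center(r) - fel.bin_center(o)), o)
                for o in basin_roots
                if o != r and g[o] <= g[r]
            ]
            if partners:
                lowest[r] = (g_cut, min(partners)[1])
        shallow = []
        for r in basin_roots:
            if r not in lowest:
                continue  # deepest isolated basin: keep
            depth = lowest[r][0] - g[r]
            if depth < min_depth:
                shallow.append((depth, g[r] == 0.0, -g[r], r))
        if not shallow:
            break
        # merge the shallowest first; prefer removing the less deep basin
        shallow.sort()
        _, _, _, victim = shallow[0]
        target = lowest[victim][1]
        # keep the deeper of the two as the surviving root
        if g[target] > g[victim]:
            victim, target = target, victim
        roots[roots == victim] = target

    basin_roots = sorted({int(r) for r in roots[roots >= 0]})
    frame_roots = np.where(
        eligible.reshape(-1)[fel.frame_bins], roots[fel.frame_bins], -1
    )

    # fold negligible-population basins into their nearest deeper neighbor
    while len(basin_roots) > 1:
        pops = {r: int((frame_roots == r).sum()) for r in basin_roots}
        victims = [
            r for r in basin_roots
            if pops[r] < min_population * fel.n_frames
        ]
        if not victims:
            break
        victim = min(victims, key=lambda r: (pops[r], r))
        partners = [
            (np.linalg.norm(fel.bin_center(victim) - fel.bin_center(o)), o)
            for o in basin_roots
            if o != victim and pops[o] >= pops[victim]
        ]
        if not partners:
            break
        target = min(partners)[1]
        roots[roots == victim] = target
        frame_roots[frame_roots == victim] = target
        basin_roots.remove(victim)
    basins = []
    for r in basin_roots:
        members = frozenset(int(i) for i in np.flatnonzero(roots == r))
        member_frames = np.flatnonzero(frame_roots == r)
        prob = len(member_frames) / fel.n_frames
        member_list = np.array(sorted(members))
        mode = int(member_list[np.lexsort((member_list, g[member_list]))[0]])
        center = fel.bin_center(mode)
        d = np.linalg.norm(
            fel.frame_projections[member_frames] - center, axis=1
        )
        rep = int(member_frames[np.argmin(d)]) if member_frames.size else -1
        basins.append(
            Basin("", members, prob, rep, mode, center, float(g[mode]))
        )
    basins.sort(key=lambda b: -b.probability)
    labels = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for i, b in enumerate(basins):
        b.label = labels[i] if i < len(labels) else f"B{i}"
    return BasinSet(basins, fel.n_frames, g_cut, min_depth)


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

@dataclass
class WeightedConformer:
    """A representative cluster conformation with its final weight
    w = p_i (solute basin) x p_ji (cluster basin)."""

    label: str
    weight: float
    representative_frame: int
    solute_label: str = ""


def combine_weights(
    solute_weight: float,
    cluster_basins: BasinSet,
    renormalize: bool = True,
    solute_label: str = "",
) -> list[WeightedConformer]:
    """Attach w_ji = p_i * p_ji to each cluster basin's representative.

    With ``renormalize`` (default) the cluster basin weights are first
    rescaled to sum to one, so a full product measure over solute states
    sums to one as well.
    """
    if not 0 <= solute_weight <= 1:
        raise ValueError("solute weight must lie in [0, 1]")
    bs = cluster_basins.renormalize() if renormalize else cluster_basins
    return [
        WeightedConformer(
            label=(f"{solute_label}/{b.label}" if solute_label else b.label),
            weight=solute_weight * b.probability,
            representative_frame=b.representative_frame,
            solute_label=solute_label,
        )
        for b in bs
    ]


def product_weights(
    solute_states: dict[str, tuple[float, BasinSet]],
    renormalize: bool = True,
) -> list[WeightedConformer]:
    """Flatten a {solute label: (p_i, cluster BasinSet)} map into one
    weighted conformer list (the i x j product measure)."""
    out: list[WeightedConformer] = []
    for label, (p_i, bs) in solute_states.items():
        out.extend(combine_weights(p_i, bs, renormalize, label))
    return out


# ---------------------------------------------------------------------------
# convergence check
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Per-split basin sets plus the matched-probability comparison."""

    split_basin_sets: list[BasinSet]
    basin_counts: list[int]
    consistent: bool
    probability_table: dict[str, list[float]]
    max_deviation: float

    def report(self) -> dict:
        return {
            "n_splits": len(self.split_basin_sets),
            "basin_counts": self.basin_counts,
            "consistent": self.consistent,
            "probability_table": self.probability_table,
            "max_deviation": self.max_deviation,
        }


def convergence_check(
    cluster,
    n_splits: int = 3,
    dims: tuple[int, ...] = (0, 1),
    n_bins: int = 64,
    temperature_K: float = 300.0,
    g_cut: float = 4.0,
    min_depth: float = 1.0,
    fit_subset=None,
    analyze_subset=None,
    reference="first",
    renormalize: bool = True,
) -> ConvergenceReport:
    """Stationarity check: rerun the full ED + landscape + basin pipeline
    on ``n_splits`` contiguous trajectory blocks and compare basin
    weights.

    Basins are matched across splits by mode-bin proximity in projection
    space, but only when every split finds the same number of basins;
    otherwise the report flags the mismatch (``consistent=False``) and no
    deviation is computed.
    """
    from .essential_dynamics import _coerce_coords

    coords, default_fit = _coerce_coords(cluster)
    n = coords.shape[0]
    if n < 2 * n_splits:
        raise ValueError(
            f"{n} frames cannot support {n_splits} splits of >= 2 frames"
        )
    bounds = np.linspace(0, n, n_splits + 1).astype(int)
    fit_idx = default_fit if fit_subset is None else fit_subset
    basin_sets = []
    for s in range(n_splits):
        block = coords[bounds[s] : bounds[s + 1]]
        ed = ed_analyze(block, fit_subset=fit_idx,
                        analyze_subset=analyze_subset, reference=reference)
        fel = build_landscape(ed, dims=dims, n_bins=n_bins,
                              temperature_K=temperature_K)
        bs = detect_basins(fel, g_cut=g_cut, min_depth=min_depth)
        basin_sets.append(bs.renormalize() if renormalize else bs)
    counts = [len(bs) for bs in basin_sets]
    consistent = len(set(counts)) == 1 and counts[0] > 0
    if not consistent:
        return ConvergenceReport(basin_sets, counts, False, {}, float("nan"))
    ref_bs = basin_sets[0]
    table: dict[str, list[float]] = {
        b.label: [b.probability] for b in ref_bs
    }
    for bs in basin_sets[1:]:
        used = set()
        for rb in ref_bs:
            best, best_d = None, np.inf
            for b in bs:
                if id(b) in used:
                    continue
                d = np.linalg.norm(b.mode_center - rb.mode_center)
                if d < best_d:
                    best, best_d = b, d
            used.add(id(best))
            table[rb.label].append(best.probability)
    max_dev = max(max(v) - min(v) for v in table.values())
    return ConvergenceReport(basin_sets, counts, True, table, float(max_dev))
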