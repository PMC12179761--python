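"""Config-driven pipeline runner chaining the extraction stages.

Stages communicate through files in the run directory so any stage can be
re-run from its predecessor's output; the resolved configuration, a JSON
run report (solvent counts at each reduction, basin weights, eigenvalue
fractions, convergence deviations) and a log are always written alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .basins import build_landscape, convergence_check, detect_basins
from .emcs import ClusterTrajectory, determine_M, emcs_extract
from .errors import ShellpickError, TopologyError
from .essential_dynamics import ed_analyze, essential_count
from .qm_glue import DMSO, WATER, build_constraints
from .remcs import AggregationCenter, remcs_reduce
from .spectra import Spectrum, assemble, broaden, normalize, spectrum_rmsd
from .synthetic import alanine_water_spec, generate
from .trajectory_io import Trajectory, read_trajectory, write_trajectory

log = logging.getLogger("shellpick")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "shellpick_run",
    "stages": ["emcs", "remcs", "ed", "basins"],
    "input": {
        "trajectory": None,
        "format": None,
        "solvent": ["SOL", "WAT", "HOH"],
        "synthetic": None,  # {"n_frames": ..., "sigma": ..., "n_bulk": ...}
    },
    "emcs": {
        "M": None,
        "padding": 3.0,
        "scale": 1.0,
        "statistic": "median",
        "reference_point": "cog",
    },
    "remcs": {
        "centers": [],  # [{"label": ..., "atoms": "name O OXT" | [..], "n": int}]
        "distance_mode": "nearest_atom",
    },
    "ed": {"fit": "solute", "reference": "first", "variance_fraction": 0.6},
    "basins": {
        "dims": [0, 1],
        "n_bins": 64,
        "temperature_K": 300.0,
        "g_cut": 4.0,
        "min_depth": 1.0,
        "renormalize": True,
    },
    "convergence": {"enabled": False, "n_splits": 3},
    "constraints": {
        "enabled": False,
        "solute_torsions": [],
        "solvent": "water",
    },
    "spectrum": {
        "enabled": False,
        "sticks": [],
        "weights": "basins",  # or an explicit list
        "bandwidth": 7.0,
        "grid": None,  # [lo, hi] or [lo, hi, spacing]
        "reference": None,
        "rmsd_range": None,
        "frequency_scale": 1.0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Resolved stage parameters for a full pipeline run."""

    data: dict = field(default_factory=lambda: _merge(DEFAULT_CONFIG, {}))
    version: str = __version__

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(data=_merge(DEFAULT_CONFIG, doc))

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        return cls(data=_merge(DEFAULT_CONFIG, doc or {}))

    def __getitem__(self, key):
        return self.data[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"version": self.version, **self.data}, sort_keys=False
        )


def resolve_centers(
    specs: list[dict], cluster: ClusterTrajectory
) -> list[AggregationCenter]:
    """Center declarations -> AggregationCenter; ``atoms`` is either an
    explicit solute index list or a ``"name A B"`` selection."""
    names = [a.name for a in cluster.solute_topology]
    out = []
    for spec in specs:
        sel = spec["atoms"]
        if isinstance(sel, str):
            tokens = sel.split()
            if not tokens or tokens[0] != "name":
                raise TopologyError(
                    f"center {spec.get('label')!r}: selection {sel!r} must "
                    "be 'name A B ...' or an index list"
                )
            wanted = set(tokens[1:])
            idx = [i for i, n in enumerate(names) if n in wanted]
            if not idx:
                raise TopologyError(
                    f"center {spec.get('label')!r}: selection {sel!r} "
                    "matches no solute atom"
                )
        else:
            idx = [int(i) for i in sel]
        out.append(
            AggregationCenter(np.array(idx), int(spec["n"]),
                              str(spec.get("label", "")))
        )
    return out


def _load_input(cfg: RunConfig) -> tuple[Trajectory, dict]:
    inp = cfg["input"]
    if inp.get("synthetic") is not None:
        syn = dict(inp["synthetic"])
        n_frames = int(syn.pop("n_frames", 2000))
        spec = alanine_water_spec(
            n_frames=n_frames, seed=int(cfg["seed"]), **syn
        )
        traj, labels, names = generate(spec)
        log.info(
            "synthetic input: %d frames, %d solvent molecules, seed %d",
            traj.n_frames, traj.n_solvent, cfg["seed"],
        )
        return traj, {"synthetic_labels": names}
    if not inp.get("trajectory"):
        raise ShellpickError("config names neither a trajectory nor a "
                             "synthetic input")
    traj = read_trajectory(
        inp["trajectory"], inp.get("format"), inp.get("solvent") or ("SOL",)
    )
    log.info(
        "read %s: %d frames, %d atoms, %d solvent molecules",
        inp["trajectory"], traj.n_frames, traj.n_atoms, traj.n_solvent,
    )
    return traj, {}


def run_pipeline(config: RunConfig, outdir=None) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"version": config.version, "seed": config["seed"]}
    stages = list(config["stages"])
    try:
        (outdir / "resolved_config.yml").write_text(config.to_yaml())
        cluster = None
        reduced = None
        ed = None
        basin_set = None
        if {"emcs", "remcs", "ed", "basins", "constraints"} & set(stages):
            traj, extra = _load_input(config)
            report.update(extra)
            report["n_solvent_source"] = traj.n_solvent
        if "emcs" in stages:
            e = config["emcs"]
            m = e["M"] or determine_M(
                traj, e["padding"], e["scale"], e["statistic"],
                e["reference_point"],
            )
            cluster = emcs_extract(
                traj, m, e["padding"], e["scale"], e["statistic"],
                e["reference_point"],
            )
            cluster.save(outdir / "cluster.h5")
            report["M"] = cluster.M
            log.info("emcs: N=%d -> M=%d", traj.n_solvent, cluster.M)
        if "remcs" in stages:
            if cluster is None:
                cluster = ClusterTrajectory.load(outdir / "cluster.h5")
            centers = resolve_centers(config["remcs"]["centers"], cluster)
            if not centers:
                raise ShellpickError("remcs stage needs at least one center")
            reduced = remcs_reduce(
                cluster, centers, config["remcs"]["distance_mode"]
            )
            reduced.save(outdir / "reduced.h5")
            report["k"] = reduced.k
            log.info("remcs: M=%d -> k=%d", cluster.M, reduced.k)
        if "ed" in stages:
            target = reduced if reduced is not None else cluster
            if target is None:
                raise ShellpickError("ed stage needs an emcs/remcs cluster")
            fit_mode = config["ed"]["fit"]
            fit_subset = (
                target.solute_atom_indices if fit_mode == "solute" else None
            )
            ed = ed_analyze(
                target, fit_subset=fit_subset,
                reference=config["ed"]["reference"],
            )
            ed.save(outdir / "ed.h5")
            ed.export_eigenvalue_spectrum(outdir / "eigenvalues.tsv")
            d = essential_count(ed, config["ed"]["variance_fraction"])
            report["essential_count"] = d
            report["first2_fraction"] = ed.cumulative_fraction(2)
            log.info("ed: %d essential eigenvectors (%.0f%% threshold)",
                     d, 100 * config["ed"]["variance_fraction"])
        if "basins" in stages:
            if ed is None:
                raise ShellpickError("basins stage needs the ed stage")
            b = config["basins"]
            fel = build_landscape(
                ed, dims=tuple(b["dims"]), n_bins=b["n_bins"],
                temperature_K=b["temperature_K"],
            )
            fel.export_text(outdir / "landscape.tsv")
            basin_set = detect_basins(fel, b["g_cut"], b["min_depth"])
            if b["renormalize"]:
                basin_set = basin_set.renormalize()
            (outdir / "basins.json").write_text(
                json.dumps(basin_set.report(), indent=2)
            )
            report["basins"] = basin_set.report()
            log.info("basins: %d basins, weights %s", len(basin_set),
                     [round(p, 3) for p in basin_set.probabilities])
            target = reduced if reduced is not None else cluster
            reps = [bb.representative_frame for bb in basin_set]
            if target is not None and reps:
                rep_traj = target.to_trajectory()
                rep = Trajectory(
                    rep_traj.topology, rep_traj.coordinates[reps]
                )
                write_trajectory(rep, outdir / "representatives.pdb")
            if config["convergence"]["enabled"]:
                conv = convergence_check(
                    target, n_splits=config["convergence"]["n_splits"],
                    dims=tuple(b["dims"]), n_bins=b["n_bins"],
                    temperature_K=b["temperature_K"], g_cut=b["g_cut"],
                    min_depth=b["min_depth"], renormalize=b["renormalize"],
                )
                report["convergence"] = conv.report()
                log.info("convergence: max deviation %.4f",
                         conv.max_deviation)
        if config["constraints"]["enabled"]:
            target = reduced if reduced is not None else cluster
            if target is None or basin_set is None:
                raise ShellpickError(
                    "constraints stage needs clusters and basins"
                )
            template = {"water": WATER, "dmso": DMSO}[
                config["constraints"]["solvent"]
            ]
            torsions = [
                tuple(t) for t in config["constraints"]["solute_torsions"]
            ]
            for bb in basin_set:
                spec = build_constraints(
                    target, bb.representative_frame, torsions, template
                )
                spec.write(outdir / f"constraints_{bb.label}.txt")
        if config["spectrum"]["enabled"] or "spectrum" in stages:
            s = config["spectrum"]
            from .qm_glue import parse_sticks

            sticks = [parse_sticks(p) for p in s["sticks"]]
            if not sticks:
                raise ShellpickError("spectrum stage needs stick files")
            if s.get("frequency_scale", 1.0) != 1.0:
                sticks = [st.scaled(s["frequency_scale"]) for st in sticks]
            lo = min(st.lines[:, 0].min() for st in sticks) - 4 * s["bandwidth"]
            hi = max(st.lines[:, 0].max() for st in sticks) + 4 * s["bandwidth"]
            grid = tuple(s["grid"]) if s["grid"] else (lo, hi)
            curves = [broaden(st, s["bandwidth"], grid) for st in sticks]
            if s["weights"] == "basins":
                if basin_set is None or len(basin_set) != len(curves):
                    raise ShellpickError(
                        "spectrum weights 'basins' need one basin per "
                        "stick file"
                    )
                weights = basin_set.renormalize().probabilities
            else:
                weights = np.asarray(s["weights"], dtype=float)
            total = normalize(assemble(curves, weights))
            total.write(outdir / "spectrum.tsv")
            report["spectrum"] = {"n_conformers": len(curves),
                                  "weights": [float(w) for w in weights]}
            if s["reference"]:
                ref = Spectrum.read(s["reference"])
                rng = tuple(s["rmsd_range"]) if s["rmsd_range"] else None
                rmsd = spectrum_rmsd(total, ref, rng)
                report["spectrum"]["rmsd_vs_reference"] = rmsd
                log.info("spectrum RMSD vs reference: %.2f", rmsd)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    except ShellpickError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise ShellpickError(f"pipeline failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
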