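"""Config-driven orchestration of the analysis stages.

A run config (YAML or dict) names the inputs (structure + trajectory files,
or a synthetic-generation block), an output directory and an ordered stage
list with per-stage parameters.  Every referenced selection is resolved
before any stage runs (fail fast); stages execute in the order given, a
failed stage aborts its dependents but independent stages still run, and a
consolidated JSON report records parameters, outputs and timings.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import yaml

from . import core_io, collective_motion, geometry_states, solvent_lipids, structural_metrics
from .core_io import AtomSelection, select
from .synthetic_data import SyntheticSpec, generate

logger = logging.getLogger("gsecdyn")


def _setup_logging(output_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {type(h) for h in logger.handlers}
    if logging.StreamHandler not in have:
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(output_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    logger.addHandler(fh)


class StageError(RuntimeError):
    pass


class PipelineContext:
    """Holds the loaded system/trajectory and intermediate stage products."""

    def __init__(self, system, trajectory, output_dir: Path, ground_truth=None):
        self.system = system
        self.trajectory = trajectory
        self.output_dir = output_dir
        self.ground_truth = ground_truth
        self.segmentation = None
        self.aligned: dict[str, object] = {}

    def sel(self, expression: str) -> AtomSelection:
        return select(self.system, expression)


def _load_inputs(config: dict, output_dir: Path) -> PipelineContext:
    inputs = config.get("inputs") or {}
    if "synthetic" in inputs:
        syn = dict(inputs["synthetic"])
        seed = int(syn.pop("seed", 0))
        spec_kwargs = {}
        if "n_frames" in syn:
            from .synthetic_data import TransitionSpec
            n = int(syn.pop("n_frames"))
            spec_kwargs["n_frames"] = n
            # keep the transition at the study's halfway point for any length
            spec_kwargs["transition"] = TransitionSpec(frame=int(syn.pop("transition_frame", n // 2)))
        if not syn.get("solvent", True):
            spec_kwargs["solvent"] = None
        if not syn.get("lipids", True):
            spec_kwargs["lipids"] = None
        spec = SyntheticSpec(**spec_kwargs)
        system, traj, truth = generate(spec, seed)
        return PipelineContext(system, traj, output_dir, ground_truth=truth)
    seg_cfg = None
    if inputs.get("segments"):
        seg_cfg = core_io.load_segment_config(inputs["segments"])
    if "structure" not in inputs:
        raise StageError("config must provide inputs.structure or inputs.synthetic")
    system, coords = core_io.load_structure(inputs["structure"], seg_cfg)
    if inputs.get("trajectory"):
        traj = core_io.load_trajectory(
            inputs["trajectory"], system,
            frame_period=seg_cfg.frame_period if seg_cfg else None,
            topology=inputs["structure"])
    else:
        traj = core_io.Trajectory(coords[None], frame_period=1.0)
    return PipelineContext(system, traj, output_dir)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_rmsd(ctx: PipelineContext, params: dict) -> dict:
    fit = ctx.sel(params.get("fit", "protein and name CA"))
    measure = ctx.sel(params.get("measure", params.get("fit", "protein and name CA")))
    series = structural_metrics.rmsd_series(
        ctx.trajectory, fit, measure, reference=params.get("reference", 0),
        label=params.get("label", "RMSD"))
    out = ctx.output_dir / f"rmsd_{params.get('name', 'default')}.tsv"
    core_io.write_timeseries(series, out)
    return {"table": str(out), "mean": float(series.values.mean()),
            "max": float(series.values.max())}

def _stage_heatmap(ctx: PipelineContext, params: dict) -> dict:
    fit = ctx.sel(params.get("fit", "protein and name CA"))
    ref = structural_metrics.mean_structure(ctx.trajectory, fit)
    rmap = structural_metrics.per_residue_rmsd(
        ctx.trajectory, ctx.system, ref, fit,
        atom_name=params.get("atom_name", "CA"), reference_tag="trajectory mean")
    out = ctx.output_dir / f"heatmap_{params.get('name', 'default')}.tsv"
    header = "\t".join(["residue"] + [str(f) for f in range(rmap.n_frames)])
    with open(out, "w") as fh:
        fh.write("# per-residue RMSD (Å); reference: %s\n%s\n" % (rmap.reference_tag, header))
        for r, row in zip(rmap.residues, rmap.values):
            fh.write(r + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    (ctx.output_dir / f"heatmap_{params.get('name', 'default')}.json").write_text(
        json.dumps({"residues": rmap.residues, "n_frames": rmap.n_frames,
                    "reference": rmap.reference_tag}))
    return {"table": str(out), "n_residues": len(rmap.residues)}

def _stage_pca(ctx: PipelineContext, params: dict) -> dict:
    fit = ctx.sel(params.get("fit", "protein and name CA"))
    measure = ctx.sel(params.get("measure", params.get("fit", "protein and name CA")))
    result = collective_motion.covariance_pca(ctx.trajectory, fit, measure)
    k = int(params.get("n_report", 3))
    out = ctx.output_dir / f"pca_{params.get('name', 'default')}.tsv"
    frac = np.cumsum(result.eigenvalues) / result.eigenvalues.sum()
    np.savetxt(out, np.column_stack([result.eigenvalues, frac]),
               header="eigenvalue_A2\tcumulative_fraction", delimiter="\t")
    return {"table": str(out),
            "variance_fractions": [float(collective_motion.variance_fraction(result, i))
                                   for i in range(1, k + 1)]}

def _stage_tilt(ctx: PipelineContext, params: dict) -> dict:
    fit = ctx.sel(params["fit"])
    helix = ctx.sel(params["helix"]) if "helix" in params else None
    mode = params.get("axis_mode", "helix")
    top = ctx.sel(params["top"]) if "top" in params else None
    bottom = ctx.sel(params["bottom"]) if "bottom" in params else None
    result = geometry_states.tilt_series(
        ctx.trajectory, fit, helix, axis_mode=mode, top=top, bottom=bottom,
        ddof=int(params.get("ddof", 1)))
    out = ctx.output_dir / f"tilt_{params.get('name', 'default')}.tsv"
    core_io.write_timeseries(
        core_io.TimeSeries(result.angles, "degrees", "tilt vs +z"), out)
    return {"table": str(out), "spread_deg": result.spread,
            "mean_deg": float(np.nanmean(result.angles))}

def _stage_states(ctx: PipelineContext, params: dict) -> dict:
    a = params.get("residue_a", {"subunit": "PS1", "resid": 257})
    b = params.get("residue_b", {"subunit": "PS1", "resid": 385})
    site = params.get("site", "CA")
    sel_a = geometry_states.residue_site(ctx.system, a["subunit"], a["resid"], site)
    sel_b = geometry_states.residue_site(ctx.system, b["subunit"], b["resid"], site)
    series = geometry_states.distance_series(
        ctx.trajectory, sel_a, sel_b,
        label=f"d({a['subunit']}:{a['resid']}-{b['subunit']}:{b['resid']}) {site}")
    seg = geometry_states.segment_states(
        series, buffer=int(params.get("buffer", 50)),
        window=int(params.get("window", 100)))
    ctx.segmentation = seg
    report = {
        "transition_frame": seg.transition_frame,
        "orientation_rule": seg.orientation_rule,
        "per_state": seg.per_state,
    }
    out = ctx.output_dir / "states.json"
    out.write_text(json.dumps(report, indent=2))
    core_io.write_timeseries(series, ctx.output_dir / "state_series.tsv")
    return {"report": str(out), **report}

def _stage_hydration(ctx: PipelineContext, params: dict) -> dict:
    waters = ctx.sel(params.get("waters", "WATER and name O"))
    anchor = ctx.sel(params["anchor"]) if "anchor" in params else None
    box = solvent_lipids.BoxSpec(
        center=params["center"], edges=params["edges"], anchor=anchor,
        name=params.get("name", "box"))
    report = solvent_lipids.box_water_counts(
        ctx.trajectory, waters, box, segmentation=ctx.segmentation,
        anchor_rmsd_tol=params.get("anchor_rmsd_tol", 5.0))
    out = ctx.output_dir / f"hydration_{box.name}.tsv"
    core_io.write_timeseries(
        core_io.TimeSeries(report.per_frame_counts.astype(float), "count",
                           f"waters in {box.name}"), out)
    return {"table": str(out), "mean": report.mean, "std": report.std,
            "min": report.min, "max": report.max, "per_state": report.per_state}

def _stage_lipids(ctx: PipelineContext, params: dict) -> dict:
    fit = ctx.sel(params.get("fit", "protein and name CA"))
    table = solvent_lipids.lipid_bfactors(ctx.trajectory, ctx.system, fit)
    out = ctx.output_dir / "lipid_bfactors.tsv"
    table.table.to_csv(out, sep="\t", index=False)
    result = {"table": str(out), "n_chains": len(table.table),
              "lowest_b": float(table.table.bfactor.iloc[0])}
    if params.get("segments"):
        contacts = solvent_lipids.binding_site_contacts(
            table, ctx.trajectory, ctx.system, params["segments"],
            contact_cutoff=float(params.get("contact_cutoff", 4.5)),
            top_n=int(params.get("top_n", 17)))
        cout = ctx.output_dir / "lipid_sites.tsv"
        contacts.to_csv(cout, sep="\t", index=False)
        result["sites"] = str(cout)
    return result

def _stage_align(ctx: PipelineContext, params: dict) -> dict:
    fit = ctx.sel(params.get("fit", "protein and name CA"))
    ctx.trajectory = structural_metrics.align_trajectory(
        ctx.trajectory, fit, params.get("reference", 0))
    return {"aligned_on": params.get("fit", "protein and name CA")}

_STAGES = {
    "align": _stage_align,
    "rmsd": _stage_rmsd,
    "heatmap": _stage_heatmap,
    "pca": _stage_pca,
    "tilt": _stage_tilt,
    "states": _stage_states,
    "hydration": _stage_hydration,
    "lipids": _stage_lipids,
}

#: stages that consume another stage's product
_DEPENDS = {"hydration": "states"}

_SELECTION_KEYS = ("fit", "measure", "helix", "top", "bottom", "waters", "anchor")


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    output_dir = Path(config.get("output_dir", "gsecdyn_out"))
    output_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(output_dir)
    ctx = _load_inputs(config, output_dir)

    stages = config.get("stages") or []
    # fail fast: resolve every referenced selection before any stage runs
    for entry in stages:
        name = entry.get("stage")
        if name not in _STAGES:
            raise StageError(f"unknown stage {name!r}")
        for key in _SELECTION_KEYS:
            if key in entry:
                ctx.sel(entry[key])  # raises on unknown segment/subunit

    import gsecdyn
    report: dict = {
        "version": getattr(gsecdyn, "__version__", "unknown"),
        "config": {k: v for k, v in config.items() if k != "stages"},
        "stages": {},
    }
    failed: set[str] = set()
    ok = True
    for entry in stages:
        name = entry["stage"]
        dep = _DEPENDS.get(name)
        if dep and dep in failed:
            report["stages"][name] = {"status": "skipped", "reason": f"dependency {dep} failed"}
            continue
        t0 = time.perf_counter()
        try:
            result = _STAGES[name](ctx, entry)
            report["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
                "params": {k: v for k, v in entry.items() if k != "stage"},
                "result": result,
            }
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        except Exception as exc:
            ok = False
            failed.add(name)
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "error", "error": str(exc)}
    report["exit_status"] = 0 if ok else 1
    (output_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
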