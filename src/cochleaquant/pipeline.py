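"""Config-driven pipeline orchestration.

``run(config)`` executes the requested stages in dependency order from
one YAML/JSON-style mapping, writes every stage output as CSV with a
fixed column order and 6-significant-digit floats (so reruns are
byte-identical and hashable), and emits a JSON manifest recording
stage outputs with SHA-256 hashes, the echoed parameters (defaults
included), the seed, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cochleomap import bin_cochleogram
from .imaging import (RowGeometry, classify_cells, control_stats, gfp_quantify,
                      save_stack, segment_nuclei)
from .morphometry import fit_arc, nucleus_position
from .stats import pearson
from .synthgen import CochleaSimParams, gen_cochlea_stack, study_params

log = logging.getLogger("cochleaquant.pipeline")

STAGE_ORDER = ["simulate", "segment", "morphometry", "cochleogram",
               "transduction", "stats"]


class PipelineError(RuntimeError):
    """Raised with the first failing stage named."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


def _write_csv(df: pd.DataFrame, path: Path, columns) -> str:
    df = df[[c for c in columns if c in df.columns]]
    df.to_csv(path, index=False, float_format="%.6g")
    return _sha256(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run(config: dict, outdir=None) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir or config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages")
    if not stages:
        raise PipelineError("config", "no stages requested")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(unknown[0], "unknown stage")
    stages = [s for s in STAGE_ORDER if s in stages]

    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "stages": {}}
    state: dict = {}

    for stage in stages:
        params = dict(config.get(stage, {}))
        log.info("stage %s: params=%s", stage, params)
        outputs = _STAGES[stage](state, params, seed, outdir)
        manifest["stages"][stage] = {"params": params, "outputs": outputs}

    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(state, params, seed, outdir):
    genotype = params.setdefault("genotype", "KO_treated")
    params.setdefault("seed", seed)
    known = set(CochleaSimParams.__dataclass_fields__)
    sim = study_params(genotype, seed=int(params["seed"]),
                       **{k: v for k, v in params.items()
                          if k in known and k not in ("genotype", "seed")})
    stack, truth, polyline = gen_cochlea_stack(sim)
    state.update(stack=stack, truth=truth, polyline=polyline, sim=sim)

    tiff = outdir / "stack.ome.tif"
    save_stack(stack, tiff)
    truth_csv = outdir / "truth.csv"
    h_truth = _write_csv(truth, truth_csv, list(truth.columns))
    poly_csv = outdir / "polyline.csv"
    pd.DataFrame(polyline.points, columns=["x_um", "y_um"]).to_csv(
        poly_csv, index=False, float_format="%.6g")
    return {"stack": str(tiff), "truth": {"path": str(truth_csv), "sha256": h_truth},
            "polyline": {"path": str(poly_csv), "sha256": _sha256(poly_csv)}}


def _stage_segment(state, params, seed, outdir):
    if "stack" not in state:
        raise PipelineError("segment", "missing upstream simulate output (stack)")
    stack = state["stack"]
    segs = segment_nuclei(stack, channel=params.setdefault("channel", "DAPI"),
                          min_volume_um3=params.setdefault("min_volume_um3", 8.0))
    geom = RowGeometry(polyline=state["polyline"],
                       row_spacing_um=params.setdefault(
                           "row_spacing_um", state["sim"].row_spacing_um))
    dets = classify_cells(segs, stack, geom)
    state["detections"] = dets

    df = pd.DataFrame([{
        "cell_id": d.cell_id, "type": d.type, "row": d.row,
        "position_um": d.position_um,
        "cx_um": d.centroid_um[0], "cy_um": d.centroid_um[1], "cz_um": d.centroid_um[2],
        "ax_um": d.apical_um[0], "ay_um": d.apical_um[1], "az_um": d.apical_um[2],
        "bx_um": d.basal_um[0], "by_um": d.basal_um[1], "bz_um": d.basal_um[2],
        "volume_um3": d.segment.volume_um3, "flags": ";".join(d.flags),
    } for d in dets])
    state["detections_df"] = df
    path = outdir / "detections.csv"
    h = _write_csv(df, path, list(df.columns))
    return {"detections": {"path": str(path), "sha256": h, "n": len(df)}}


def _stage_morphometry(state, params, seed, outdir):
    if "detections" not in state:
        raise PipelineError("morphometry", "missing upstream segment output")
    rows = []
    for d in state["detections"]:
        try:
            fit = fit_arc(d.apical_um, d.centroid_um, d.basal_um)
            posn = nucleus_position(fit)
        except ValueError:
            continue
        rows.append({"cell_id": d.cell_id, "type": d.type, "row": d.row,
                     "position_um": d.position_um,
                     "distance_from_apical_um": posn["distance_from_apical"],
                     "normalized": posn["normalized"],
                     "collinear": fit.collinear})
    df = pd.DataFrame(rows)
    state["morphometry_df"] = df
    path = outdir / "morphometry.csv"
    h = _write_csv(df, path, list(df.columns))
    return {"morphometry": {"path": str(path), "sha256": h, "n": len(df)}}


def _stage_cochleogram(state, params, seed, outdir):
    if "detections" not in state:
        raise PipelineError("cochleogram", "missing upstream segment output")
    bins = bin_cochleogram(state["detections"], state["polyline"],
                           bin_width=params.setdefault("bin_width_um", 100.0))
    state["bins"] = bins
    df = pd.DataFrame([{
        "start_um": b.start_um, "end_um": b.end_um, "ihc": b.ihc, "ohc": b.ohc,
        "ihc_per_100um": b.ihc_per_100um, "ohc_per_100um": b.ohc_per_100um,
        "partial": b.partial,
    } for b in bins])
    path = outdir / "cochleogram.csv"
    h = _write_csv(df, path, list(df.columns))
    return {"cochleogram": {"path": str(path), "sha256": h, "n_bins": len(df)}}


def _stage_transduction(state, params, seed, outdir):
    if "detections" not in state:
        raise PipelineError("transduction", "missing upstream segment output")
    if "control" not in params:
        raise PipelineError(
            "transduction",
            "missing required 'control' specimen config (control-animal stack)")
    ctrl_cfg = dict(params["control"])
    ctrl_cfg.setdefault("genotype", "WT")
    ctrl_cfg.setdefault("seed", seed + 1)
    known = set(CochleaSimParams.__dataclass_fields__)
    ctrl_sim = study_params(ctrl_cfg["genotype"], seed=int(ctrl_cfg["seed"]),
                            **{k: v for k, v in ctrl_cfg.items()
                               if k in known and k not in ("genotype", "seed")})
    cstack, _, cpoly = gen_cochlea_stack(ctrl_sim)
    csegs = segment_nuclei(cstack)
    cdets = classify_cells(csegs, cstack, RowGeometry(
        polyline=cpoly, row_spacing_um=ctrl_sim.row_spacing_um))
    ctrl = control_stats(cdets, cstack)

    table, rates = gfp_quantify(state["detections"], state["stack"], ctrl)
    path = outdir / "transduction.csv"
    h = _write_csv(table, path, list(table.columns))
    return {"transduction": {"path": str(path), "sha256": h,
                             "rates": {k: round(v, 6) for k, v in rates.items()}}}


def _stage_stats(state, params, seed, outdir):
    if "bins" not in state:
        raise PipelineError("stats", "missing upstream cochleogram output")
    bins = state["bins"]
    x = np.array([(b.start_um + b.end_um) / 2.0 for b in bins])
    y = np.array([b.ohc_per_100um for b in bins])
    rows = []
    if len(bins) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        res = pearson(x, y)
        rows.append({"test": "pearson_ohc_density_vs_position",
                     "estimate": res.estimate, "statistic": res.statistic,
                     "df": res.df, "p": res.p})
    df = pd.DataFrame(rows, columns=["test", "estimate", "statistic", "df", "p"])
    path = outdir / "stats.csv"
    h = _write_csv(df, path, list(df.columns))
    return {"stats": {"path": str(path), "sha256": h}}


_STAGES = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "morphometry": _stage_morphometry,
    "cochleogram": _stage_cochleogram,
    "transduction": _stage_transduction,
    "stats": _stage_stats,
}


def demo_config(seed: int = 0) -> dict:
    """A small end-to-end configuration on synthetic data."""
    return {
        "seed": seed,
        "stages": ["simulate", "segment", "morphometry", "cochleogram",
                   "transduction", "stats"],
        "simulate": {"genotype": "KO_treated", "n_cells_per_row": 12},
        "transduction": {"control": {"genotype": "WT", "n_cells_per_row": 12}},
    }
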