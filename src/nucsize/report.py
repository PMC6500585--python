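"""End-to-end pipeline orchestration and method benchmarking against truth.

A run is described by a config (YAML-friendly dict): one input source (a TIFF
path with calibration, or a phantom config), the methods to run, per-method
parameters, and the statistics settings. Every output is stamped with the
package version, seed and full parameter echo, so any artifact is regenerable
bit-exactly from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import __version__
from .counter3d import run_object_counter
from .phantom import PhantomConfig, PhantomObject, generate_phantom, truth_to_frame
from .ploidy import bin_classes
from .rsd import run_rsd, surface_objects_to_frame
from .stack import CalibratedStack, load_stack, save_stack
from .track import run_track_method

__all__ = ["run_pipeline", "benchmark_methods", "load_config"]

MATCH_RADIUS_UM = 5.0


def benchmark_methods(truth: list[PhantomObject], detections: pd.DataFrame,
                      match_radius: float = MATCH_RADIUS_UM,
                      kinds: tuple[str, ...] = ("plant_nucleus",)) -> dict:
    """Score detections against phantom truth by nearest-centroid matching.

    Truth objects and detections are paired by optimal assignment on centroid
    distance (lateral-only when the detection table has no z column), rejecting
    pairs beyond ``match_radius`` μm. Unmatched truth = miss; unmatched
    detection = false positive. Volume (or area) relative errors are reported
    for the matched pairs.
    """
    objs = [o for o in truth if o.kind in kinds]
    has_z = "centroid_z_um" in detections.columns
    det_y = detections["centroid_y_um"].to_numpy(float)
    det_x = detections["centroid_x_um"].to_numpy(float)
    det_z = detections["centroid_z_um"].to_numpy(float) if has_z else None
    n_t, n_d = len(objs), len(detections)
    matches: list[tuple[int, int]] = []
    if n_t and n_d:
        cost = np.full((n_t, n_d), 1e9)
        for i, o in enumerate(objs):
            oz, oy, ox = o.center
            d2 = (det_y - oy) ** 2 + (det_x - ox) ** 2
            if has_z:
                d2 = d2 + (det_z - oz) ** 2
            d = np.sqrt(d2)
            cost[i, d <= match_radius] = d[d <= match_radius]
        rows, cols = linear_sum_assignment(cost)
        matches = [(i, j) for i, j in zip(rows, cols) if cost[i, j] < 1e9]
    errors = []
    value_col = "volume_um3" if "volume_um3" in detections.columns else (
        "area_um2" if "area_um2" in detections.columns else None)
    if value_col:
        for i, j in matches:
            measured = detections.iloc[j][value_col]
            if pd.isna(measured):
                continue
            ref = (objs[i].true_volume if value_col == "volume_um3"
                   else objs[i].equatorial_area)
            errors.append((measured - ref) / ref)
    errors = np.asarray(errors, dtype=float)
    return {
        "n_truth": n_t,
        "n_detected": n_d,
        "n_matched": len(matches),
        "recall": len(matches) / n_t if n_t else float("nan"),
        "precision": len(matches) / n_d if n_d else float("nan"),
        "value": value_col,
        "n_measured": int(errors.size),
        "median_abs_rel_error": float(np.median(np.abs(errors))) if errors.size else float("nan"),
        "mean_rel_error": float(errors.mean()) if errors.size else float("nan"),
        "rel_errors": errors.tolist(),
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _get_input(cfg: dict) -> tuple[CalibratedStack, list[PhantomObject] | None]:
    src = cfg.get("input", {})
    if ("phantom" in src) == ("tiff" in src):
        raise ValueError("config must name exactly one input source: "
                         "input.phantom or input.tiff")
    if "phantom" in src:
        pc = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in (src["phantom"] or {}).items()})
        stack, truth = generate_phantom(pc)
        return stack, truth
    t = src["tiff"]
    stack = load_stack(t["path"], dx=t["dx"], dy=t["dy"], dz=t["dz"])
    return stack, None


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured methods and statistics; write a report bundle.

    Outputs per method: a measurement CSV; for phantom inputs additionally a
    truth CSV and per-method benchmark scores; a volume class table when the
    volumetric method ran; plus report.json with every parameter, the seed and
    the package version. Returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, truth = _get_input(config)
    methods = config.get("methods", ["oc3d"])
    stats_cfg = config.get("stats", {})
    report: dict = {"version": __version__, "config": config,
                    "stack_shape": list(stack.shape),
                    "calibration_um": [stack.dz, stack.dy, stack.dx],
                    "methods": {}}
    if truth is not None:
        truth_to_frame(truth).to_csv(outdir / "truth.csv", index=False)
        save_stack(stack, outdir / "phantom.tif")
    tables: dict[str, pd.DataFrame] = {}
    constant_stack = stack.voxels.min() == stack.voxels.max()
    for m in methods:
        params = dict(config.get(m, {}))
        if constant_stack:
            # nothing to segment: empty tables, zero-count report, success
            cols = {"track": ["track_id", "n_slices", "centroid_y_um",
                              "centroid_x_um", "slice_of_d_max", "d_max_um",
                              "area_um2", "volume_um3"],
                    "rsd": ["object_id", "substack", "centroid_y_um",
                            "centroid_x_um", "area_um2", "perimeter_um",
                            "circularity"],
                    "oc3d": ["object_id", "voxel_count", "volume_um3",
                             "centroid_z_um", "centroid_y_um", "centroid_x_um",
                             "touches_border", "lobedness"]}
            if m not in cols:
                raise ValueError(f"unknown method {m!r}")
            tab = pd.DataFrame(columns=cols[m])
            entry = {"n": 0, "note": "constant stack, nothing detected"}
        elif m == "track":
            tab = run_track_method(stack, **params)
            entry = {"n": int(len(tab)),
                     "quality_threshold": tab.attrs.get("quality_threshold")}
        elif m == "rsd":
            tab = surface_objects_to_frame(run_rsd(stack, **params))
            entry = {"n": int(len(tab))}
        elif m == "oc3d":
            tab, _labels, audit = run_object_counter(stack, **params)
            entry = {"n": int(len(tab)), "threshold": audit["threshold"],
                     "excluded_by_reason": audit["excluded_by_reason"]}
        else:
            raise ValueError(f"unknown method {m!r}")
        tab.to_csv(outdir / f"{m}.csv", index=False)
        tables[m] = tab
        if truth is not None:
            entry["benchmark"] = {
                k: v for k, v in benchmark_methods(truth, tab).items()
                if k != "rel_errors"}
        report["methods"][m] = entry
    if "oc3d" in tables and len(tables["oc3d"]):
        _, class_table = bin_classes(tables["oc3d"]["volume_um3"],
                                     width=stats_cfg.get("width", 25.0),
                                     anchor=stats_cfg.get("anchor", 20.0))
        class_table.to_csv(outdir / "classes.csv", index=False)
        report["classes"] = class_table.to_dict(orient="records")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
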