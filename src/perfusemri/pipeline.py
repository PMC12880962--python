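"""Configuration-driven orchestration of the full phantom-to-report run.

A run is described by a YAML/dict config with one flat namespace per stage.
Stages execute in dependency order:

    phantom -> segment -> graph -> morphometrics
    phantom -> adc
    phantom -> dce
    histology (independent)

Every artifact lands in the run directory together with the resolved config
and a log; identical config and seeds reproduce identical outputs.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .diffusion import compute_adc_map, parenchyma_stats
from .dce import (
    estimate_velocity,
    roi_enhancement_curve,
    track_bolus_front,
    ttp_map,
    volumetric_flow,
)
from .graph import SpatialGraph
from .histology import compare_groups, summarize_groups
from .morphometrics import network_summary
from .phantom import (
    PhantomSpec,
    generate_vessel_tree,
    rasterize_tree,
    simulate_dce,
    simulate_dwi,
    simulate_histology,
    simulate_t2_volume,
)
from .segmentation import region_grow
from .skeleton import mask_to_graph
from .volume import ImageVolume, write_volume

log = logging.getLogger("perfusemri")

_STAGES = ("phantom", "segment", "graph", "morphometrics", "adc", "dce", "histology")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(_STAGES),
    "phantom": {
        "grid_shape": [168, 144, 144],
        "voxel_spacing_mm": [0.66, 0.66, 0.66],
        "tree_depth": 4,
        "root_radius_mm": 5.0,
        "radius_decay": 2.0 ** (-1.0 / 3.0),
        "segment_length_mm": 20.0,
        "length_decay": 0.8,
        "tortuosity_amplitude_mm": 1.5,
        "branch_half_angle_deg": 37.5,
        "vessel_intensity": 200.0,
        "parenchyma_intensity": 100.0,
        "t2_noise_sd": 5.0,
        "parenchyma_D": 0.55e-3,
        "vessel_D": 2.5e-3,
    },
    "segment": {"low": 150.0, "high": 1e9, "connectivity": 26, "seeds": None},
    "graph": {"min_end_length": 2, "smooth_iterations": 10, "smoothing": 0.5, "attach": 0.25},
    "morphometrics": {},
    "adc": {
        "b_values": [90.0, 500.0, 1500.0, 2000.0],
        "directions": 3,
        "S0": 100.0,
        "noise_sd": 2.0,
        "background_threshold": None,
    },
    "dce": {
        "velocity_cm_per_min": 30.0,
        "frame_interval_s": 10.0,
        "n_frames": 24,
        "bolus_amplitude": 100.0,
        "kernel": "step",
        "noise_sd": 0.0,
        "threshold_fraction": 0.5,
        "roi_size": 4,
    },
    "histology": {
        "group_means": {
            "Perfused|Baseline": [1.0, 1.3, 2.1, 1.9],
            "SCS|Baseline": [1.0, 1.6, 2.0, 2.0],
            "Perfused|30 min": [1.1, 2.2, 2.1, 3.0],
            "SCS|30 min": [2.9, 3.0, 3.0, 3.0],
        },
        "dispersion": 0.3,
        "n_biopsies": 3,
    },
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    unknown_top = set(config) - set(merged) - {"output_dir"}
    if unknown_top:
        raise ValueError(f"unknown config keys: {sorted(unknown_top)}")
    for key, value in config.items():
        if key in _STAGES:
            if not isinstance(value, dict):
                raise ValueError(f"stage section {key!r} must be a mapping")
            unknown = set(value) - set(merged[key])
            if unknown:
                raise ValueError(f"unknown keys in stage {key!r}: {sorted(unknown)}")
            merged[key].update(value)
        else:
            merged[key] = value
    bad = [s for s in merged["stages"] if s not in _STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return merged


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute the configured stages; returns a dict of key results.

    Raises when a requested stage's upstream artifact is missing (e.g.
    ``graph`` without ``segment`` or ``phantom``).
    """
    cfg = validate_config(config or {})
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    results: dict = {"config": cfg}
    from . import __version__

    (outdir / "resolved_config.yaml").write_text(
        f"# perfusemri {__version__}\n" + yaml.safe_dump(cfg, sort_keys=False)
    )

    truth_graph = None
    mask = None
    t2 = None
    true_D = None
    traced = None

    try:
        if "phantom" in stages:
            p = cfg["phantom"]
            spec = PhantomSpec(
                grid_shape=tuple(p["grid_shape"]),
                voxel_spacing_mm=tuple(p["voxel_spacing_mm"]),
                tree_depth=int(p["tree_depth"]),
                root_radius_mm=p["root_radius_mm"],
                radius_decay=p["radius_decay"],
                segment_length_mm=p["segment_length_mm"],
                length_decay=p["length_decay"],
                tortuosity_amplitude_mm=p["tortuosity_amplitude_mm"],
                branch_half_angle_deg=p["branch_half_angle_deg"],
                seed=seed,
            )
            log.info("phantom: generating depth-%d tree", spec.tree_depth)
            truth_graph = generate_vessel_tree(spec)
            mask = rasterize_tree(truth_graph, spec)
            t2 = simulate_t2_volume(
                mask, p["vessel_intensity"], p["parenchyma_intensity"], p["t2_noise_sd"], seed
            )
            fg = np.asarray(mask.values, dtype=bool)
            true_D = mask.with_values(
                np.where(fg, float(p["vessel_D"]), float(p["parenchyma_D"]))
            )
            truth_graph.to_json(outdir / "ground_truth_graph.json")
            write_volume(mask, outdir / "phantom_mask.nii.gz")
            write_volume(t2, outdir / "phantom_t2.nii.gz")
            results["phantom"] = {
                "n_segments": truth_graph.n_segments,
                "n_nodes": truth_graph.n_nodes,
                "foreground_voxels": int(fg.sum()),
            }
            results["_phantom_spec"] = spec

        if "segment" in stages:
            if t2 is None:
                raise RuntimeError("stage 'segment' requires stage 'phantom' upstream")
            s = cfg["segment"]
            seeds = s["seeds"]
            if seeds is None:
                inlet = truth_graph.nodes[truth_graph.inlet_node]
                seeds = [tuple(np.round(t2.world_to_voxel(inlet)).astype(int))]
            seg_mask = region_grow(t2, seeds, s["low"], s["high"], int(s["connectivity"]))
            write_volume(
                seg_mask.with_values(seg_mask.values.astype(np.uint8)),
                outdir / "segmentation.nii.gz",
            )
            results["segment"] = {"voxels": int(np.asarray(seg_mask.values).sum())}
            mask = seg_mask.with_values(np.asarray(seg_mask.values, dtype=bool))

        if "graph" in stages:
            if mask is None:
                raise RuntimeError("stage 'graph' requires a mask from 'phantom' or 'segment'")
            g = cfg["graph"]
            log.info("graph: skeletonizing %d voxels", int(np.asarray(mask.values).sum()))
            traced = mask_to_graph(
                mask,
                min_end_length=int(g["min_end_length"]),
                smooth_iterations=int(g["smooth_iterations"]),
                smoothing=g["smoothing"],
                attach=g["attach"],
            )
            traced.to_json(outdir / "traced_graph.json")
            traced.to_csv(outdir / "traced_graph_segments.csv")
            results["graph"] = {"n_segments": traced.n_segments, "n_nodes": traced.n_nodes}

        if "morphometrics" in stages:
            if traced is None:
                raise RuntimeError("stage 'morphometrics' requires stage 'graph' upstream")
            summary = network_summary(traced)
            summary.segments.to_csv(outdir / "morphometrics_segments.csv", index=False)
            morpho = summary.to_dict()
            if mask is not None:
                # voxel-count volume alongside the graph (frustum) volume
                voxel_vol = float(np.prod(mask.voxel_spacing_mm))
                morpho["mask_voxel_volume_mm3"] = float(
                    np.asarray(mask.values, dtype=bool).sum() * voxel_vol
                )
            _write_json(outdir / "morphometrics.json", morpho)
            results["morphometrics"] = morpho
            if truth_graph is not None:
                truth = network_summary(truth_graph)
                _write_json(outdir / "morphometrics_ground_truth.json", truth.to_dict())
                results["morphometrics_ground_truth"] = truth.to_dict()

        if "adc" in stages:
            if true_D is None or mask is None:
                raise RuntimeError("stage 'adc' requires stage 'phantom' upstream")
            a = cfg["adc"]
            dwi = simulate_dwi(
                true_D,
                S0=a["S0"],
                b_values=tuple(a["b_values"]),
                directions=int(a["directions"]),
                noise_sd=a["noise_sd"],
                seed=seed + 1,
            )
            adc = compute_adc_map(dwi)
            write_volume(
                ImageVolume(np.nan_to_num(adc.values), mask.voxel_spacing_mm),
                outdir / "adc_map.nii.gz",
            )
            bmin = dwi[0][min(a["b_values"])]
            mean, sd, (hist, edges) = parenchyma_stats(
                adc, bmin, vessel_mask=mask, background_threshold=a["background_threshold"]
            )
            results["adc"] = {
                "parenchyma_mean_mm2_per_s": mean,
                "parenchyma_sd_mm2_per_s": sd,
                "true_parenchyma_D": cfg["phantom"]["parenchyma_D"],
            }
            _write_json(outdir / "adc_stats.json", results["adc"])

        if "dce" in stages:
            if truth_graph is None or mask is None:
                raise RuntimeError("stage 'dce' requires stage 'phantom' upstream")
            d = cfg["dce"]
            series = simulate_dce(
                truth_graph,
                mask,
                velocity_cm_per_min=d["velocity_cm_per_min"],
                frame_interval_s=d["frame_interval_s"],
                n_frames=int(d["n_frames"]),
                bolus_amplitude=d["bolus_amplitude"],
                kernel=d["kernel"],
                noise_sd=d["noise_sd"],
                seed=seed + 2,
            )
            ttp = ttp_map(series, baseline_frames=1)
            write_volume(
                ImageVolume(
                    np.nan_to_num(ttp.values), mask.voxel_spacing_mm
                ),
                outdir / "ttp_map.nii.gz",
            )
            path_pts = truth_graph.inlet_to_leaf_path_points()
            # ROI enhancement curves near the inlet, three repeats shifted by
            # one voxel, mirroring repeated manual ROI placement
            roi_size = int(d["roi_size"])
            probe = np.round(
                series.world_to_voxel(path_pts[min(len(path_pts) - 1, 10)])
            ).astype(int)
            centers = [tuple(probe + off) for off in ([0, 0, 0], [1, 0, 0], [0, 1, 0])]
            try:
                curve = roi_enhancement_curve(series, centers, roi_size=roi_size)
                with open(outdir / "dce_curves.csv", "w") as fh:
                    fh.write("time_s,mean_signal,min_signal,max_signal\n")
                    for row in zip(
                        curve.times_s, curve.mean_signal, curve.min_signal, curve.max_signal
                    ):
                        fh.write(",".join(str(float(v)) for v in row) + "\n")
            except ValueError as exc:
                log.warning("dce: ROI curves skipped (%s)", exc)
            front = track_bolus_front(
                series, path_pts, threshold_fraction=d["threshold_fraction"]
            )
            v_hat, v_sd = estimate_velocity(front)
            # diameter at the root mid-point, from the traced graph when
            # available, else ground truth
            root = truth_graph.segments[0]
            if traced is not None and traced.n_segments:
                mid = root.points[len(root.points) // 2]
                best, radius = None, 0.0
                for seg in traced.segments:
                    dist = np.linalg.norm(seg.points - mid, axis=1)
                    j = int(np.argmin(dist))
                    if best is None or dist[j] < best:
                        best, radius = float(dist[j]), float(seg.radii_mm[j])
            else:
                radius = float(root.radii_mm[0])
            diameter_cm = 2.0 * radius / 10.0
            q = volumetric_flow(diameter_cm, v_hat)
            with open(outdir / "bolus_front.csv", "w") as fh:
                fh.write("time_s,front_distance_cm\n")
                for t, dist_cm in front:
                    fh.write(f"{t},{dist_cm}\n")
            results["dce"] = {
                "velocity_cm_per_min": v_hat,
                "velocity_sd_cm_per_min": v_sd,
                "true_velocity_cm_per_min": d["velocity_cm_per_min"],
                "diameter_cm": diameter_cm,
                "flow_mL_per_min": q,
            }
            _write_json(outdir / "flow.json", results["dce"])

        if "histology" in stages:
            h = cfg["histology"]
            means = {
                tuple(k.split("|")): tuple(v) for k, v in h["group_means"].items()
            }
            scores = simulate_histology(
                means, dispersion=h["dispersion"], n_biopsies=int(h["n_biopsies"]), seed=seed + 3
            )
            scores.to_csv(outdir / "histology_scores.csv", index=False)
            summary = summarize_groups(scores)
            summary.to_csv(outdir / "histology_summary.csv", index=False)
            timepoints = scores["timepoint"].unique()
            comparisons = {tp: compare_groups(scores, tp) for tp in timepoints}
            _write_json(outdir / "histology_report.json", comparisons)
            results["histology"] = {
                "summary": summary.to_dict(orient="records"),
                "comparisons": comparisons,
            }
    finally:
        log.removeHandler(handler)
        handler.close()

    results.pop("_phantom_spec", None)
    return results


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc)
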