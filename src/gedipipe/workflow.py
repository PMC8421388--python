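"""End-to-end orchestration: simulate -> process -> track -> call -> survive.

Each stage reads and writes plain CSV/TIFF so any step can be rerun or
audited in isolation. The processing order is: per-image median background
subtraction, montage stitching, translation registration across timepoints,
soma segmentation, proximity tracking, feature extraction, ratio-threshold
death calling, then survival statistics. Every dropped object or excluded
track leaves a machine-parseable log row with a reason code — a pipeline
that silently loses neurons cannot be audited for artifacts.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deathcall, images, simulate, survival, tracking

__all__ = ["RunConfig", "run_simulate", "run_process", "run_survival", "run_all"]

_TIFF_RE = re.compile(r"(?P<well>[^_]+)_T(?P<t>\d+)_CH(?P<channel>[^_]+)_X(?P<col>\d+)_Y(?P<row>\d+)\.tif$")

FLOAT_FMT = "%.6g"  # fixed precision keeps reruns byte-identical


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_dir: str = "plate"
    output_dir: str = "results"
    plate: simulate.PlateConfig = field(default_factory=simulate.PlateConfig)
    groups: dict[str, str] = field(default_factory=dict)  # well -> group label
    positive_control_wells: list[str] = field(default_factory=list)
    min_size: int = images.MIN_SOMA_AREA_PX
    max_link_dist: float = 20.0
    max_shift_px: int = 25
    threshold_override: float | None = None
    threshold_weight: float = deathcall.THRESHOLD_WEIGHT
    reference_group: str = "control"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "plate" in doc:
            plate_doc = doc.pop("plate")
            wells = [simulate.WellSpec(**w) for w in plate_doc.pop("wells", [])]
            for key in ("timepoints", "image_shape", "tile_grid"):
                if key in plate_doc:
                    plate_doc[key] = tuple(plate_doc[key])
            doc["plate"] = (simulate.PlateConfig(wells=wells, **plate_doc)
                            if wells else simulate.PlateConfig(**plate_doc))
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: RunConfig, out: Path, stage: str) -> None:
    manifest = {"stage": stage, "seed": config.seed, "config_hash": config.config_hash()}
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def run_simulate(config: RunConfig, overwrite: bool = False) -> Path:
    """Generate the synthetic plate described by ``config.plate``."""
    plate = config.plate
    if plate.seed != config.seed:
        plate = simulate.PlateConfig(**{**asdict_plate(plate), "seed": config.seed})
    out = simulate.generate_plate(plate, config.input_dir, overwrite=overwrite)
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    _write_manifest(config, Path(config.output_dir), "simulate")
    # default group labels fall out of the plate layout unless overridden
    if not config.groups:
        config.groups = {w.well: w.group for w in plate.wells}
    if not config.positive_control_wells:
        config.positive_control_wells = [w.well for w in plate.wells if w.positive_control]
    return out


def asdict_plate(plate: simulate.PlateConfig) -> dict:
    d = asdict(plate)
    d["wells"] = [simulate.WellSpec(**w) for w in d["wells"]]
    return d


def _scan_plate(input_dir: Path) -> tuple[pd.DataFrame, list[float]]:
    rows = []
    for f in sorted(input_dir.glob("*.tif")):
        m = _TIFF_RE.match(f.name)
        if m:
            rows.append({"path": f, "well": m["well"], "t_index": int(m["t"]),
                         "channel": m["channel"], "col": int(m["col"]), "row": int(m["row"])})
    if not rows:
        raise FileNotFoundError(f"no plate TIFFs matching the naming scheme in {input_dir}")
    frame = pd.DataFrame(rows)
    tp_file = input_dir / "timepoints.csv"
    if tp_file.exists():
        times = pd.read_csv(tp_file)["time_h"].tolist()
    else:
        times = sorted(frame["t_index"].unique().astype(float))
    return frame, times


def _load_stitched(config: RunConfig, files: pd.DataFrame, well: str, t_index: int,
                   channel: str, time_h: float) -> images.FrameImage:
    sel = files[(files.well == well) & (files.t_index == t_index) & (files.channel == channel)]
    if sel.empty:
        raise FileNotFoundError(f"missing channel {channel!r} for well {well} T{t_index}")
    tiles = [
        images.subtract_background(
            images.FrameImage.from_tiff(r.path, well=well, timepoint=time_h,
                                        channel=channel, tile=(r.row, r.col)))
        for r in sel.itertuples()
    ]
    grid = (files.row.max() + 1, files.col.max() + 1)
    if grid == (1, 1):
        return tiles[0]
    return images.stitch_montage(tiles, grid, config.plate.tile_overlap_px)


def run_process(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Process a plate directory into feature, track, and death-call tables.

    Returns the tables and writes them (plus a drop log and the calibrated
    threshold model) under ``config.output_dir``.
    """
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files, times = _scan_plate(input_dir)
    channels = sorted(files["channel"].unique())
    for needed in ("gedi", "morphology"):
        if needed not in channels:
            raise FileNotFoundError(f"plate lacks the {needed!r} channel (found {channels})")

    seg_params = images.SegmentationParams(min_size=config.min_size)
    drops: list[dict] = []
    all_features: list[pd.DataFrame] = []
    all_tracks: list[tracking.Track] = []
    track_meta: dict[int, tuple[str, str]] = {}  # global id -> (well, group)
    ratio_records: dict[int, dict[float, float]] = {}
    global_offset = 0

    for well in sorted(files["well"].unique()):
        morph_series = []
        objects_by_t: dict[float, list[images.SegmentedObject]] = {}
        for t_index, time_h in enumerate(times):
            morph = _load_stitched(config, files, well, t_index, "morphology", time_h)
            gedi = _load_stitched(config, files, well, t_index, "gedi", time_h)
            morph_series.append(morph)
            labels, objs = images.segment(morph, seg_params)
            images.extract_features(labels, objs, {"morphology": morph, "gedi": gedi})
            objects_by_t[time_h] = objs
        if len(morph_series) >= 2:
            shift_list = images.align_timepoints(morph_series, config.max_shift_px)
            shifts = {t: s for t, s in zip(times, shift_list)}
        else:
            shifts = {t: (0, 0) for t in times}

        well_tracks = tracking.link_tracks(objects_by_t, config.max_link_dist, shifts=shifts)
        group = config.groups.get(well, well)
        for tr in well_tracks:
            tr.track_id += global_offset
            track_meta[tr.track_id] = (well, group)
            ratios: dict[float, float] = {}
            for obs in tr.observations:
                try:
                    ratios[obs.timepoint] = deathcall.compute_gedi_ratio(obs)
                except ValueError as exc:
                    drops.append({"well": well, "track_id": tr.track_id,
                                  "timepoint_h": obs.timepoint,
                                  "reason": "undefined_ratio", "detail": str(exc)})
            ratio_records[tr.track_id] = ratios
        global_offset += len(well_tracks)
        all_tracks.extend(well_tracks)
        feats = images.features_to_frame([o for objs in objects_by_t.values() for o in objs])
        all_features.append(feats)

    features = pd.concat(all_features, ignore_index=True) if all_features else pd.DataFrame()

    # --- threshold calibration -------------------------------------------
    if config.threshold_override is not None:
        model = deathcall.ThresholdModel(np.nan, np.nan, config.threshold_override,
                                         config.threshold_weight)
    else:
        pc_wells = set(config.positive_control_wells)
        live, dead = [], []
        for tid, ratios in ratio_records.items():
            well, _ = track_meta[tid]
            if well in pc_wells:
                dead.extend(r for t, r in ratios.items() if t > times[0])
            elif times[0] in ratios:
                live.append(ratios[times[0]])
        if live and dead:
            model = deathcall.calibrate_threshold(np.array(live), np.array(dead),
                                                  config.threshold_weight)
        else:
            pooled = np.array([r for ratios in ratio_records.values() for r in ratios.values()])
            lo, hi = deathcall.split_calibration_populations(pooled)
            model = deathcall.calibrate_threshold(lo, hi, config.threshold_weight)
    model.to_json(out / "threshold_model.json")

    # --- artifact flags and death calls ----------------------------------
    calls = []
    for tr in all_tracks:
        flags = tracking.flag_reversal_artifacts(tr, ratio_records[tr.track_id], model.threshold)
        for t, reason in flags:
            drops.append({"well": track_meta[tr.track_id][0], "track_id": tr.track_id,
                          "timepoint_h": t, "reason": f"artifact_{reason}", "detail": ""})
        call = deathcall.assign_death_time(tr, ratio_records[tr.track_id], model, times[-1])
        if call.cause == "excluded_artifact":
            drops.append({"well": track_meta[tr.track_id][0], "track_id": tr.track_id,
                          "timepoint_h": np.nan, "reason": "excluded_artifact", "detail": ""})
        calls.append(call)

    groups_map = {tid: g for tid, (_, g) in track_meta.items()}
    wells_map = {tid: w for tid, (w, _) in track_meta.items()}
    kept = [c for c in calls if c.cause != "excluded_artifact"]
    death_calls = deathcall.death_calls_to_frame(kept, groups_map, wells_map)

    track_table = tracking.tracks_to_frame(all_tracks)
    features.to_csv(out / "features.csv", index=False, float_format=FLOAT_FMT)
    track_table.to_csv(out / "tracks.csv", index=False, float_format=FLOAT_FMT)
    death_calls.to_csv(out / "death_calls.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(drops, columns=["well", "track_id", "timepoint_h", "reason", "detail"]
                 ).to_csv(out / "drops.csv", index=False, float_format=FLOAT_FMT)
    _write_manifest(config, out, "process")
    return {"features": features, "tracks": track_table,
            "death_calls": death_calls, "drops": pd.DataFrame(drops)}


def run_survival(config: RunConfig, death_calls: pd.DataFrame | None = None) -> dict:
    """KM/CRD curves and Cox hazard-ratio table from a death-call table."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if death_calls is None:
        path = out / "death_calls.csv"
        if not path.exists():
            raise FileNotFoundError(f"{path} not found; run the process stage first")
        death_calls = pd.read_csv(path)
    if "group" not in death_calls.columns:
        raise ValueError("death-call table lacks a 'group' column")
    records = death_calls.rename(columns={"time_h": "time"})[["id", "group", "time", "event"]]

    curves = survival.km_estimator(records)
    km_frames = []
    for name, curve in curves.items():
        frame = curve.to_frame()
        frame.insert(0, "group", name)
        crd = survival.cumulative_risk(curve)
        frame["cumulative_incidence"] = crd["cumulative_incidence"].to_numpy()
        frame["cumulative_hazard"] = crd["cumulative_hazard"].to_numpy()
        km_frames.append(frame)
    km_table = pd.concat(km_frames, ignore_index=True)
    km_table.to_csv(out / "km_curves.csv", index=False, float_format=FLOAT_FMT)

    cox_results = []
    groups = records["group"].unique()
    if len(groups) > 1 and records["event"].any():
        try:
            cox_results = survival.cox_fit(records, config.reference_group)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"Cox fit skipped: {exc}", stacklevel=2)
    else:
        warnings.warn("single group or no events: Cox fit skipped", stacklevel=2)
    cox_table = pd.DataFrame([asdict(r) for r in cox_results])
    cox_table.to_csv(out / "cox_table.csv", index=False, float_format=FLOAT_FMT)

    lines = [f"Survival summary ({len(records)} subjects, "
             f"{int(records['event'].sum())} events)"]
    for r in cox_results:
        lines.append(
            f"  {r.group} vs {config.reference_group}: HR = {r.hr:.3f} "
            f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}, p = {r.p_value:.2e}, "
            f"n = {r.n}, events = {r.n_events})"
        )
    report = "\n".join(lines)
    (out / "report.txt").write_text(report + "\n")
    _write_manifest(config, out, "survival")
    return {"km": km_table, "cox": cox_results, "report": report}


def run_all(config: RunConfig, overwrite: bool = False) -> dict:
    """simulate -> process -> survival in one call."""
    run_simulate(config, overwrite=overwrite)
    tables = run_process(config)
    result = run_survival(config, tables["death_calls"])
    return {**tables, **result}
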