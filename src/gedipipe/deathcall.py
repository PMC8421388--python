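"""GEDI-ratio computation, death-threshold calibration, and death calling.

The pseudo-ratiometric readout divides the background-subtracted GEDI-channel
mean by the morphology-channel mean within the soma mask. Live and dead
populations separate widely on this ratio, so a single cutoff suffices; it
is calibrated per experiment from a live population (typically every object
at the pre-treatment timepoint) and a dead population (objects in a
lethal-treatment positive-control well) as

    threshold = mean_live + 0.25 * (mean_dead - mean_live)

i.e. one quarter of the way from the live mean to the dead mean. A neuron is
called dead the first time its ratio strictly exceeds the threshold, or at
the first timepoint its tracked segmentation label goes missing — whichever
comes first; a neuron that does neither is censored at the last imaging
time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import filters

from .images import SegmentedObject
from .tracking import Track

__all__ = [
    "GEDIRecord",
    "ThresholdModel",
    "DeathCall",
    "compute_gedi_ratio",
    "calibrate_threshold",
    "split_calibration_populations",
    "classify",
    "assign_death_time",
    "curation_concordance",
    "death_calls_to_frame",
]

THRESHOLD_WEIGHT = 0.25  # fraction of the live-to-dead separation


@dataclass
class GEDIRecord:
    """One track-timepoint ratio observation with its live/dead call."""

    track_id: int
    timepoint: float
    gedi_ratio: float
    call: str  # "live" | "dead"


@dataclass
class ThresholdModel:
    """Calibrated live/dead means and the resulting death threshold."""

    mean_live: float
    mean_dead: float
    threshold: float
    weight: float = THRESHOLD_WEIGHT
    reliable: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class DeathCall:
    """Per-track time of death (or censoring) with its cause."""

    track_id: int
    death_time: float  # hours; for censored tracks, the censoring time
    event: bool
    cause: str  # "ratio_crossing" | "track_loss" | "censored" | "excluded_artifact"


def compute_gedi_ratio(obj: SegmentedObject) -> float:
    """GEDI ratio of one segmented object: mean_gedi / mean_morph.

    Both means must come from background-subtracted images over the soma
    mask.

    Raises
    ------
    ValueError
        If the morphology mean is non-positive (ratio undefined; the caller
        drops the object with a log entry).
    """
    try:
        gedi = obj.mean_intensity["gedi"]
        morph = obj.mean_intensity["morphology"]
    except KeyError as exc:
        raise ValueError(f"object {obj.label} lacks channel means") from exc
    if morph <= 0:
        raise ValueError(
            f"object {obj.label} at t={obj.timepoint}: morphology mean {morph} <= 0"
        )
    return float(gedi / morph)


def calibrate_threshold(
    live_ratios: np.ndarray, dead_ratios: np.ndarray, weight: float = THRESHOLD_WEIGHT
) -> ThresholdModel:
    """Death threshold from calibration populations.

    ``threshold = (mean(dead) - mean(live)) * weight + mean(live)`` with the
    conventional weight 0.25. If the dead mean falls below the live mean the
    model is still returned but flagged unreliable, with a warning.
    """
    live = np.asarray(live_ratios, dtype=float)
    dead = np.asarray(dead_ratios, dtype=float)
    if live.size == 0 or dead.size == 0:
        raise ValueError("both calibration populations must be non-empty")
    mean_live = float(live.mean())
    mean_dead = float(dead.mean())
    reliable = mean_dead >= mean_live
    if not reliable:
        warnings.warn(
            f"dead mean {mean_dead:.4g} < live mean {mean_live:.4g}: "
            "calibration flagged unreliable",
            stacklevel=2,
        )
    threshold = (mean_dead - mean_live) * weight + mean_live
    return ThresholdModel(mean_live, mean_dead, threshold, weight, reliable)


def split_calibration_populations(ratios: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unsupervised live/dead split of pooled ratios by Otsu's criterion.

    Fallback for experiments without an explicit positive-control well: the
    pooled ratio distribution is strongly bimodal, so a two-class variance
    split recovers the populations. Returns (live, dead) samples.
    """
    arr = np.asarray(ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2 or np.ptp(arr) == 0:
        raise ValueError("need at least two distinct ratios to split")
    cut = filters.threshold_otsu(arr)
    return arr[arr <= cut], arr[arr > cut]


def classify(ratio: float, model: ThresholdModel) -> str:
    """"dead" iff the ratio strictly exceeds the threshold, else "live"."""
    return "dead" if ratio > model.threshold else "live"


def assign_death_time(
    track: Track,
    records: list[GEDIRecord] | dict[float, float],
    model: ThresholdModel,
    last_imaging_time: float,
    exclude_flagged: bool = True,
) -> DeathCall:
    """Time of death for one track: first threshold crossing or track loss.

    ``death_time`` is the earliest of (a) the first timepoint whose ratio
    strictly exceeds the threshold and (b) the timepoint the track was lost
    (the loss is dated at the first missing timepoint, where it is actually
    observed). If neither occurs the track is censored at
    ``last_imaging_time``. Artifact-flagged tracks are excluded by default
    (cause ``excluded_artifact``) rather than re-classified.

    Raises
    ------
    ValueError
        On an empty track.
    """
    if not track.observations:
        raise ValueError(f"track {track.track_id} has no observations")
    if exclude_flagged and track.is_flagged:
        return DeathCall(track.track_id, np.nan, False, "excluded_artifact")
    if isinstance(records, dict):
        ratio_by_t = dict(records)
    else:
        ratio_by_t = {r.timepoint: r.gedi_ratio for r in records if r.track_id == track.track_id}

    crossing = None
    for t in track.timepoints:
        if t in ratio_by_t and ratio_by_t[t] > model.threshold:
            crossing = t
            break
    candidates = [t for t in (crossing, track.lost_at) if t is not None]
    if candidates:
        death_time = min(candidates)
        cause = "ratio_crossing" if death_time == crossing else "track_loss"
        return DeathCall(track.track_id, float(death_time), True, cause)
    return DeathCall(track.track_id, float(last_imaging_time), False, "censored")


def curation_concordance(
    calls_by_threshold: dict[int, str],
    calls_by_curation: dict[int, str],
    dead_next_timepoint: set[int] | None = None,
) -> pd.DataFrame:
    """2x2 concordance of threshold vs. manual (by-eye) live/dead calls.

    Returns a table indexed by threshold call with curated calls as columns,
    plus a ``human_error`` count: tracks curated live but above the threshold
    that are unambiguously dead at the next imaged timepoint — the cases
    where the by-eye call, not the threshold, was wrong.

    Raises
    ------
    ValueError
        If the two call sets cover different tracks.
    """
    if set(calls_by_threshold) != set(calls_by_curation):
        raise ValueError("threshold and curation call sets cover different tracks")
    dead_next = dead_next_timepoint or set()
    table = pd.DataFrame(0, index=["live", "dead"], columns=["live", "dead", "human_error"])
    for tid, thr_call in calls_by_threshold.items():
        cur_call = calls_by_curation[tid]
        if thr_call == "dead" and cur_call == "live" and tid in dead_next:
            table.loc["dead", "human_error"] += 1
        else:
            table.loc[thr_call, cur_call] += 1
    return table


def death_calls_to_frame(calls: list[DeathCall], groups: dict[int, str] | None = None,
                         wells: dict[int, str] | None = None) -> pd.DataFrame:
    """Flatten death calls to the survival CSV schema."""
    rows = []
    for c in calls:
        rows.append({
            "id": c.track_id,
            "well": (wells or {}).get(c.track_id, ""),
            "group": (groups or {}).get(c.track_id, ""),
            "time": c.death_time,
            "event": c.event,
            "cause": c.cause,
        })
    return pd.DataFrame(rows, columns=["id", "well", "group", "time", "event", "cause"])
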