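"""Synthetic two-channel time-lapse plates with known ground truth.

Robotic-microscopy survival experiments image sparsely transfected neurons in
multiwell plates at fixed intervals in two channels: a constitutive
morphology fluorophore (used for segmentation and normalisation) and the
death-indicator channel. This module emulates that data at the statistical
level the downstream pipeline assumes:

* somata are rendered as Gaussian blobs with faint neurite strokes on a
  noisy, optionally graded background;
* each neuron carries a programmed death time drawn from a group-specific
  proportional-hazards law (exponential by default, Weibull optional);
* before death the GEDI:morphology intensity ratio sits in a low "live"
  band; at death it jumps irreversibly to a high "dead" band;
* after death both channels decay exponentially — with equal half-lives by
  default, matching the observation that the two fluorophores degrade at
  equivalent rates in dead cells — until the debris drops below a
  disappearance floor and the object is removed;
* a global per-timepoint translation jitter emulates stage drift.

Everything is driven by a single integer seed: identical config + seed gives
bit-identical images and truth tables.

The generator also produces survival cohorts (exponential lifetimes under a
group hazard ratio with administrative censoring) and noisy exponential decay
traces, for exercising the statistics layer without images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .sensors import FluorescenceTrace

__all__ = [
    "WellSpec",
    "PlateConfig",
    "GroundTruth",
    "generate_well",
    "generate_plate",
    "generate_survival_cohort",
    "generate_decay_trace",
]

TRUTH_COLUMNS = [
    "neuron_id", "well", "group", "t", "x", "y",
    "true_gedi_intensity", "true_morph_intensity",
    "death_time", "disappear_time", "censored",
]


@dataclass(frozen=True)
class WellSpec:
    """One well: group label, neuron count, and its hazard of death."""

    well: str
    group: str
    n_neurons: int
    hazard_per_h: float  # exponential death rate (events/hour)
    weibull_shape: float = 1.0  # 1.0 = exponential
    positive_control: bool = False  # all neurons die at t=0 (lethal treatment)


@dataclass
class PlateConfig:
    """Full description of a synthetic plate acquisition.

    Defaults emulate a 96-well-format survival experiment sampled every 24 h
    over a week: 4 wells, 125 sparsely plated neurons each, a disease group
    dying at twice the control hazard, and live/dead GEDI-ratio bands of
    0.01 and 0.5.
    """

    wells: list[WellSpec] = field(default_factory=lambda: [
        WellSpec("A1", "control", 125, 0.01),
        WellSpec("A2", "control", 125, 0.01),
        WellSpec("B1", "disease", 125, 0.02),
        WellSpec("B2", "disease", 125, 0.02),
    ])
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0)
    image_shape: tuple[int, int] = (600, 600)
    tile_grid: tuple[int, int] = (1, 1)
    tile_overlap_px: int = 0
    psf_sigma: float = 3.0
    noise_sd: float = 8.0
    background_level: float = 100.0
    background_gradient: float = 0.0  # intensity units across the frame
    soma_peak: float = 4000.0
    live_ratio_mean: float = 0.01
    dead_ratio_mean: float = 0.5
    ratio_jitter_frac: float = 0.05  # lognormal-ish per-neuron spread of bands
    decay_half_life_gedi: float = 20.45
    decay_half_life_morph: float = 20.73
    jitter_px: float = 1.5
    neurite_peak_frac: float = 0.04  # neurite stroke amplitude vs soma peak
    fragmentation: bool = False
    min_spacing_px: float = 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) and np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("psf_sigma", "soma_peak", "decay_half_life_gedi",
                     "decay_half_life_morph", "min_spacing_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.dead_ratio_mean > self.live_ratio_mean:
            raise ValueError("dead_ratio_mean must exceed live_ratio_mean")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        wells = [WellSpec(**w) for w in doc.pop("wells", [])]
        tuples = {k: tuple(v) for k, v in doc.items()
                  if k in ("timepoints", "image_shape", "tile_grid") and isinstance(v, list)}
        doc.update(tuples)
        if wells:
            return cls(wells=wells, **doc)
        return cls(**doc)


@dataclass
class GroundTruth:
    """Per-neuron truth: identity, path, intensities, and death bookkeeping."""

    table: pd.DataFrame  # one row per neuron per timepoint (TRUTH_COLUMNS)

    @property
    def neurons(self) -> pd.DataFrame:
        """One row per neuron (death/censoring summary)."""
        return (
            self.table.groupby("neuron_id")
            .agg(well=("well", "first"), group=("group", "first"),
                 death_time=("death_time", "first"),
                 disappear_time=("disappear_time", "first"),
                 censored=("censored", "first"))
            .reset_index()
        )


def _well_rng(config: PlateConfig, well: str) -> np.random.Generator:
    # stable per-well stream: CRC of the well id (process-independent, unlike
    # the builtin str hash) spawns an independent substream off the plate seed
    return np.random.default_rng([config.seed, zlib.crc32(well.encode()) % (2**31)])


def _place_somata(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  spacing: float, margin: float) -> np.ndarray:
    """Jittered-grid placement guaranteeing pairwise spacing >= `spacing`."""
    h, w = shape
    cell = spacing + 2.0  # grid pitch; jitter keeps centres >= spacing apart
    cols = int((w - 2 * margin) // cell)
    rows = int((h - 2 * margin) // cell)
    if rows * cols < n:
        raise ValueError(
            f"cannot place {n} somata with spacing {spacing} in a {h}x{w} frame; "
            f"reduce n_neurons or min_spacing_px (capacity {rows * cols})"
        )
    slots = rng.permutation(rows * cols)[:n]
    jit = rng.uniform(-1.0, 1.0, size=(n, 2))
    ys = margin + (slots // cols + 0.5) * cell + jit[:, 0]
    xs = margin + (slots % cols + 0.5) * cell + jit[:, 1]
    return np.column_stack([xs, ys])


def _draw_death_times(rng: np.random.Generator, spec: WellSpec) -> np.ndarray:
    if spec.positive_control:
        return np.zeros(spec.n_neurons)
    if spec.hazard_per_h < 0:
        raise ValueError("hazard must be non-negative")
    if spec.hazard_per_h == 0:
        return np.full(spec.n_neurons, np.inf)
    u = rng.uniform(size=spec.n_neurons)
    scale = 1.0 / spec.hazard_per_h
    return scale * (-np.log(u)) ** (1.0 / spec.weibull_shape)


def _stamp_gaussian(img: np.ndarray, x: float, y: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


def _stamp_neurites(img: np.ndarray, rng_angles: np.ndarray, x: float, y: float,
                    sigma: float, amp: float, length: float) -> None:
    # thin dim strokes radiating from the soma; deliberately far below any
    # sensible segmentation threshold
    for ang in rng_angles:
        ts = np.linspace(2 * sigma, length, 12)
        for t in ts:
            _stamp_gaussian(img, x + t * np.cos(ang), y + t * np.sin(ang), sigma * 0.45,
                            amp * np.exp(-t / length))


def _render_frame(config: PlateConfig, states: list[dict], jitter: np.ndarray,
                  channel: str, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_shape
    img = np.full((h, w), config.background_level, dtype=float)
    if config.background_gradient:
        img += config.background_gradient * (np.arange(w) / max(w - 1, 1))[None, :]
    for st in states:
        if not st["visible"]:
            continue
        amp = st["gedi_amp"] if channel == "gedi" else st["morph_amp"]
        x = st["x"] + jitter[0]
        y = st["y"] + jitter[1]
        if st["fragmented"]:
            for fx, fy, ffrac in st["fragments"]:
                _stamp_gaussian(img, x + fx, y + fy, config.psf_sigma * 0.6, amp * ffrac)
        else:
            _stamp_gaussian(img, x, y, config.psf_sigma, amp)
            if channel == "morphology":
                _stamp_neurites(img, st["neurite_angles"], x, y, config.psf_sigma,
                                amp * config.neurite_peak_frac, length=6 * config.psf_sigma)
    img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0, 65535)


def _split_tiles(frame: np.ndarray, grid: tuple[int, int], overlap: int) -> dict[tuple[int, int], np.ndarray]:
    rows, cols = grid
    h, w = frame.shape
    th = (h + (rows - 1) * overlap) // rows
    tw = (w + (cols - 1) * overlap) // cols
    tiles = {}
    for r in range(rows):
        for c in range(cols):
            y0 = r * (th - overlap)
            x0 = c * (tw - overlap)
            tiles[(r, c)] = frame[y0 : y0 + th, x0 : x0 + tw]
    return tiles


def generate_well(config: PlateConfig, well: str) -> tuple[dict, GroundTruth]:
    """Render one well's full time series and return images + ground truth.

    Returns
    -------
    images : dict keyed by ``(timepoint, channel, (tile_row, tile_col))`` of
        uint16 arrays.
    truth : GroundTruth with one row per neuron per timepoint (whether or not
        the object is still visible), plus death/disappearance bookkeeping.
    """
    spec = next((wsp for wsp in config.wells if wsp.well == well), None)
    if spec is None:
        raise KeyError(f"well {well!r} not in config")
    rng = _well_rng(config, well)
    n = spec.n_neurons
    margin = 6 * config.psf_sigma
    centers = (_place_somata(rng, n, config.image_shape, config.min_spacing_px, margin)
               if n else np.empty((0, 2)))
    death_times = _draw_death_times(rng, spec)
    end_time = config.timepoints[-1] if config.timepoints else 0.0

    # per-neuron band draws: live/dead ratios and morphology brightness
    live_ratios = config.live_ratio_mean * np.exp(
        rng.normal(0, config.ratio_jitter_frac, n))
    dead_ratios = config.dead_ratio_mean * np.exp(
        rng.normal(0, config.ratio_jitter_frac, n))
    morph_amps = config.soma_peak * np.exp(rng.normal(0, 0.1, n))
    neurite_angles = [rng.uniform(0, 2 * np.pi, size=rng.integers(2, 5)) for _ in range(n)]
    frag_layouts = []
    for _ in range(n):
        k = rng.integers(2, 5)
        offs = rng.uniform(-2.5 * config.psf_sigma, 2.5 * config.psf_sigma, size=(k, 2))
        fracs = rng.dirichlet(np.ones(k))
        frag_layouts.append([(ox, oy, fr) for (ox, oy), fr in zip(offs, fracs)])

    jitters = rng.normal(0, config.jitter_px, size=(len(config.timepoints), 2))
    if len(jitters):
        jitters[0] = 0.0  # first frame is the registration reference

    floor = 2.0 * config.noise_sd
    rows = []
    images: dict = {}
    disappear_times = np.full(n, np.inf)

    for ti, t in enumerate(config.timepoints):
        states = []
        for i in range(n):
            dead = t >= death_times[i]
            if dead:
                dt = t - death_times[i]
                morph = morph_amps[i] * 2.0 ** (-dt / config.decay_half_life_morph)
                gedi = dead_ratios[i] * morph_amps[i] * 2.0 ** (-dt / config.decay_half_life_gedi)
            else:
                morph = morph_amps[i]
                gedi = live_ratios[i] * morph_amps[i]
            visible = morph >= floor
            if not visible and disappear_times[i] == np.inf:
                disappear_times[i] = t
            states.append({
                "x": centers[i, 0], "y": centers[i, 1],
                "morph_amp": morph, "gedi_amp": gedi,
                "visible": visible,
                "fragmented": config.fragmentation and dead and visible,
                "fragments": frag_layouts[i],
                "neurite_angles": neurite_angles[i],
            })
            rows.append({
                "neuron_id": f"{well}-{i:04d}", "well": well, "group": spec.group,
                "t": t, "x": centers[i, 0] + jitters[ti, 0], "y": centers[i, 1] + jitters[ti, 1],
                "true_gedi_intensity": gedi, "true_morph_intensity": morph,
                "death_time": death_times[i] if death_times[i] <= end_time else np.nan,
                "disappear_time": np.nan,  # filled below once known
                "censored": death_times[i] > end_time,
            })
        for channel in ("gedi", "morphology"):
            frame = _render_frame(config, states, jitters[ti], channel, rng)
            for (r, c), tile in _split_tiles(frame, config.tile_grid, config.tile_overlap_px).items():
                images[(t, channel, (r, c))] = tile.astype(np.uint16)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if len(truth):
        dis = pd.Series(
            {f"{well}-{i:04d}": (disappear_times[i] if np.isfinite(disappear_times[i]) else np.nan)
             for i in range(n)})
        truth["disappear_time"] = truth["neuron_id"].map(dis)
    return images, GroundTruth(truth)


def generate_plate(config: PlateConfig, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a full plate to disk: one TIFF per well/tile/channel/timepoint.

    Filenames follow ``{well}_T{t}_CH{channel}_X{col}_Y{row}.tif`` with the
    timepoint index as ``T``; the ground truth for all wells is concatenated
    into ``truth.csv`` and the acquisition times into ``timepoints.csv``.
    """
    if not config.wells:
        raise ValueError("plate needs at least one well")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is non-empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    truths = []
    for wsp in config.wells:
        images, truth = generate_well(config, wsp.well)
        truths.append(truth.table)
        for (t, channel, (r, c)), tile in images.items():
            ti = config.timepoints.index(t)
            name = f"{wsp.well}_T{ti}_CH{channel}_X{c}_Y{r}.tif"
            tifffile.imwrite(out / name, tile)
    pd.concat(truths, ignore_index=True).to_csv(out / "truth.csv", index=False)
    pd.DataFrame({"timepoint_index": range(len(config.timepoints)),
                  "time_h": config.timepoints}).to_csv(out / "timepoints.csv", index=False)
    return out


def generate_survival_cohort(
    n_per_group: Sequence[int] | dict[str, int],
    baseline_rate: float,
    hazard_ratio: float | Sequence[float],
    censor_time: float,
    seed: int | np.random.Generator = 0,
    group_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate exponential lifetimes under group proportional hazards.

    Group 0 is the reference with rate ``baseline_rate``; group k has rate
    ``baseline_rate * hazard_ratio[k-1]``. Administrative censoring at
    ``censor_time`` hours sets ``event=False`` and ``time=censor_time``.

    Returns a DataFrame with columns ``id, group, time, event``.
    """
    if isinstance(n_per_group, dict):
        group_names = list(n_per_group.keys())
        counts = list(n_per_group.values())
    else:
        counts = list(n_per_group)
    if group_names is None:
        group_names = ["control"] + [f"group{k}" for k in range(1, len(counts))]
    hrs = [hazard_ratio] if np.isscalar(hazard_ratio) else list(hazard_ratio)
    if len(hrs) != len(counts) - 1:
        raise ValueError("need one hazard ratio per non-reference group")
    if baseline_rate <= 0 or any(h <= 0 for h in hrs):
        raise ValueError("rates and hazard ratios must be positive")
    if censor_time < 0:
        raise ValueError("censor_time must be non-negative")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for k, (name, count) in enumerate(zip(group_names, counts)):
        rate = baseline_rate * (1.0 if k == 0 else hrs[k - 1])
        lifetimes = rng.exponential(1.0 / rate, size=count)
        event = lifetimes <= censor_time
        time = np.minimum(lifetimes, censor_time)
        frames.append(pd.DataFrame({
            "id": [f"{name}-{i}" for i in range(count)],
            "group": name, "time": time, "event": event,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_decay_trace(
    initial: float,
    half_life: float,
    times: Sequence[float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> FluorescenceTrace:
    """Exponential decay ``initial * 2^(-t/half_life)`` plus Gaussian noise."""
    if initial <= 0:
        raise ValueError("initial intensity must be positive")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(times, dtype=float)
    values = initial * 2.0 ** (-t / half_life)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values = values + rng.normal(0, noise_sd, size=values.shape)
    return FluorescenceTrace(t, values, baseline_window=(0, 1))
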