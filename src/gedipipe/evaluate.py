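"""Evaluate pipeline output against a synthetic plate's ground truth.

Tracks carry no truth identity, so evaluation first matches each track to a
generated neuron by nearest first-observation centroid (the generator
guarantees inter-neuron spacing far above any drift, so the match is
unambiguous within half the minimum spacing), then scores the death calls:
sensitivity = fraction of truly dead neurons called dead, specificity =
fraction of surviving neurons left censored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_tracks_to_truth", "call_performance"]


def match_tracks_to_truth(
    track_table: pd.DataFrame, truth_table: pd.DataFrame, max_dist: float = 21.0
) -> pd.DataFrame:
    """Assign each track to the nearest ground-truth neuron at its birth frame.

    Returns a frame (track_id, neuron_id, dist) containing only matches
    within ``max_dist`` pixels; with well-spaced synthetic plates this covers
    every track exactly once.
    """
    first_obs = (
        track_table.sort_values("timepoint_h").groupby("track_id").first().reset_index()
    )
    rows = []
    for well, obs in first_obs.groupby("well"):
        tw = truth_table[truth_table["well"] == well]
        for _, o in obs.iterrows():
            tr_t = tw[tw["t"] == o["timepoint_h"]]
            if tr_t.empty:
                continue
            d = np.hypot(tr_t["x"] - o["x"], tr_t["y"] - o["y"])
            k = d.idxmin()
            if d[k] <= max_dist:
                rows.append({"track_id": o["track_id"], "neuron_id": tr_t.loc[k, "neuron_id"],
                             "dist": float(d[k])})
    return pd.DataFrame(rows, columns=["track_id", "neuron_id", "dist"])


def call_performance(
    death_calls: pd.DataFrame, truth_table: pd.DataFrame, matching: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity/specificity of dead vs. censored calls against truth."""
    neurons = (
        truth_table.groupby("neuron_id")
        .agg(censored=("censored", "first"))
        .reset_index()
    )
    merged = death_calls.merge(matching, left_on="id", right_on="track_id").merge(
        neurons, on="neuron_id"
    )
    truly_dead = ~merged["censored"]
    called_dead = merged["event"].astype(bool)
    tp = int((truly_dead & called_dead).sum())
    fn = int((truly_dead & ~called_dead).sum())
    tn = int((~truly_dead & ~called_dead).sum())
    fp = int((~truly_dead & called_dead).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_matched": len(merged),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }
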