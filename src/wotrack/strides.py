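"""Gait-cycle segmentation and per-stride muscular indexes.

A stride runs between two successive Lateral Gastrocnemius trigger onsets
of the same leg (foot strike / initial simple support).  Within each
stride the module computes, per muscle, total contraction and relaxation
times, the duty cycle (contraction over stride time, percent), and the
two agonist/antagonist co-contraction times (LG-TA and RF-BF).  All
durations are integer multiples of the 2 ms sample period, and
contraction + relaxation equals the stride time exactly by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import MUSCLES, SAMPLE_MS
from .triggers import TriggerTrain, trigger_edges


def segment_strides(lg_trigger: TriggerTrain) -> list:
    """Half-open sample intervals [start, end) between consecutive LG onsets.

    Incomplete leading/trailing cycles are discarded; fewer than two onsets
    yield an empty list with a warning.
    """
    onsets = trigger_edges(lg_trigger)["onsets"]
    if len(onsets) < 2:
        warnings.warn("fewer than two LG onsets; no complete stride")
        return []
    return [(int(a), int(b)) for a, b in zip(onsets[:-1], onsets[1:])]


def compute_indexes(
    strides: list,
    triggers: dict,
    *,
    leg: str = "R",
    subject_id: str = "S1",
    condition: str = "pre",
    exclude: set | None = None,
) -> pd.DataFrame:
    """Per-stride muscular feature vectors for one leg.

    ``triggers`` maps muscle name (LG, TA, BF, RF) to its TriggerTrain.
    ``exclude`` holds stride indices to drop (e.g. trajectory-curving steps).
    """
    trig = {m: np.asarray(triggers[m].values, dtype=np.uint8) for m in MUSCLES}
    n_samp = len(trig["LG"])
    rows = []
    for k, (s, e) in enumerate(strides):
        valid = e <= n_samp and (exclude is None or k not in exclude)
        e_c = min(e, n_samp)
        n = e - s
        contraction = {m: int(trig[m][s:e_c].sum()) for m in MUSCLES}
        row = {
            "subject_id": subject_id,
            "leg": leg,
            "condition": condition,
            "stride_idx": k,
            "onset": s,
            "stride_time_ms": n * SAMPLE_MS,
            "cocon_lg_ta_ms": int((trig["LG"][s:e_c] & trig["TA"][s:e_c]).sum()) * SAMPLE_MS,
            "cocon_rf_bf_ms": int((trig["RF"][s:e_c] & trig["BF"][s:e_c]).sum()) * SAMPLE_MS,
            "valid": bool(valid),
        }
        for m in MUSCLES:
            c_ms = contraction[m] * SAMPLE_MS
            row[f"dc_{m.lower()}_pct"] = c_ms / row["stride_time_ms"] * 100.0
            row[f"contraction_{m.lower()}_ms"] = c_ms
            row[f"relaxation_{m.lower()}_ms"] = row["stride_time_ms"] - c_ms
        rows.append(row)
    cols = ["subject_id", "leg", "condition", "stride_idx", "onset", "stride_time_ms",
            "cocon_lg_ta_ms", "cocon_rf_bf_ms"] + \
        [f"dc_{m.lower()}_pct" for m in MUSCLES] + \
        [f"contraction_{m.lower()}_ms" for m in MUSCLES] + \
        [f"relaxation_{m.lower()}_ms" for m in MUSCLES] + ["valid"]
    return pd.DataFrame(rows, columns=cols)


def pool_legs(per_leg_tables: list) -> pd.DataFrame:
    """Concatenate per-leg stride tables into one observation table.

    Left and right strides are pooled as independent observations (the leg
    stays as metadata only), ordered chronologically by onset within each
    source table group, and invalid strides are dropped.
    """
    tables = [t for t in per_leg_tables if len(t)]
    if not tables:
        return pd.DataFrame()
    out = pd.concat(tables, ignore_index=True)
    if "valid" in out.columns:
        out = out[out["valid"]].drop(columns=["valid"])
    sort_keys = [k for k in ("subject_id", "condition", "onset") if k in out.columns]
    return out.sort_values(sort_keys, kind="stable").reset_index(drop=True)


def session_features(rec, triggers: dict, exclude_curve_steps: bool = True) -> pd.DataFrame:
    """Segment both legs of a recording and pool their stride features.

    ``triggers`` maps channel label (e.g. ``R_LG``) to TriggerTrain, as
    returned by :func:`wotrack.triggers.binarize_session`.
    """
    tables = []
    for leg in ("R", "L"):
        by_muscle = {m: triggers[f"{leg}_{m}"] for m in MUSCLES}
        strides = segment_strides(by_muscle["LG"])
        exclude = None
        if exclude_curve_steps and rec.truth is not None:
            tt = rec.truth.stride_table
            flagged = tt[(tt["leg"] == leg) & tt["curve_step"]]["stride_idx"]
            exclude = set(int(i) for i in flagged)
        tables.append(compute_indexes(
            strides, by_muscle, leg=leg, subject_id=rec.subject_id,
            condition=rec.condition, exclude=exclude,
        ))
    return pool_legs(tables)
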