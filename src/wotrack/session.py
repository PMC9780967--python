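"""Session container and on-disk round trip.

A :class:`SessionRecording` holds one walking run: 8 surface-EMG channels
(R/L x {LG, TA, BF, RF}, 16-bit-range integer counts) and 7 EEG channels
(T3, C3, Cz, C4, T4, P3, P4, volts), sharing one 500 Hz sample clock.
Synthetic recordings additionally carry ground truth: per-channel activation
masks, per-leg stride onsets, a per-stride truth table and the drawn EEG
band amplitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import EEG_CHANNELS, EMG_CHANNELS, FS_HZ


@dataclass
class GroundTruth:
    """Synthetic-only ground truth attached to a recording."""

    masks: np.ndarray                     # (8, T) uint8, rows follow EMG_CHANNELS
    onsets: dict                          # leg -> strictly increasing sample indices of LG onsets
    stride_table: pd.DataFrame            # one row per complete stride (both legs)
    eeg_amplitudes: pd.DataFrame | None   # drawn per-stride band amplitudes, dB re 1 uV

    def __post_init__(self):
        for leg, o in self.onsets.items():
            o = np.asarray(o)
            if o.size > 1 and not np.all(np.diff(o) > 0):
                raise ValueError(f"stride onsets for leg {leg!r} must be strictly increasing")
        if not np.isin(self.masks, (0, 1)).all():
            raise ValueError("mask values must be 0/1")


@dataclass
class SessionRecording:
    emg: np.ndarray                       # (8, T) int16-range integers
    eeg: np.ndarray | None                # (7, T) volts, or None when the EEG branch is off
    fs_hz: int = FS_HZ
    emg_labels: tuple = EMG_CHANNELS
    eeg_labels: tuple = EEG_CHANNELS
    subject_id: str = "S1"
    run_id: int = 0
    condition: str = "pre"
    truth: GroundTruth | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    def __post_init__(self):
        if self.emg.ndim != 2 or self.emg.shape[0] != len(self.emg_labels):
            raise ValueError("emg must be (8, T)")
        if self.emg.shape[1] == 0:
            raise ValueError("empty recording")
        if self.eeg is not None and self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("emg and eeg must share the sample clock")

    def emg_channel(self, label: str) -> np.ndarray:
        return self.emg[self.emg_labels.index(label)]


def write_session(rec: SessionRecording, out_dir: str | Path) -> Path:
    """Persist a recording as delimiter-separated signals + JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cols = {lab: rec.emg[i] for i, lab in enumerate(rec.emg_labels)}
    if rec.eeg is not None:
        cols.update({lab: rec.eeg[i] for i, lab in enumerate(rec.eeg_labels)})
    pd.DataFrame(cols).to_csv(out_dir / "signals.csv", index=False, float_format="%.8e")

    meta = {
        "fs_hz": rec.fs_hz,
        "emg_labels": list(rec.emg_labels),
        "eeg_labels": list(rec.eeg_labels) if rec.eeg is not None else [],
        "subject_id": rec.subject_id,
        "run_id": rec.run_id,
        "condition": rec.condition,
        "n_samples": int(rec.n_samples),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))

    if rec.truth is not None:
        t = rec.truth
        pd.DataFrame({lab: t.masks[i] for i, lab in enumerate(rec.emg_labels)}).to_csv(
            out_dir / "truth_masks.csv", index=False
        )
        t.stride_table.to_csv(out_dir / "truth_strides.csv", index=False)
        if t.eeg_amplitudes is not None:
            t.eeg_amplitudes.to_csv(out_dir / "truth_eeg.csv", index=False)
        (out_dir / "truth.json").write_text(
            json.dumps({leg: [int(x) for x in o] for leg, o in t.onsets.items()})
        )
    return out_dir


def read_session(in_dir: str | Path) -> SessionRecording:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    sig = pd.read_csv(in_dir / "signals.csv")
    emg = np.asarray([sig[lab].to_numpy() for lab in meta["emg_labels"]], dtype=np.int32)
    eeg = None
    if meta["eeg_labels"]:
        eeg = np.asarray([sig[lab].to_numpy() for lab in meta["eeg_labels"]], dtype=float)

    truth = None
    if (in_dir / "truth.json").exists():
        onsets = {
            leg: np.asarray(o, dtype=np.int64)
            for leg, o in json.loads((in_dir / "truth.json").read_text()).items()
        }
        masks_df = pd.read_csv(in_dir / "truth_masks.csv")
        masks = np.asarray(
            [masks_df[lab].to_numpy() for lab in meta["emg_labels"]], dtype=np.uint8
        )
        stride_table = pd.read_csv(in_dir / "truth_strides.csv")
        eeg_amp = None
        if (in_dir / "truth_eeg.csv").exists():
            eeg_amp = pd.read_csv(in_dir / "truth_eeg.csv")
        truth = GroundTruth(masks=masks, onsets=onsets, stride_table=stride_table,
                            eeg_amplitudes=eeg_amp)

    return SessionRecording(
        emg=emg,
        eeg=eeg,
        fs_hz=meta["fs_hz"],
        emg_labels=tuple(meta["emg_labels"]),
        eeg_labels=tuple(meta["eeg_labels"]) if meta["eeg_labels"] else EEG_CHANNELS,
        subject_id=meta["subject_id"],
        run_id=meta["run_id"],
        condition=meta["condition"],
        truth=truth,
    )
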