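"""Movement-related-potential band features from EEG.

The EEG branch keeps a FIFO of the most recent 256 samples (~512 ms at
500 Hz) per channel.  Each time a Lateral Gastrocnemius trigger fires
(foot strike), the buffer snapshot is analysed by a short-time Fourier
transform and, per channel, the maximum spectral magnitude inside each
movement-related band is expressed in dB relative to 1 uV:

* BP  (Bereitschaftspotential), 2-5 Hz
* mu  rhythm, 9-11 Hz
* beta rhythm, 12-30 Hz

Magnitudes are coherent-gain corrected so a unit-amplitude sinusoid on a
bin centre yields peak magnitude equal to its amplitude, which makes the
1 uV reference physically meaningful.  Features are floored at -120 dBu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import EEG_CHANNELS, FS_HZ, MRP_BANDS

WINDOW_SAMPLES = 256
DB_FLOOR = -120.0


@dataclass
class MRPConfig:
    frame: int = 128
    hop: int = 64
    window: str = "hann"        # "hann" or "rect"
    use_power: bool = False     # band maximum of |X| (default) or |X|^2

    def __post_init__(self):
        if not 1 <= self.frame <= WINDOW_SAMPLES:
            raise ValueError("frame must be in [1, 256]")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")


def _band_bins(frame: int, f_lo: float, f_hi: float) -> np.ndarray:
    """Bin indices whose centre frequency falls inside [f_lo, f_hi].

    With coarse frames a band can contain no bin centre; the bin nearest
    the band midpoint is then used so the feature stays defined.
    """
    freqs = np.fft.rfftfreq(frame, d=1.0 / FS_HZ)
    inside = np.flatnonzero((freqs >= f_lo) & (freqs <= f_hi))
    if inside.size:
        return inside
    return np.array([int(np.argmin(np.abs(freqs - 0.5 * (f_lo + f_hi))))])


def _stft_magnitude(x: np.ndarray, cfg: MRPConfig) -> np.ndarray:
    """(frames, bins) magnitude spectrum, amplitude-normalized."""
    if cfg.window == "hann":
        win = np.hanning(cfg.frame)
    elif cfg.window == "rect":
        win = np.ones(cfg.frame)
    else:
        raise ValueError(f"unknown window {cfg.window!r}")
    starts = range(0, x.size - cfg.frame + 1, cfg.hop)
    frames = np.asarray([x[s:s + cfg.frame] * win for s in starts])
    # 2/sum(win): a unit in-bin sinusoid gives peak magnitude 1
    return np.abs(np.fft.rfft(frames, axis=1)) * (2.0 / win.sum())


def extract_mrp(eeg_window: np.ndarray, cfg: MRPConfig | None = None) -> dict:
    """21 band features (dB re 1 uV) from a 7 x 256 EEG window in volts."""
    cfg = cfg or MRPConfig()
    eeg_window = np.asarray(eeg_window, dtype=float)
    if eeg_window.shape != (len(EEG_CHANNELS), WINDOW_SAMPLES):
        raise ValueError(f"EEG window must be 7 x {WINDOW_SAMPLES}")
    out = {}
    for ci, ch in enumerate(EEG_CHANNELS):
        mag = _stft_magnitude(eeg_window[ci], cfg)
        if cfg.use_power:
            mag = mag ** 2
        for band, (f_lo, f_hi) in MRP_BANDS.items():
            bins = _band_bins(cfg.frame, f_lo, f_hi)
            peak = float(mag[:, bins].max())
            if cfg.use_power:
                peak = np.sqrt(peak)
            db = 20.0 * np.log10(peak / 1e-6) if peak > 0 else DB_FLOOR
            out[f"{band}_{ch}_dbu"] = max(db, DB_FLOOR)
    return out


class EEGFifo:
    """Fixed-capacity FIFO over the most recent 256 samples per channel."""

    def __init__(self, n_channels: int = len(EEG_CHANNELS)):
        self._buf = np.zeros((n_channels, WINDOW_SAMPLES))
        self._filled = 0

    @property
    def full(self) -> bool:
        return self._filled >= WINDOW_SAMPLES

    def push(self, samples: np.ndarray) -> None:
        """Append new samples (n_channels x k); oldest are evicted."""
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        k = samples.shape[1]
        if k >= WINDOW_SAMPLES:
            self._buf = samples[:, -WINDOW_SAMPLES:].copy()
        else:
            self._buf = np.concatenate([self._buf[:, k:], samples], axis=1)
        self._filled = min(self._filled + k, WINDOW_SAMPLES)

    def snapshot(self) -> np.ndarray:
        if not self.full:
            raise ValueError("FIFO underfilled: fewer than 256 samples pushed")
        return self._buf.copy()


def session_mrp_features(rec, feature_table: pd.DataFrame,
                         cfg: MRPConfig | None = None) -> pd.DataFrame:
    """Append the 21 MRP features to a per-stride feature table.

    For each stride row the EEG snapshot ends at that stride's detected LG
    onset, mirroring the FIFO triggering.  Strides whose onset precedes a
    full buffer get NaN features.
    """
    if rec.eeg is None:
        raise ValueError("recording has no EEG channels")
    cfg = cfg or MRPConfig()
    feats = []
    for onset in feature_table["onset"]:
        t = int(onset)
        if t + 1 < WINDOW_SAMPLES:
            feats.append({})
            continue
        feats.append(extract_mrp(rec.eeg[:, t + 1 - WINDOW_SAMPLES:t + 1], cfg))
    return pd.concat([feature_table.reset_index(drop=True), pd.DataFrame(feats)], axis=1)
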