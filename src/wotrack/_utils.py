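"""Small shared helpers: seeding, rounding, run-length encoding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

#: one sEMG/EEG sample at 500 Hz, in milliseconds
SAMPLE_MS = 2
FS_HZ = 500

EMG_CHANNELS = ("R_LG", "R_TA", "R_BF", "R_RF", "L_LG", "L_TA", "L_BF", "L_RF")
EEG_CHANNELS = ("T3", "C3", "Cz", "C4", "T4", "P3", "P4")
MUSCLES = ("LG", "TA", "BF", "RF")
MRP_BANDS = {"bp": (2.0, 5.0), "mu": (9.0, 11.0), "beta": (12.0, 30.0)}

MUSCULAR_FEATURES = (
    "stride_time_ms",
    "cocon_lg_ta_ms",
    "cocon_rf_bf_ms",
    "dc_lg_pct",
    "dc_ta_pct",
    "dc_rf_pct",
    "dc_bf_pct",
)


def derive_rng(master_seed: int, *key) -> np.random.Generator:
    """Deterministic per-stage RNG derived from a master seed and a key path.

    Non-integer key parts are hashed to stable 32-bit words so that e.g.
    subject labels can participate in the derivation.
    """
    words = [int(master_seed) & 0x7FFFFFFF]
    for part in key:
        if isinstance(part, (int, np.integer)):
            words.append(int(part) & 0xFFFFFFFF)
        else:
            h = 2166136261
            for ch in str(part).encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
            words.append(h)
    return np.random.default_rng(np.random.SeedSequence(words))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at `ndigits` decimals (table convention)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def run_lengths(binary: np.ndarray):
    """Return (starts, lengths, values) of maximal constant runs of a 1-D array."""
    binary = np.asarray(binary)
    if binary.size == 0:
        return np.array([], int), np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(binary)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [binary.size])))
    return starts, lengths, binary[starts]
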