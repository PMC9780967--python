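"""Synthetic walking-session generator.

Emulates the bilateral lower-limb sEMG + EEG recordings of a 10-m-walk
protocol in Parkinson's patients, before ("pre", OFF state) and after
("post", ON state) Levodopa administration.  Each leg is a renewal process
of strides anchored at the Lateral Gastrocnemius (LG) onset (foot strike).
Within a stride, each muscle's activation window is placed by a fixed
physiologically motivated phase template and sized so that the realized
duty cycles and agonist/antagonist co-contraction times match the
configured condition statistics in expectation:

* LG fires at foot strike, for ``dc_lg`` percent of the stride;
* TA spans late swing through foot strike, so its burst straddles the
  stride boundary and overlaps the LG burst for the drawn LG-TA
  co-contraction time;
* RF fires from foot strike through stance; BF overlaps the end of the RF
  burst for the drawn RF-BF co-contraction time.

sEMG is baseline white noise plus a 20-200 Hz band-limited Gaussian
carrier, amplitude-modulated by a trapezoidal envelope of the activation
mask (20 ms linear ramps centred on the mask edges).  EEG is 1/f
background plus band-limited movement-related bursts (delta/BP, mu, beta)
time-locked 100-500 ms before every LG onset; the burst amplitude draws
are taken from a condition-independent random stream, so for matched
seeds the pre and post ground-truth band features are identical by
construction (the cortical null).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._utils import (EEG_CHANNELS, EMG_CHANNELS, FS_HZ, MRP_BANDS, MUSCLES,
                     SAMPLE_MS, derive_rng)
from .session import GroundTruth, SessionRecording

# Table of condition statistics: stride time, per-muscle duty cycles and the
# two co-contraction times.  Means follow the published population table;
# SDs follow the running-text population description (the only place SDs are
# given); duty-cycle SDs are only published for the pre condition and are
# reused for post.
_PRE = dict(
    stride_time_mean_ms=1081.09, stride_time_sd_ms=72.01,
    dc_mean_pct={"LG": 24.78, "TA": 63.48, "BF": 23.31, "RF": 56.29},
    dc_sd_pct={"LG": 3.70, "TA": 5.44, "BF": 2.42, "RF": 5.49},
    cocon_lg_ta_mean_ms=113.74, cocon_lg_ta_sd_ms=32.12,
    cocon_rf_bf_mean_ms=232.51, cocon_rf_bf_sd_ms=50.04,
)
_POST = dict(
    stride_time_mean_ms=1044.64, stride_time_sd_ms=34.49,
    dc_mean_pct={"LG": 24.34, "TA": 63.49, "BF": 23.54, "RF": 57.49},
    dc_sd_pct={"LG": 3.70, "TA": 5.44, "BF": 2.42, "RF": 5.49},
    cocon_lg_ta_mean_ms=106.16, cocon_lg_ta_sd_ms=29.19,
    cocon_rf_bf_mean_ms=228.02, cocon_rf_bf_sd_ms=17.00,
)

#: Published pre-condition EEG band features (dB re 1 uV) per channel,
#: (BP, mu, beta).  Used as the means of the ground-truth band-feature draws;
#: identical for both conditions (the cortical null).
EEG_BAND_MEANS_DBU = {
    "T4": (61.97, 47.97, 40.50),
    "T3": (60.49, 48.02, 40.00),
    "C4": (59.50, 46.99, 40.97),
    "C3": (61.51, 48.96, 42.51),
    "Cz": (62.50, 49.52, 37.49),
    "P4": (63.02, 48.51, 44.03),
    "P3": (63.02, 48.47, 43.98),
}
EEG_BAND_SD_DB = 1.5


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition stride statistics driving the generator."""

    condition: str
    stride_time_mean_ms: float
    stride_time_sd_ms: float
    dc_mean_pct: dict
    dc_sd_pct: dict
    cocon_lg_ta_mean_ms: float
    cocon_lg_ta_sd_ms: float
    cocon_rf_bf_mean_ms: float
    cocon_rf_bf_sd_ms: float
    subject_sd_scale: float = 0.03   # between-subject multiplicative effect on means

    def __post_init__(self):
        if self.condition not in ("pre", "post"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.stride_time_mean_ms <= 0 or self.stride_time_sd_ms < 0:
            raise ValueError("stride time mean must be > 0 and SD >= 0")
        for m in MUSCLES:
            if not 0 < self.dc_mean_pct[m] < 100:
                raise ValueError(f"duty-cycle mean for {m} must lie in (0, 100)")
            if self.dc_sd_pct[m] < 0:
                raise ValueError("duty-cycle SDs must be >= 0")
        for v in (self.cocon_lg_ta_mean_ms, self.cocon_lg_ta_sd_ms,
                  self.cocon_rf_bf_mean_ms, self.cocon_rf_bf_sd_ms,
                  self.subject_sd_scale):
            if v < 0:
                raise ValueError("co-contraction and subject-effect parameters must be >= 0")


@dataclass(frozen=True)
class NoiseProfile:
    """Signal-synthesis knobs (everything downstream of the stride statistics)."""

    snr_db: float = 20.0            # burst RMS over baseline RMS, in dB
    emg_noise_rms: float = 30.0     # baseline noise RMS, ADC counts
    ramp_ms: float = 20.0           # trapezoid rise/fall time
    lead_in_ms: float = 1000.0      # quiet standing before the first stride
    lead_out_ms: float = 1000.0
    eeg_background_uv: float = 20.0
    eeg_burst_uv: dict = field(default_factory=lambda: {"bp": 8.0, "mu": 5.0, "beta": 3.0})
    curve_steps: int = 0            # strides flagged at each end of a run (trajectory curving)


def default_params(condition: str, dc_convention: str = "table") -> ConditionParams:
    """Built-in condition statistics.

    ``dc_convention`` selects which of the two mutually inconsistent
    published TA/RF duty-cycle listings to use: ``"table"`` (TA ~63%,
    RF ~56%) or ``"text"`` (the swapped values, TA ~56%, RF ~63%).
    """
    if condition == "pre":
        base = dict(_PRE)
    elif condition == "post":
        base = dict(_POST)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if dc_convention == "text":
        dc = dict(base["dc_mean_pct"])
        dc["TA"], dc["RF"] = dc["RF"], dc["TA"]
        base["dc_mean_pct"] = dc
    elif dc_convention != "table":
        raise ValueError("dc_convention must be 'table' or 'text'")
    base["dc_mean_pct"] = dict(base["dc_mean_pct"])
    base["dc_sd_pct"] = dict(base["dc_sd_pct"])
    return ConditionParams(condition=condition, **base)


def subject_params(params: ConditionParams, master_seed: int, subject_id: str) -> ConditionParams:
    """Apply the per-subject multiplicative random effect to all feature means.

    Multipliers are derived from ``(master_seed, subject_id)`` only, so a
    subject keeps the same gait scale in both conditions, as a real subject
    would; paired pre/post contrasts are therefore unaffected by the effect.
    """
    rng = derive_rng(master_seed, "subject-effect", subject_id)
    s = params.subject_sd_scale
    mult = dict(zip(
        ["stride", "cc_lgta", "cc_rfbf", "LG", "TA", "BF", "RF"],
        np.clip(rng.normal(1.0, s, 7), 0.7, 1.3),
    ))
    dc_mean = {m: min(params.dc_mean_pct[m] * mult[m], 97.0) for m in MUSCLES}
    return replace(
        params,
        stride_time_mean_ms=params.stride_time_mean_ms * mult["stride"],
        cocon_lg_ta_mean_ms=params.cocon_lg_ta_mean_ms * mult["cc_lgta"],
        cocon_rf_bf_mean_ms=params.cocon_rf_bf_mean_ms * mult["cc_rfbf"],
        dc_mean_pct=dc_mean,
    )


# ---------------------------------------------------------------------------
# stride-record drawing

def _cocon_draw_shift(params: ConditionParams, pair: tuple) -> float:
    """Mean compensation for the co-contraction cap.

    A co-contraction time cannot exceed either muscle's contraction time, so
    draws are capped at the realized minimum per stride.  With the default
    condition statistics the RF-BF co-contraction mean sits within one SD of
    the BF contraction mean, so the cap binds often enough to bias the
    realized mean visibly.  The draw mean is therefore shifted by the root
    ``delta`` of ``E[min(N(m + delta, s), cap)] = m`` under a normal
    approximation of the tighter cap, which re-centres the realized mean on
    the configured one.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    if pair == ("LG", "TA"):
        mw, sw = params.cocon_lg_ta_mean_ms, params.cocon_lg_ta_sd_ms
    else:
        mw, sw = params.cocon_rf_bf_mean_ms, params.cocon_rf_bf_sd_ms
    # normal approximation of the tighter cap (the smaller-mean muscle)
    m_tight = min(pair, key=lambda m: params.dc_mean_pct[m])
    mc = params.dc_mean_pct[m_tight] / 100.0 * params.stride_time_mean_ms
    sc = np.hypot(params.dc_mean_pct[m_tight] / 100.0 * params.stride_time_sd_ms,
                  params.dc_sd_pct[m_tight] / 100.0 * params.stride_time_mean_ms)
    s = np.hypot(sw, sc)
    if s < 1e-9:
        return 0.0

    def gap(delta):
        a = (mc - mw - delta) / s
        e_min = (mw + delta) * norm.cdf(a) + mc * norm.cdf(-a) - s * norm.pdf(a)
        return e_min - mw

    if gap(0.0) >= 0.0:
        return 0.0
    hi = abs(mc - mw) + 10.0 * s
    if gap(hi) < 0.0:
        # configured co-contraction mean is unreachable under the cap
        # (possible under extreme subject effects); saturate.
        return hi
    return float(brentq(gap, 0.0, hi))


def _draw_stride_records(params: ConditionParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n stride records (sample-domain geometry) for one leg."""
    S_ms = rng.normal(params.stride_time_mean_ms, params.stride_time_sd_ms, n)
    S = np.rint(np.clip(S_ms, 700.0, None) / SAMPLE_MS).astype(np.int64)

    c = {}
    for m in MUSCLES:
        dc = np.clip(rng.normal(params.dc_mean_pct[m], params.dc_sd_pct[m], n), 2.0, 95.0)
        c[m] = np.clip(np.rint(dc / 100.0 * S), 1, S - 1).astype(np.int64)

    d_lgta = _cocon_draw_shift(params, ("LG", "TA"))
    v_ms = rng.normal(params.cocon_lg_ta_mean_ms + d_lgta, params.cocon_lg_ta_sd_ms, n)
    v = np.rint(np.clip(v_ms, 0.0, None) / SAMPLE_MS).astype(np.int64)
    v = np.clip(v, np.maximum(0, c["LG"] + c["TA"] - S), np.minimum(c["LG"], c["TA"]))

    d_rfbf = _cocon_draw_shift(params, ("RF", "BF"))
    w_ms = rng.normal(params.cocon_rf_bf_mean_ms + d_rfbf, params.cocon_rf_bf_sd_ms, n)
    w = np.rint(np.clip(w_ms, 0.0, None) / SAMPLE_MS).astype(np.int64)
    w = np.clip(w, np.maximum(0, c["RF"] + c["BF"] - S), np.minimum(c["RF"], c["BF"]))

    return pd.DataFrame({
        "S": S, "c_LG": c["LG"], "c_TA": c["TA"], "c_BF": c["BF"], "c_RF": c["RF"],
        "v_lgta": v, "w_rfbf": w,
    })


def _paint_leg_masks(rec: pd.DataFrame, onset0: int, masks: dict):
    """Write one leg's activation windows into the per-muscle mask arrays.

    Returns the onset sample of each stride record.
    """
    onsets = onset0 + np.concatenate(([0], np.cumsum(rec["S"].to_numpy()[:-1])))
    for o, row in zip(onsets, rec.itertuples()):
        S, clg, cta, cbf, crf, v, w = row.S, row.c_LG, row.c_TA, row.c_BF, row.c_RF, \
            row.v_lgta, row.w_rfbf
        masks["LG"][o:o + clg] = 1
        masks["TA"][o:o + v] = 1                      # head: carries over foot strike
        masks["TA"][o + S - (cta - v):o + S] = 1      # tail: late stance into swing
        masks["RF"][o:o + crf] = 1
        b0 = o + crf - w                              # BF overlaps the end of RF
        masks["BF"][b0:b0 + cbf] = 1
    return onsets


def _emg_from_mask(mask: np.ndarray, noise: NoiseProfile, rng: np.random.Generator,
                   sos) -> np.ndarray:
    """Baseline noise + band-limited carrier amplitude-modulated by the mask."""
    T = mask.size
    ramp = max(int(round(noise.ramp_ms / SAMPLE_MS)), 1)
    kernel = np.ones(ramp) / ramp
    env = np.convolve(mask.astype(float), kernel, mode="same")
    carrier = sps.sosfilt(sos, rng.standard_normal(T))
    carrier /= max(carrier.std(), 1e-12)
    amp = noise.emg_noise_rms * 10.0 ** (noise.snr_db / 20.0)
    x = noise.emg_noise_rms * rng.standard_normal(T) + amp * env * carrier
    return np.clip(np.rint(x), -32767, 32767).astype(np.int16)


def _pink_noise(T: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-shaped noise."""
    spec = np.fft.rfft(rng.standard_normal(T))
    f = np.fft.rfftfreq(T, d=1.0 / FS_HZ)
    f[0] = f[1] if T > 1 else 1.0
    spec /= np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n=T)
    return x / max(x.std(), 1e-12)


def _eeg_for_session(T: int, all_onsets: list, eeg_rng: np.random.Generator,
                     noise: NoiseProfile):
    """1/f background plus pre-movement band bursts for every LG onset.

    ``all_onsets`` is a list of (leg, stride_index, onset_sample) in a fixed
    (leg, stride) order that does not depend on the onset times.  Burst
    amplitudes, frequencies and latencies are drawn in that order, so two
    sessions generated from the same EEG stream share the draw sequence
    stride for stride even when their gait timing differs.
    """
    # separate substreams: background consumption depends on the session
    # length, which differs across conditions; burst draws must not.
    bg_rng, burst_rng = eeg_rng.spawn(2)
    eeg = np.empty((len(EEG_CHANNELS), T))
    for i in range(len(EEG_CHANNELS)):
        eeg[i] = noise.eeg_background_uv * _pink_noise(T, bg_rng)

    burst_len = int(round(0.300 * FS_HZ))
    win = np.hanning(burst_len)
    t = np.arange(burst_len) / FS_HZ
    rows = []
    for leg, k, onset in all_onsets:
        rec = {"leg": leg, "stride_idx": k, "onset": onset}
        latency = burst_rng.uniform(0.150, 0.450)                # burst centre before onset
        centre = onset - int(round(latency * FS_HZ))
        start = centre - burst_len // 2
        for ci, ch in enumerate(EEG_CHANNELS):
            for band, (f_lo, f_hi) in MRP_BANDS.items():
                amp = abs(burst_rng.normal(noise.eeg_burst_uv[band],
                                           0.2 * noise.eeg_burst_uv[band]))
                freq = burst_rng.uniform(f_lo, f_hi)
                phase = burst_rng.uniform(0, 2 * np.pi)
                lo, hi = max(start, 0), min(start + burst_len, T)
                if hi > lo:
                    seg = slice(lo - start, hi - start)
                    eeg[ci, lo:hi] += amp * win[seg] * np.sin(2 * np.pi * freq * t[seg] + phase)
                rec[f"{band}_{ch}_dbu"] = 20.0 * np.log10(max(amp, 1e-9))
        rows.append(rec)
    return eeg * 1e-6, pd.DataFrame(rows)   # store in volts


def simulate_session(
    params: ConditionParams,
    n_strides: int,
    seed: int,
    noise: NoiseProfile | None = None,
    *,
    eeg_seed: int | None = None,
    include_eeg: bool = True,
    subject_id: str = "S1",
    run_id: int = 0,
) -> SessionRecording:
    """Generate one walking run with ``n_strides`` complete strides per leg.

    ``eeg_seed`` defaults to a stream derived from ``seed`` but can be fixed
    independently; passing the same ``eeg_seed`` (and stride count) to a pre
    and a post session makes the ground-truth EEG band draws identical
    across conditions.  Identical (params, n_strides, seed) give a
    bit-identical recording.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    noise = noise or NoiseProfile()
    if noise.curve_steps * 2 > n_strides:
        raise ValueError("curve_steps exceed the available strides")
    rng = derive_rng(seed, "emg", params.condition)
    eeg_rng = derive_rng(eeg_seed if eeg_seed is not None else seed, "eeg")

    lead_in = int(round(noise.lead_in_ms / SAMPLE_MS))
    lead_out = int(round(noise.lead_out_ms / SAMPLE_MS))

    # n_strides + 1 records per leg: the last one is the terminator whose LG
    # onset closes the final counted stride.
    legs = {}
    for leg in ("R", "L"):
        legs[leg] = _draw_stride_records(params, n_strides + 1, rng)
    offset_L = int(legs["R"]["S"].iloc[0]) // 2         # legs alternate by ~half a stride
    extent = max(lead_in + int(legs["R"]["S"].sum()),
                 lead_in + offset_L + int(legs["L"]["S"].sum()))
    T = extent + lead_out

    masks = {f"{leg}_{m}": np.zeros(T, dtype=np.uint8) for leg in ("R", "L") for m in MUSCLES}
    onsets = {}
    for leg, onset0 in (("R", lead_in), ("L", lead_in + offset_L)):
        sub = {m: masks[f"{leg}_{m}"] for m in MUSCLES}
        onsets[leg] = _paint_leg_masks(legs[leg], onset0, sub)

    sos = sps.butter(4, [20.0, 200.0], btype="bandpass", fs=FS_HZ, output="sos")
    emg = np.empty((len(EMG_CHANNELS), T), dtype=np.int16)
    for i, lab in enumerate(EMG_CHANNELS):
        emg[i] = _emg_from_mask(masks[lab], noise, rng, sos)

    rows = []
    for leg in ("R", "L"):
        rec = legs[leg]
        o = onsets[leg]
        for k in range(n_strides):          # the terminator record is not counted
            r = rec.iloc[k]
            rows.append({
                "leg": leg, "stride_idx": k, "onset": int(o[k]),
                "stride_time_ms": int(r["S"]) * SAMPLE_MS,
                "cocon_lg_ta_ms": int(r["v_lgta"]) * SAMPLE_MS,
                "cocon_rf_bf_ms": int(r["w_rfbf"]) * SAMPLE_MS,
                **{f"dc_{m.lower()}_pct": float(r[f"c_{m}"] / r["S"] * 100.0) for m in MUSCLES},
                **{f"contraction_{m.lower()}_ms": int(r[f"c_{m}"]) * SAMPLE_MS for m in MUSCLES},
                "curve_step": bool(k < noise.curve_steps or k >= n_strides - noise.curve_steps),
            })
    stride_table = pd.DataFrame(rows)

    eeg_sig, eeg_amp = None, None
    if include_eeg:
        events = [(leg, k, int(onsets[leg][k]))
                  for leg in ("R", "L") for k in range(n_strides + 1)]
        eeg_sig, eeg_amp = _eeg_for_session(T, events, eeg_rng, noise)
        eeg_amp = eeg_amp[eeg_amp["stride_idx"] < n_strides].reset_index(drop=True)

    truth = GroundTruth(
        masks=np.asarray([masks[lab] for lab in EMG_CHANNELS]),
        onsets={leg: np.asarray(onsets[leg][: n_strides + 1]) for leg in ("R", "L")},
        stride_table=stride_table,
        eeg_amplitudes=eeg_amp,
    )
    return SessionRecording(
        emg=emg, eeg=eeg_sig, subject_id=subject_id, run_id=run_id,
        condition=params.condition, truth=truth,
    )


# ---------------------------------------------------------------------------
# ground-truth summaries

def realized_statistics(rec: SessionRecording) -> pd.DataFrame:
    """Per-feature mean/SD computed directly from the ground-truth masks.

    Bypasses the detection pipeline entirely: strides are re-segmented from
    the true onsets and contraction/co-contraction samples are counted on
    the true masks, so this doubles as an independent check of the stored
    stride table.
    """
    if rec.truth is None:
        raise ValueError("recording carries no ground truth")
    t = rec.truth
    rows = []
    for leg in t.onsets:
        o = t.onsets[leg]
        m = {mus: t.masks[list(EMG_CHANNELS).index(f"{leg}_{mus}")] for mus in MUSCLES}
        for k in range(len(o) - 1):
            s, e = int(o[k]), int(o[k + 1])
            n = e - s
            c = {mus: int(m[mus][s:e].sum()) for mus in MUSCLES}
            rows.append({
                "leg": leg,
                "stride_time_ms": n * SAMPLE_MS,
                "cocon_lg_ta_ms": int((m["LG"][s:e] & m["TA"][s:e]).sum()) * SAMPLE_MS,
                "cocon_rf_bf_ms": int((m["RF"][s:e] & m["BF"][s:e]).sum()) * SAMPLE_MS,
                **{f"dc_{mus.lower()}_pct": c[mus] / n * 100.0 for mus in MUSCLES},
            })
    per_stride = pd.DataFrame(rows)
    feats = [c for c in per_stride.columns if c != "leg"]
    return pd.DataFrame({
        "mean": per_stride[feats].mean(),
        "sd": per_stride[feats].std(ddof=1),
        "n": len(per_stride),
    })


# ---------------------------------------------------------------------------
# stride-statistics-level tables (no signal synthesis)

def simulate_feature_tables(
    params_pre: ConditionParams,
    params_post: ConditionParams,
    n_pairs: int,
    seed: int,
    n_subjects: int = 3,
    include_eeg: bool = True,
):
    """Draw paired pre/post per-stride feature tables directly.

    This is the statistical-sample layer of the generator: it produces the
    per-stride feature populations (muscular indexes and, optionally, EEG
    band features) without synthesising signals, for use where only the
    population statistics matter (feature-selection studies, large-n
    benchmarks).  Muscular features are drawn independently per condition;
    EEG band features are drawn once from a condition-independent stream
    and shared by both tables, making the cortical pre/post null exact.
    Durations are quantized to the 2 ms sample grid.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    counts = [n_pairs // n_subjects + (1 if i < n_pairs % n_subjects else 0)
              for i in range(n_subjects)]
    tables = {"pre": [], "post": []}
    for i, n_i in enumerate(counts):
        if n_i == 0:
            continue
        subject = f"S{i + 1}"
        eeg_block = None
        if include_eeg:
            eeg_rng = derive_rng(seed, "table-eeg", subject)
            eeg_block = {}
            for ch, means in EEG_BAND_MEANS_DBU.items():
                for band, mu in zip(("bp", "mu", "beta"), means):
                    eeg_block[f"{band}_{ch}_dbu"] = eeg_rng.normal(mu, EEG_BAND_SD_DB, n_i)
        for params in (params_pre, params_post):
            p = subject_params(params, seed, subject)
            rng = derive_rng(seed, "table-emg", subject, params.condition)
            rec = _draw_stride_records(p, n_i, rng)
            tab = pd.DataFrame({
                "subject_id": subject,
                "condition": params.condition,
                "stride_time_ms": rec["S"] * SAMPLE_MS,
                "cocon_lg_ta_ms": rec["v_lgta"] * SAMPLE_MS,
                "cocon_rf_bf_ms": rec["w_rfbf"] * SAMPLE_MS,
                **{f"dc_{m.lower()}_pct": rec[f"c_{m}"] / rec["S"] * 100.0 for m in MUSCLES},
            })
            if eeg_block is not None:
                for col, vals in eeg_block.items():
                    tab[col] = vals
            tables[params.condition].append(tab)
    pre = pd.concat(tables["pre"], ignore_index=True)
    post = pd.concat(tables["post"], ignore_index=True)
    return pre, post
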