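"""Fiber-photometry processing: dF/F, peri-tone z, generalization pooling.

The activity-independent isosbestic channel is fit to the sensor channel
by least squares over the session; dF/F is the residual over the fit.
Signals are downsampled to 10 Hz, aligned to tones, z-scored against each
trial's own 2-second pre-tone baseline, and trials are pooled by the
freezing they elicited: > 75% freezing forms the high-generalization pool,
< 25% the low pool, boundary trials excluded by the strict inequalities.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import EventSchedule, EventType, PhotometrySignal

logger = logging.getLogger(__name__)


def downsample_to(sig: PhotometrySignal, target_hz: float = 10.0) -> PhotometrySignal:
    """Non-overlapping window means at the target rate.

    A trailing partial window is truncated (logged).  Already at the
    target rate, the signal is returned unchanged.
    """
    if sig.rate_hz < target_hz:
        raise ValueError("cannot downsample below the source rate")
    if sig.rate_hz == target_hz:
        return sig
    factor = sig.rate_hz / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("source rate must be an integer multiple of target rate")
    factor = int(round(factor))
    n_out = len(sig.signal) // factor
    if n_out * factor != len(sig.signal):
        logger.info("truncating %d trailing sample(s)", len(sig.signal) - n_out * factor)

    def dec(x: np.ndarray) -> np.ndarray:
        return x[: n_out * factor].reshape(n_out, factor).mean(axis=1)

    return PhotometrySignal(
        t=dec(sig.t), signal=dec(sig.signal), isosbestic=dec(sig.isosbestic),
        rate_hz=target_hz,
    )


def compute_dff(sig: PhotometrySignal) -> np.ndarray:
    """dF/F via least-squares isosbestic fit: (signal - fit) / fit.

    The control channel is linearly fit to the sensor channel over the
    whole session, so shared artifacts (motion, bleaching) cancel while
    sensor-only transients survive.  A zero-variance isosbestic makes the
    fit degenerate; then the session median stands in for F0 (logged).
    """
    s, iso = sig.signal, sig.isosbestic
    if iso.std() == 0:
        logger.warning("flat isosbestic channel; falling back to session-median F0")
        f0 = np.median(s)
        if f0 == 0:
            raise ValueError("degenerate session: zero median fluorescence")
        return (s - f0) / f0
    slope, intercept = np.polyfit(iso, s, 1)
    fit = slope * iso + intercept
    if np.any(fit <= 0):
        raise ValueError("isosbestic fit crosses zero; check raw fluorescence units")
    return (s - fit) / fit


def align_z_pretone(
    dff: np.ndarray,
    schedule: EventSchedule,
    rate_hz: float,
    tone_type: EventType | str | None = None,
    pre_s: float = 2.0,
    tone_s: float = 15.0,
) -> np.ndarray:
    """Per-trial z traces against each trial's 2-s pre-tone baseline.

    Returns (n_trials, n_window_samples) covering [-pre_s, tone_s).
    """
    tones = schedule.tones(tone_type)
    if not tones:
        raise ValueError("no tones in schedule")
    n_pre = int(round(pre_s * rate_hz))
    n_tone = int(round(tone_s * rate_hz))
    out = np.empty((len(tones), n_pre + n_tone))
    for i, ev in enumerate(tones):
        onset = int(round(ev.onset_s * rate_hz))
        lo, hi = onset - n_pre, onset + n_tone
        if lo < 0 or hi > len(dff):
            raise ValueError(f"window for tone at {ev.onset_s:g}s outside recording")
        win = dff[lo:hi]
        base = win[:n_pre]
        sd = base.std(ddof=1)
        if sd == 0:
            out[i] = 0.0
        else:
            out[i] = (win - base.mean()) / sd
    return out


def peak_response(z_trace: np.ndarray, window: tuple[int, int]) -> float:
    """Maximum z within a sample window [lo, hi)."""
    lo, hi = window
    if not 0 <= lo < hi <= len(z_trace):
        raise ValueError("peak window outside trace")
    return float(np.max(z_trace[lo:hi]))


def split_by_generalization(
    trial_z: np.ndarray,
    trial_freezing: np.ndarray,
    high_pct: float = 75.0,
    low_pct: float = 25.0,
    tone_window: tuple[int, int] | None = None,
) -> dict:
    """Pool trials by the freezing they elicited.

    High pool: freezing strictly above ``high_pct``; low pool: strictly
    below ``low_pct``; everything between (inclusive of the boundaries) is
    excluded.  Returns pooled mean traces and per-trial tone-window peaks;
    an empty pool is flagged, not an error.
    """
    trial_z = np.atleast_2d(np.asarray(trial_z, float))
    freezing = np.asarray(trial_freezing, float)
    if len(freezing) != trial_z.shape[0]:
        raise ValueError("one freezing percent per trial required")
    if np.any((freezing < 0) | (freezing > 100)):
        raise ValueError("freezing percents must lie in [0, 100]")
    hi_mask = freezing > high_pct
    lo_mask = freezing < low_pct
    win = tone_window or (0, trial_z.shape[1])

    def pool(mask):
        if not mask.any():
            return {"n": 0, "mean_trace": None, "peaks": np.array([]), "flag": "empty"}
        zs = trial_z[mask]
        return {
            "n": int(mask.sum()),
            "mean_trace": zs.mean(axis=0),
            "peaks": np.array([peak_response(z, win) for z in zs]),
            "flag": None,
        }

    return {
        "high": pool(hi_mask),
        "low": pool(lo_mask),
        "excluded": int((~hi_mask & ~lo_mask).sum()),
    }
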