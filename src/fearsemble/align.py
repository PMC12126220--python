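"""Peri-tone alignment, 1-s binning, block averaging and z-scoring.

Raw traces are aligned to tone onsets and averaged into 1-second bins
(half-open intervals, bin 0 starting at onset), trials are averaged into
blocks of 2 in presentation order, and each neuron x block trace is
z-transformed against its own 15-second pre-tone baseline.  A second,
whole-session z-transform produces the per-neuron scalar responses that
feed the stimulus-preference index.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .io import AlignedZTensor, EventSchedule, EventType, TraceMatrix

logger = logging.getLogger(__name__)


def _bin_edges_samples(onset_s: float, bin_index: int, rate_hz: float) -> tuple[int, int]:
    # half-open [onset + b, onset + b + 1) seconds; round to nearest sample to
    # absorb float jitter in onset times
    start = int(round((onset_s + bin_index) * rate_hz))
    stop = int(round((onset_s + bin_index + 1) * rate_hz))
    return start, stop


def align_and_bin(
    traces: TraceMatrix,
    schedule: EventSchedule,
    tone_type: EventType | str,
    pre_s: int = 15,
    tone_s: int = 15,
) -> np.ndarray:
    """Align traces to tone onsets and average into 1-s bins.

    Returns a (n_neurons, n_trials, pre_s + tone_s) array; bin ``pre_s``
    is the first tone bin (time [onset, onset+1)).

    Raises ``ValueError`` naming the offending event if any requested
    window (15-s pre-tone baseline plus tone period) falls outside the
    recording.
    """
    tones = schedule.tones(tone_type)
    if not tones:
        raise ValueError(f"no tones of type {EventType(tone_type).value} in schedule")
    n_bins = pre_s + tone_s
    out = np.empty((traces.n_neurons, len(tones), n_bins), dtype=float)
    for t_idx, ev in enumerate(tones):
        for b, rel in enumerate(range(-pre_s, tone_s)):
            lo, hi = _bin_edges_samples(ev.onset_s, rel, traces.rate_hz)
            if lo < 0 or hi > traces.n_samples:
                raise ValueError(
                    f"window for event {ev.event_type.value}@{ev.onset_s:g}s "
                    f"(bin {rel}) outside recording of {traces.duration_s:g}s"
                )
            out[:, t_idx, b] = traces.values[:, lo:hi].mean(axis=1)
    return out


def block_average(tensor: np.ndarray, block_size: int = 2) -> np.ndarray:
    """Average trials into consecutive blocks in presentation order.

    Trial axis is axis 1.  A trailing unpaired trial is dropped with a
    warning.
    """
    n_trials = tensor.shape[1]
    n_blocks, rem = divmod(n_trials, block_size)
    if rem:
        warnings.warn(
            f"trial count {n_trials} not divisible by block size {block_size}; "
            f"dropping final {rem} trial(s)",
            stacklevel=2,
        )
    if n_blocks == 0:
        raise ValueError(f"need at least {block_size} trials to form a block")
    trimmed = tensor[:, : n_blocks * block_size]
    shape = (tensor.shape[0], n_blocks, block_size) + tensor.shape[2:]
    return trimmed.reshape(shape).mean(axis=2)


def ztransform_pretone(
    blocked: np.ndarray,
    baseline_bins: int = 15,
    block_size: int = 2,
    neuron_ids: list[str] | None = None,
) -> AlignedZTensor:
    """Z-score each neuron x block trace against its own pre-tone baseline.

    The baseline mean and SD (unbiased, n-1) come from that block's own
    ``baseline_bins`` leading bins.  Zero-SD baselines are flagged and the
    whole block set to z = 0 rather than raising, so degenerate synthetic
    neurons do not abort batch runs.
    """
    if blocked.shape[2] <= baseline_bins:
        raise ValueError("no tone bins after baseline")
    base = blocked[:, :, :baseline_bins]
    mu = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, ddof=1, keepdims=True)
    flags = sd[:, :, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (blocked - mu) / safe_sd
    z[flags] = 0.0
    if flags.any():
        logger.info("zero-SD baseline in %d neuron-block(s); z forced to 0", flags.sum())
    return AlignedZTensor(
        z=z,
        baseline_bins=baseline_bins,
        tone_bins=blocked.shape[2] - baseline_bins,
        block_size=block_size,
        neuron_ids=neuron_ids or [],
        flags=flags,
    )


def peri_tone_tensor(
    traces: TraceMatrix,
    schedule: EventSchedule,
    tone_type: EventType | str,
    pre_s: int = 15,
    tone_s: int = 15,
    block_size: int = 2,
) -> AlignedZTensor:
    """Full align -> bin -> block-average -> pre-tone z pipeline."""
    binned = align_and_bin(traces, schedule, tone_type, pre_s=pre_s, tone_s=tone_s)
    blocked = block_average(binned, block_size=block_size)
    return ztransform_pretone(
        blocked,
        baseline_bins=pre_s,
        block_size=block_size,
        neuron_ids=list(traces.neuron_ids),
    )


def peri_tone_trials(
    traces: TraceMatrix,
    schedule: EventSchedule,
    tone_type: EventType | str,
    pre_s: int = 15,
    tone_s: int = 15,
) -> AlignedZTensor:
    """Per-trial (unblocked) peri-tone z tensor, for stability analyses."""
    binned = align_and_bin(traces, schedule, tone_type, pre_s=pre_s, tone_s=tone_s)
    return ztransform_pretone(
        binned, baseline_bins=pre_s, block_size=1, neuron_ids=list(traces.neuron_ids)
    )


def ztransform_whole_session(
    traces: TraceMatrix,
    schedule: EventSchedule,
    tone_type: EventType | str,
    tone_s: int = 15,
    n_presentations: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Average stimulus z per neuron against the whole-session baseline.

    Averages the first ``n_presentations`` aligned tone-period traces,
    z-scores that average against the neuron's whole-session mean/SD, then
    averages the z over the tone duration.  Returns ``(scalars, flags)``
    where flags mark zero-SD (constant) neurons whose scalar is forced to 0.
    """
    tones = schedule.tones(tone_type)
    if len(tones) < n_presentations:
        raise ValueError(
            f"need >= {n_presentations} presentations of "
            f"{EventType(tone_type).value}, found {len(tones)}"
        )
    rate = traces.rate_hz
    n_win = int(round(tone_s * rate))
    windows = []
    for ev in tones[:n_presentations]:
        lo = int(round(ev.onset_s * rate))
        hi = lo + n_win
        if lo < 0 or hi > traces.n_samples:
            raise ValueError(f"tone window at {ev.onset_s:g}s outside recording")
        windows.append(traces.values[:, lo:hi])
    avg = np.mean(windows, axis=0)  # neurons x window samples
    mu = traces.values.mean(axis=1, keepdims=True)
    sd = traces.values.std(axis=1, ddof=1, keepdims=True)
    flags = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    scalars = ((avg - mu) / safe_sd).mean(axis=1)
    scalars[flags] = 0.0
    return scalars, flags
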