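"""Threshold-based responsive-neuron classification and the 9-type taxonomy.

A neuron is (+)responsive to a tone if its z-scored tone-period trace
exceeds +3 for two consecutive 1-s bins, (-)responsive if it falls below
-3 for two consecutive bins, and non-responsive otherwise.  Combining the
labels for the neutral tone (NT) and the conditioned tone (CS+) yields
3 x 3 = 9 response types; "dual" aggregates every type responsive to both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlignedZTensor, EventSchedule, TraceMatrix


class Label(str, Enum):
    PLUS = "PLUS"
    MINUS = "MINUS"
    NONE = "NONE"


@dataclass(frozen=True)
class ResponseLabel:
    label: Label
    trigger_bin: int | None = None  # first bin of the qualifying pair


ALL_TYPE_CODES = tuple(
    f"{nt.value}/{cs.value}" for nt in Label for cs in Label
)  # 9 ordered (NT, CS+) pairs

DUAL_CODES = tuple(
    f"{nt.value}/{cs.value}"
    for nt in (Label.PLUS, Label.MINUS)
    for cs in (Label.PLUS, Label.MINUS)
)


def _qualifying_pairs(z: np.ndarray, threshold: float, n_consec: int, sign: int):
    """Start indices of runs of n_consec bins strictly beyond the threshold."""
    hit = z > threshold if sign > 0 else z < -threshold
    starts = []
    for i in range(len(z) - n_consec + 1):
        if hit[i : i + n_consec].all():
            starts.append(i)
    return starts


def classify_response(
    z_bins: np.ndarray, threshold: float = 3.0, n_consec: int = 2
) -> ResponseLabel:
    """Classify one tone-period z trace.

    ``z_bins`` covers the tone period only (bin 0 = onset).  PLUS if two
    consecutive bins exceed +threshold, MINUS if two fall below -threshold;
    if both patterns occur the pair with the larger mean |z| decides.
    """
    z = np.asarray(z_bins, float)
    if z.ndim != 1:
        raise ValueError("z_bins must be 1-D (tone-period bins)")
    if len(z) < n_consec:
        raise ValueError(f"need at least {n_consec} tone bins, got {len(z)}")
    plus = _qualifying_pairs(z, threshold, n_consec, +1)
    minus = _qualifying_pairs(z, threshold, n_consec, -1)

    def best(starts):
        means = [np.abs(z[s : s + n_consec]).mean() for s in starts]
        k = int(np.argmax(means))
        return starts[k], means[k]

    if plus and minus:
        ps, pm = best(plus)
        ms, mm = best(minus)
        if pm >= mm:
            return ResponseLabel(Label.PLUS, ps)
        return ResponseLabel(Label.MINUS, ms)
    if plus:
        return ResponseLabel(Label.PLUS, best(plus)[0])
    if minus:
        return ResponseLabel(Label.MINUS, best(minus)[0])
    return ResponseLabel(Label.NONE, None)


def classify_neuron(
    tone_z_blocks: np.ndarray, threshold: float = 3.0, n_consec: int = 2
) -> ResponseLabel:
    """Label a neuron from its per-block tone-period z traces.

    A neuron is responsive if any block qualifies; when blocks disagree in
    sign, the qualifying pair with the larger mean |z| across all blocks
    decides (same tie-break as within a single trace).
    """
    blocks = np.atleast_2d(np.asarray(tone_z_blocks, float))
    best_label, best_mag, best_bin = Label.NONE, -np.inf, None
    for b in blocks:
        lab = classify_response(b, threshold=threshold, n_consec=n_consec)
        if lab.label is Label.NONE:
            continue
        mag = np.abs(b[lab.trigger_bin : lab.trigger_bin + n_consec]).mean()
        if mag > best_mag:
            best_label, best_mag, best_bin = lab.label, mag, lab.trigger_bin
    return ResponseLabel(best_label, best_bin)


def classify_tensor(
    tensor: AlignedZTensor, threshold: float = 3.0, n_consec: int = 2
) -> list[ResponseLabel]:
    """Per-neuron labels from a block-averaged aligned z tensor."""
    return [
        classify_neuron(tz, threshold=threshold, n_consec=n_consec)
        for tz in tensor.tone_z()
    ]


def response_taxonomy(
    labels_nt: list[ResponseLabel],
    labels_cs: list[ResponseLabel],
    neuron_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Assign every neuron one of the 9 NT x CS+ response types.

    Returns a DataFrame (neuron_id, nt_label, cs_label, type_code).  Use
    :func:`taxonomy_proportions` for counts/proportions.
    """
    if len(labels_nt) != len(labels_cs):
        raise ValueError("NT and CS+ label sets must cover identical neurons")
    n = len(labels_nt)
    ids = neuron_ids if neuron_ids is not None else [f"n{i:04d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("neuron_ids length mismatch")
    return pd.DataFrame(
        {
            "neuron_id": ids,
            "nt_label": [l.label.value for l in labels_nt],
            "cs_label": [l.label.value for l in labels_cs],
            "type_code": [
                f"{a.label.value}/{b.label.value}"
                for a, b in zip(labels_nt, labels_cs)
            ],
        }
    )


def taxonomy_proportions(taxonomy: pd.DataFrame) -> dict:
    """Counts and proportions per type plus the dual-responsive aggregate."""
    n = len(taxonomy)
    if n == 0:
        raise ValueError("empty taxonomy")
    counts = Counter(taxonomy["type_code"])
    props = {code: counts.get(code, 0) / n for code in ALL_TYPE_CODES}
    dual = sum(counts.get(code, 0) for code in DUAL_CODES)
    return {
        "n": n,
        "counts": {code: counts.get(code, 0) for code in ALL_TYPE_CODES},
        "proportions": props,
        "dual_count": dual,
        "dual_proportion": dual / n,
    }


def compare_type_proportions(
    counts_a: dict, counts_b: dict, codes: str | list[str]
) -> dict:
    """Fisher's exact test on membership in a type (or aggregate) A vs B.

    ``counts_a``/``counts_b`` are outputs of :func:`taxonomy_proportions`;
    ``codes`` is a type code, list of codes, or the string ``"dual"``.
    """
    if isinstance(codes, str):
        codes = list(DUAL_CODES) if codes == "dual" else [codes]
    for name, c in (("A", counts_a), ("B", counts_b)):
        if c["n"] == 0:
            raise ValueError(f"group {name} is empty")
    in_a = sum(counts_a["counts"][c] for c in codes)
    in_b = sum(counts_b["counts"][c] for c in codes)
    table = [[in_a, counts_a["n"] - in_a], [in_b, counts_b["n"] - in_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p)}


def consecutive_tone_stability(
    per_trial_tensor: AlignedZTensor, threshold: float = 3.0, n_consec: int = 2
) -> dict:
    """Proportion of neurons responsive on >= 2 consecutive presentations.

    Requires a per-trial (block_size = 1) tensor for one tone type; a
    neuron counts iff it is non-NONE on two adjacent presentations.
    """
    if per_trial_tensor.z.shape[1] < 2:
        raise ValueError("need at least 2 presentations")
    tone_z = per_trial_tensor.tone_z()
    stable = np.zeros(tone_z.shape[0], dtype=bool)
    for i, trials in enumerate(tone_z):
        labs = [
            classify_response(t, threshold=threshold, n_consec=n_consec).label
            for t in trials
        ]
        stable[i] = any(
            a is not Label.NONE and b is not Label.NONE
            for a, b in zip(labs, labs[1:])
        )
    return {
        "stable_count": int(stable.sum()),
        "n": int(len(stable)),
        "proportion": float(stable.mean()),
        "stable_mask": stable,
    }


def spontaneous_event_rate(
    traces: TraceMatrix,
    schedule: EventSchedule,
    window: tuple[float, float],
    threshold: float = 3.0,
    n_consec: int = 2,
) -> np.ndarray:
    """Calcium events per minute per neuron in a tone-free window.

    An event is an excursion where the window-normalised z of the 1-s
    binned trace exceeds +threshold for >= n_consec consecutive bins; a
    maximal excursion counts once.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    for ev in schedule.events:
        if ev.onset_s < t1 and ev.offset_s > t0:
            raise ValueError(
                f"window overlaps event {ev.event_type.value}@{ev.onset_s:g}s"
            )
    rate = traces.rate_hz
    lo, hi = int(round(t0 * rate)), int(round(t1 * rate))
    if lo < 0 or hi > traces.n_samples:
        raise ValueError("window outside recording")
    seg = traces.values[:, lo:hi]
    n_bins = int((hi - lo) / rate)
    per_bin = int(round(rate))
    binned = seg[:, : n_bins * per_bin].reshape(traces.n_neurons, n_bins, per_bin).mean(2)
    mu = binned.mean(axis=1, keepdims=True)
    sd = binned.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(binned - mu, sd, out=np.zeros_like(binned), where=sd > 0)
    minutes = (t1 - t0) / 60.0
    rates = np.empty(traces.n_neurons)
    for i, zi in enumerate(z):
        hit = zi > threshold
        events = 0
        run = 0
        counted = False
        for h in hit:
            if h:
                run += 1
                if run >= n_consec and not counted:
                    events += 1
                    counted = True
            else:
                run = 0
                counted = False
        rates[i] = events / minutes
    return rates
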