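"""Signed stimulus-preference-strength index and its group comparison.

For each neuron the magnitude is |Z_NT - Z_CS+| / (|Z_NT| + |Z_CS+|),
signed positive when the neutral tone dominates (|Z_NT| > |Z_CS+|) and
negative when the conditioned tone dominates.  Distributions between
treatment groups are compared with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PreferenceIndex:
    value: float  # signed, in [-1, 1]
    magnitude: float  # |Z_NT - Z_CS+| / (|Z_NT| + |Z_CS+|)
    z_nt: float
    z_cs: float
    flag: str | None = None  # "tie" or "zero_denominator"


def preference_strength(z_nt: float, z_cs: float) -> PreferenceIndex:
    """Compute the signed preference index for one neuron.

    Exact ties |Z_NT| = |Z_CS+| carry sign 0 (value 0) with the magnitude
    recorded separately and a ``tie`` flag; a zero denominator (both
    scalars 0) yields 0 with a ``zero_denominator`` flag.
    """
    if not (np.isfinite(z_nt) and np.isfinite(z_cs)):
        raise ValueError("preference inputs must be finite")
    denom = abs(z_nt) + abs(z_cs)
    if denom == 0:
        return PreferenceIndex(0.0, 0.0, z_nt, z_cs, flag="zero_denominator")
    mag = abs(z_nt - z_cs) / denom
    if abs(z_nt) > abs(z_cs):
        return PreferenceIndex(mag, mag, z_nt, z_cs)
    if abs(z_nt) < abs(z_cs):
        return PreferenceIndex(-mag, mag, z_nt, z_cs)
    return PreferenceIndex(0.0, mag, z_nt, z_cs, flag="tie")


def preference_table(
    z_nt: np.ndarray,
    z_cs: np.ndarray,
    neuron_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-neuron preference indices as a tidy frame."""
    z_nt = np.asarray(z_nt, float)
    z_cs = np.asarray(z_cs, float)
    if z_nt.shape != z_cs.shape:
        raise ValueError("Z_NT and Z_CS+ arrays must align")
    ids = neuron_ids or [f"n{i:04d}" for i in range(len(z_nt))]
    rows = [preference_strength(a, b) for a, b in zip(z_nt, z_cs)]
    return pd.DataFrame(
        {
            "neuron_id": ids,
            "z_nt": z_nt,
            "z_cs": z_cs,
            "preference": [r.value for r in rows],
            "magnitude": [r.magnitude for r in rows],
            "flag": [r.flag or "" for r in rows],
        }
    )


def preference_distribution_compare(
    values_a: np.ndarray, values_b: np.ndarray
) -> dict:
    """Two-sample KS test between preference distributions.

    Returns D = sup |ECDF_A - ECDF_B| and the asymptotic two-sided p.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return {
        "D": float(res.statistic),
        "p_value": float(res.pvalue),
        "n1": len(a),
        "n2": len(b),
    }


def preference_histogram(values: np.ndarray, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of signed preference on [-1, 1] for reporting."""
    counts, edges = np.histogram(np.asarray(values, float), bins=n_bins, range=(-1, 1))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
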