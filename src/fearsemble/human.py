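"""Human startle standardization, CS generalization and eCB association.

Fear-potentiated startle (peak-to-peak eye-blink EMG) is standardized per
subject and phase by the mean startle on inter-trial-interval (ITI)
probes, removing individual gain.  CS generalization at recall is the
standardized CS- response minus the standardized CS+ response over the
first four recall trials per cue.  Plasma endocannabinoid baselines are
the log of the mean of two pre-task measurements; the association between
log 2-AG and generalization is summarised by Pearson's r with a
case-resampling bootstrap CI on the regression slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CUE_TYPES = ("CS_PLUS", "CS_MINUS", "ITI")
STARTLE_COLUMNS = ("subject_id", "trial_index", "trial_type", "amplitude", "phase")


def _validate_startle(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(STARTLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"startle table missing columns: {sorted(missing)}")
    if (table["amplitude"] < 0).any():
        raise ValueError("startle amplitudes must be non-negative")
    bad = set(table["trial_type"].unique()) - set(CUE_TYPES)
    if bad:
        raise ValueError(f"unknown trial types: {sorted(bad)}")
    return table


def standardize_startle(
    table: pd.DataFrame,
    phase: str = "recall",
    n_test_trials: int | None = 4,
    mode: str = "ratio",
) -> pd.DataFrame:
    """Per-subject cue responses scaled by the phase's mean ITI startle.

    For each subject, standardized(cue) = mean cue amplitude / mean ITI
    amplitude within the phase.  At recall the first ``n_test_trials``
    trials per cue (presentation order) form the generalization test.
    Subjects with a zero ITI mean are excluded and logged, mirroring
    technical-exclusion handling.  ``mode="difference"`` subtracts the ITI
    mean instead of dividing.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    t = _validate_startle(table)
    t = t[t["phase"] == phase]
    if t.empty:
        raise ValueError(f"no trials in phase {phase!r}")
    rows = []
    for sid, sub in t.groupby("subject_id", sort=True):
        iti = sub.loc[sub["trial_type"] == "ITI", "amplitude"]
        if iti.empty:
            logger.warning("subject %s: no ITI trials in %s; excluded", sid, phase)
            continue
        iti_mean = float(iti.mean())
        if iti_mean == 0:
            logger.warning("subject %s: zero ITI mean; excluded", sid)
            continue
        row = {"subject_id": sid, "iti_mean": iti_mean}
        for cue in ("CS_PLUS", "CS_MINUS"):
            amps = sub[sub["trial_type"] == cue].sort_values("trial_index")["amplitude"]
            if n_test_trials is not None:
                amps = amps.iloc[:n_test_trials]
            if amps.empty:
                row[cue] = np.nan
                continue
            m = float(amps.mean())
            row[cue] = m / iti_mean if mode == "ratio" else m - iti_mean
        rows.append(row)
    return pd.DataFrame(rows)


def cs_generalization(standardized: pd.DataFrame) -> pd.Series:
    """Per-subject generalization score: standardized CS- minus CS+.

    A larger score means the safety cue evoked startle approaching (or
    exceeding) the threat cue — less discrimination.
    """
    for col in ("CS_PLUS", "CS_MINUS"):
        if col not in standardized.columns:
            raise ValueError(f"standardized table missing {col}")
    out = standardized.set_index("subject_id")
    return (out["CS_MINUS"] - out["CS_PLUS"]).rename("generalization")


def ecb_baseline(ecb: pd.DataFrame, analyte: str = "2AG") -> pd.Series:
    """Per-subject log baseline: natural log of the mean of two time points.

    Expects columns subject_id, analyte, value_t1, value_t2 with positive
    values (non-positive values cannot be log-transformed and indicate
    below-detection measurements, which are dropped upstream).
    """
    sub = ecb[ecb["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"no rows for analyte {analyte!r}")
    vals = sub[["value_t1", "value_t2"]].to_numpy(float)
    if (vals <= 0).any():
        raise ValueError("endocannabinoid values must be positive for log transform")
    return pd.Series(
        np.log(vals.mean(axis=1)),
        index=pd.Index(sub["subject_id"], name="subject_id"),
        name=f"log_{analyte}",
    )


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float] | None
    n: int
    n_dropped: int


def associate(
    scores: pd.Series,
    log_ecb: pd.Series,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> AssociationResult:
    """Pearson correlation and bootstrap slope CI on complete cases.

    Subjects missing either value are dropped (complete-case analysis,
    logged).  The regression is score ~ log eCB; the slope CI comes from
    ``n_boot`` case-resampling bootstraps (percentile interval) driven by
    a required seed when ``n_boot > 0``.
    """
    joined = pd.concat([scores, log_ecb], axis=1, join="outer")
    complete = joined.dropna()
    n_dropped = len(joined) - len(complete)
    if n_dropped:
        logger.info("dropped %d incomplete case(s)", n_dropped)
    n = len(complete)
    if n < 3:
        raise ValueError("need at least 3 complete cases")
    y = complete.iloc[:, 0].to_numpy(float)
    x = complete.iloc[:, 1].to_numpy(float)
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    ci = None
    if n_boot > 0:
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        denom = ((xb - xm) ** 2).sum(axis=1)
        denom[denom == 0] = np.nan
        slopes = ((xb - xm) * (yb - ym)).sum(axis=1) / denom
        alpha = 1 - ci_level
        lo, hi = np.nanpercentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        ci = (float(lo), float(hi))
    return AssociationResult(
        r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=ci,
        n=n,
        n_dropped=n_dropped,
    )
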