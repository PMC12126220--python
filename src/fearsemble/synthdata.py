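"""Synthetic sessions with planted ground truth.

Every downstream stage of the pipeline is tested against data generated
here: calcium-imaging sessions with neurons drawn from known response
archetypes, two-channel photometry with tone-locked transients whose
amplitude falls with freezing, per-frame freezing series, and a human
startle/endocannabinoid cohort with a planted correlation between log
2-AG and CS generalization.

Archetypes
----------
``nt_plus`` / ``cs_plus`` / ``dual_plus``: excited by the neutral tone,
the conditioned tone, or both.  ``nt_minus`` / ``cs_minus``: suppressed by
one tone.  ``dual_mixed``: suppressed by NT, excited by CS+.  ``none``:
baseline noise only.

Amplitude convention: ``response_amplitude`` is in units of the binned
peri-tone z-score — the tone-locked kernel is normalised so its largest
1-second bin average is 1 and then scaled by
``amplitude * noise_sd / sqrt(samples_per_bin)``, so the planted peak of
the single-trial binned z trace equals the requested amplitude in
expectation (averaging trials into blocks of B scales it by sqrt(B),
since the signal is deterministic while the baseline noise shrinks).

Seeding is counter-based: neuron ``i`` draws from an RNG keyed by
``(seed, i)``, so enlarging a population never reshuffles existing
neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Event,
    EventSchedule,
    EventType,
    FreezingSeries,
    PhotometrySignal,
    TraceMatrix,
    regular_tone_schedule,
)

ARCHETYPES = (
    "nt_plus",
    "cs_plus",
    "dual_plus",
    "nt_minus",
    "cs_minus",
    "dual_mixed",
    "none",
)

# archetype -> (NT response sign, CS+ response sign); 0 = no response
ARCHETYPE_SIGNS: dict[str, tuple[int, int]] = {
    "nt_plus": (+1, 0),
    "cs_plus": (0, +1),
    "dual_plus": (+1, +1),
    "nt_minus": (-1, 0),
    "cs_minus": (0, -1),
    "dual_mixed": (-1, +1),
    "none": (0, 0),
}


@dataclass
class PopulationSpec:
    """Composition and response parameters of a synthetic ensemble."""

    n_neurons: int = 400
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {"none": 1.0}
    )
    response_amplitude: float = 6.0  # binned-z units
    response_rise_s: float = 0.5
    response_decay_s: float = 3.0
    noise_sd: float = 1.0  # raw units per frame
    trial_gain_sd: float = 0.2  # relative trial-to-trial gain SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions sum to {total!r}, not 1")

    def archetype_counts(self) -> dict[str, int]:
        """Deterministic integer allocation by largest remainder."""
        fracs = {a: self.archetype_fractions.get(a, 0.0) for a in ARCHETYPES}
        base = {a: int(np.floor(f * self.n_neurons)) for a, f in fracs.items()}
        short = self.n_neurons - sum(base.values())
        remainders = sorted(
            ARCHETYPES,
            key=lambda a: (-(fracs[a] * self.n_neurons - base[a]), ARCHETYPES.index(a)),
        )
        for a in remainders[:short]:
            base[a] += 1
        return base


@dataclass
class SessionSpec:
    """Timing of a tone-presentation session."""

    rate_hz: float = 10.0
    tone_duration_s: float = 15.0
    n_nt_tones: int = 4
    n_cs_tones: int = 4
    iti_s: float = 45.0
    pre_session_s: float = 30.0
    post_session_s: float = 30.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.tone_duration_s <= 0:
            raise ValueError("tone_duration_s must be positive")
        if self.iti_s < 15.0:
            raise ValueError("iti_s must leave room for the 15-s pre-tone baseline")

    def schedule(self) -> EventSchedule:
        return regular_tone_schedule(
            self.n_nt_tones,
            self.n_cs_tones,
            tone_duration_s=self.tone_duration_s,
            iti_s=self.iti_s,
            pre_session_s=self.pre_session_s,
        )

    def duration_s(self) -> float:
        n = self.n_nt_tones + self.n_cs_tones
        return (
            self.pre_session_s
            + n * (self.tone_duration_s + self.iti_s)
            + self.post_session_s
        )


@dataclass
class HumanCohortSpec:
    """Planted human cohort: startle trials + plasma endocannabinoids."""

    n_subjects: int = 80
    target_r: float = 0.223  # planted Pearson r, log 2-AG vs generalization
    startle_noise_sd: float = 0.1  # trial noise, ITI-mean units
    ecb_log_mean: float = 2.0
    ecb_log_sd: float = 0.5
    gen_mean: float = 0.3  # cohort mean generalization, standardized units
    gen_sd: float = 0.5
    n_iti_trials: int = 8
    n_cue_trials: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if abs(self.target_r) > 1:
            raise ValueError("|target_r| must be <= 1")


def _kernel(rise_s: float, decay_s: float, duration_s: float, rate_hz: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalised to 1."""
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay?)")
    return k / peak


def _binned_peak(kernel: np.ndarray, per_bin: int) -> float:
    n_bins = len(kernel) // per_bin
    return float(
        kernel[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1).max()
    )


def generate_session(
    pop: PopulationSpec, sess: SessionSpec
) -> tuple[TraceMatrix, EventSchedule, pd.DataFrame]:
    """Simulate one calcium-imaging session.

    Each neuron's trace is i.i.d. Gaussian frame noise plus, for its
    assigned stimulus types, a tone-locked double-exponential kernel with
    archetype-specific sign and a per-trial multiplicative gain.  Returns
    the traces, the schedule, and a ground-truth table (neuron_id,
    archetype, nt_sign, cs_sign) that is never written into the data
    files consumed by analysis stages.
    """
    schedule = sess.schedule()
    n_samples = int(round(sess.duration_s() * sess.rate_hz))
    per_bin = int(round(sess.rate_hz))
    kernel = _kernel(
        pop.response_rise_s, pop.response_decay_s, sess.tone_duration_s, sess.rate_hz
    )
    # scale so the largest 1-s bin average of the planted response equals
    # response_amplitude in binned-z units
    amp_raw = (
        pop.response_amplitude
        * pop.noise_sd
        / np.sqrt(per_bin)
        / _binned_peak(kernel, per_bin)
    )

    counts = pop.archetype_counts()
    archetypes = [a for a in ARCHETYPES for _ in range(counts[a])]
    tones = schedule.tones()
    values = np.empty((pop.n_neurons, n_samples))
    for i, arch in enumerate(archetypes):
        rng = np.random.default_rng([pop.seed, i])
        trace = rng.normal(0.0, pop.noise_sd, size=n_samples)
        gains = 1.0 + rng.normal(0.0, pop.trial_gain_sd, size=len(tones))
        gains = np.clip(gains, 0.0, None)
        nt_sign, cs_sign = ARCHETYPE_SIGNS[arch]
        for t_idx, ev in enumerate(tones):
            sign = nt_sign if ev.event_type is EventType.NT else cs_sign
            if sign == 0:
                continue
            lo = int(round(ev.onset_s * sess.rate_hz))
            hi = min(lo + len(kernel), n_samples)
            trace[lo:hi] += sign * amp_raw * gains[t_idx] * kernel[: hi - lo]
        values[i] = trace

    traces = TraceMatrix(values=values, rate_hz=sess.rate_hz)
    truth = pd.DataFrame(
        {
            "neuron_id": traces.neuron_ids,
            "archetype": archetypes,
            "nt_sign": [ARCHETYPE_SIGNS[a][0] for a in archetypes],
            "cs_sign": [ARCHETYPE_SIGNS[a][1] for a in archetypes],
        }
    )
    return traces, schedule, truth


def generate_photometry(
    sess: SessionSpec,
    trial_freezing: list[float],
    seed: int,
    base_peak_z: float = 8.0,
    freeze_slope_z: float = 4.0,
    noise_sd: float = 0.5,
    native_rate_hz: float = 100.0,
    baseline_f: float = 100.0,
    artifact_amp: float = 2.0,
) -> tuple[PhotometrySignal, FreezingSeries]:
    """Simulate a two-channel photometry session plus freezing.

    One NT tone per entry of ``trial_freezing``.  The sensor channel
    carries tone-locked transients with peak (in 10-Hz-downsampled,
    2-s-pre-tone z units) of ``base_peak_z - freeze_slope_z * f/100`` for
    trial freezing ``f`` — amplitude decreases with freezing.  A shared
    slow sinusoidal artifact rides on both channels; the isosbestic
    channel carries no transients.  Freezing frames are a deterministic
    leading block within each tone so per-tone percentages are exact.
    """
    freezing = np.asarray(trial_freezing, float)
    if np.any((freezing < 0) | (freezing > 100)):
        raise ValueError("trial freezing percents must lie in [0, 100]")
    spec = SessionSpec(
        rate_hz=sess.rate_hz,
        tone_duration_s=sess.tone_duration_s,
        n_nt_tones=len(freezing),
        n_cs_tones=0,
        iti_s=sess.iti_s,
        pre_session_s=sess.pre_session_s,
        post_session_s=sess.post_session_s,
    )
    schedule = spec.schedule()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s() * native_rate_hz))
    t = np.arange(n) / native_rate_hz

    factor = int(round(native_rate_hz / sess.rate_hz))
    kernel = _kernel(0.5, 3.0, sess.tone_duration_s, native_rate_hz)
    # calibrate so the downsampled per-sample peak z matches the request:
    # downsampled noise SD shrinks by sqrt(factor); kernel peak shrinks to
    # its largest window mean
    n_ds = len(kernel) // factor
    ds_peak = kernel[: n_ds * factor].reshape(n_ds, factor).mean(axis=1).max()
    noise_ds_sd = noise_sd / np.sqrt(factor)

    artifact = artifact_amp * np.sin(2 * np.pi * t / 120.0)
    signal = baseline_f + artifact + rng.normal(0.0, noise_sd, n)
    iso = 0.8 * baseline_f + 0.8 * artifact + rng.normal(0.0, 0.05 * noise_sd, n)

    for ev, f in zip(schedule.tones(), freezing):
        z_amp = max(base_peak_z - freeze_slope_z * f / 100.0, 0.0)
        amp_raw = z_amp * noise_ds_sd / ds_peak
        lo = int(round(ev.onset_s * native_rate_hz))
        hi = min(lo + len(kernel), n)
        signal[lo:hi] += amp_raw * kernel[: hi - lo]

    behav_rate = sess.rate_hz
    n_frames = int(round(spec.duration_s() * behav_rate))
    frames_t = np.arange(n_frames) / behav_rate
    frozen = np.zeros(n_frames, dtype=int)
    for ev, f in zip(schedule.tones(), freezing):
        lo = int(round(ev.onset_s * behav_rate))
        hi = int(round(ev.offset_s * behav_rate))
        n_frozen = int(round(f / 100.0 * (hi - lo)))
        frozen[lo : lo + n_frozen] = 1

    return (
        PhotometrySignal(t=t, signal=signal, isosbestic=iso, rate_hz=native_rate_hz),
        FreezingSeries(time_s=frames_t, freezing=frozen, rate_hz=behav_rate),
    )


def generate_human_cohort(
    spec: HumanCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a startle/endocannabinoid cohort with planted correlation.

    Per-subject generalization g_i is built so that corr(log 2-AG, g) =
    ``target_r`` in expectation; the startle table realises g_i as the gap
    between CS- and CS+ recall trial means (in ITI-mean units) under a
    per-subject multiplicative gain, which ITI standardization removes.
    Returns (startle_table, ecb_table, truth) where truth holds the
    planted per-subject parameters and never feeds the analysis.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    z_ecb = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    log_2ag = spec.ecb_log_mean + spec.ecb_log_sd * z_ecb
    g = spec.gen_mean + spec.gen_sd * (
        spec.target_r * z_ecb + np.sqrt(1.0 - spec.target_r**2) * eps
    )
    gains = np.exp(rng.normal(0.0, 0.4, n))
    subject_ids = [f"s{i:03d}" for i in range(n)]

    cs_plus_level = 1.2
    rows = []
    for i, sid in enumerate(subject_ids):
        for phase in ("acquisition", "recall"):
            trial = 0
            cue_means = {
                "ITI": 1.0,
                # conditioning: CS+ elevated, CS- near ITI during acquisition;
                # recall realises the planted generalization gap
                "CS_PLUS": cs_plus_level,
                "CS_MINUS": 1.0 if phase == "acquisition" else cs_plus_level + g[i],
            }
            for cue, n_trials in (
                ("ITI", spec.n_iti_trials),
                ("CS_PLUS", spec.n_cue_trials),
                ("CS_MINUS", spec.n_cue_trials),
            ):
                for _ in range(n_trials):
                    amp = gains[i] * (
                        cue_means[cue] + rng.normal(0.0, spec.startle_noise_sd)
                    )
                    rows.append(
                        {
                            "subject_id": sid,
                            "trial_index": trial,
                            "trial_type": cue,
                            "amplitude": max(amp, 1e-6),
                            "phase": phase,
                        }
                    )
                    trial += 1
    startle = pd.DataFrame(rows)

    # two baseline draws bracketing the planted level so their mean is exact
    spread = 0.05
    v = np.exp(log_2ag)
    aea = np.exp(rng.normal(spec.ecb_log_mean - 1.0, spec.ecb_log_sd, n))
    ecb = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "analyte": "2AG",
                    "value_t1": v * (1 + spread),
                    "value_t2": v * (1 - spread),
                }
            ),
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "analyte": "AEA",
                    "value_t1": aea * (1 + spread),
                    "value_t2": aea * (1 - spread),
                }
            ),
        ],
        ignore_index=True,
    )
    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "log_2ag": log_2ag,
            "generalization": g,
            "gain": gains,
        }
    )
    return startle, ecb, truth


def write_session(
    out_dir: str | Path,
    traces: TraceMatrix,
    schedule: EventSchedule,
    truth: pd.DataFrame | None = None,
    csv: bool = False,
) -> dict[str, Path]:
    """Write a session to disk; ground truth goes to a separate file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if csv:
        paths["traces"] = out / "traces.csv"
        traces.to_csv(paths["traces"])
    else:
        paths["traces"] = out / "traces.h5"
        traces.to_hdf5(paths["traces"])
    paths["events"] = out / "events.csv"
    schedule.to_csv(paths["events"])
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.csv"
        truth.to_csv(paths["ground_truth"], index=False)
    return paths
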