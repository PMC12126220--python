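"""Freezing quantification and cue/context generalization indices.

Freezing is a per-frame binary indicator; the percentage frozen within an
interval is the behavioral readout.  The generalization index expresses
freezing to a neutral cue (or neutral context) relative to freezing to
the trained reference (CS+ tone, or the conditioning context), as a ratio
by default with a difference variant available for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import EventSchedule, EventType, FreezingSeries


@dataclass(frozen=True)
class GeneralizationIndex:
    value: float | None  # None when undefined (reference freezing = 0)
    numerator_cue: str
    denominator_cue: str
    mode: str = "ratio"
    flag: str | None = None


def freezing_percentage(series: FreezingSeries, interval: tuple[float, float]) -> float:
    """Percent of frames frozen within [t0, t1)."""
    t0, t1 = interval
    mask = (series.time_s >= t0) & (series.time_s < t1)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty interval [{t0:g}, {t1:g})")
    return 100.0 * float(series.freezing[mask].sum()) / n


def per_tone_freezing(
    series: FreezingSeries, schedule: EventSchedule, tone_type: EventType | str
) -> list[float]:
    """Freezing percent during each tone of one type, presentation order."""
    tones = schedule.tones(tone_type)
    if not tones:
        raise ValueError(f"no tones of type {EventType(tone_type).value}")
    return [freezing_percentage(series, (e.onset_s, e.offset_s)) for e in tones]


def tone_blocks(percents: list[float], block: int = 2) -> list[float]:
    """Average per-tone percents into consecutive blocks.

    A trailing unpaired tone is kept as its own (singleton) block with a
    warning — behavior sessions legitimately have odd tone counts.
    """
    if len(percents) == 0:
        raise ValueError("need at least one tone")
    out = []
    for i in range(0, len(percents), block):
        chunk = percents[i : i + block]
        if len(chunk) < block:
            warnings.warn(
                f"trailing block of {len(chunk)} tone(s) kept unpaired", stacklevel=2
            )
        out.append(float(np.mean(chunk)))
    return out


def generalization_index(
    freeze_neutral: float,
    freeze_reference: float,
    numerator_cue: str = "NT",
    denominator_cue: str = "CS_PLUS",
    mode: str = "ratio",
) -> GeneralizationIndex:
    """Freezing to the neutral cue relative to the trained reference.

    ``mode="ratio"`` (default) gives neutral/reference, 1 meaning full
    generalization; ``mode="difference"`` gives neutral - reference.
    A zero reference makes the ratio undefined (flagged, value None).
    """
    for v in (freeze_neutral, freeze_reference):
        if not 0 <= v <= 100:
            raise ValueError("freezing percents must lie in [0, 100]")
    if mode == "difference":
        return GeneralizationIndex(
            freeze_neutral - freeze_reference, numerator_cue, denominator_cue, mode
        )
    if mode != "ratio":
        raise ValueError("mode must be 'ratio' or 'difference'")
    if freeze_reference == 0:
        return GeneralizationIndex(
            None, numerator_cue, denominator_cue, mode, flag="undefined_zero_reference"
        )
    return GeneralizationIndex(
        freeze_neutral / freeze_reference, numerator_cue, denominator_cue, mode
    )
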