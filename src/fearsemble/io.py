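"""Core data containers and on-disk formats.

The pipeline's substrate is a neurons x timepoints activity matrix sampled
at a fixed rate, plus a typed event schedule (tone onsets, tone types,
shocks) that anchors every peri-event alignment.  Traces are stored either
as HDF5 (dataset ``traces`` with a ``rate_hz`` attribute) or as CSV with
neurons as rows; schedules as CSV with columns ``event_type,onset_s,
duration_s``; freezing series as CSV ``time_s,freezing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd


class EventType(str, Enum):
    NT = "NT"
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"
    SHOCK = "SHOCK"


TONE_TYPES = (EventType.NT, EventType.CS_PLUS, EventType.CS_MINUS)


@dataclass(frozen=True)
class Event:
    event_type: EventType
    onset_s: float
    duration_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EventSchedule:
    """Ordered list of timed, typed stimulus events."""

    events: list[Event]

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be non-decreasing")
        tones = self.tones()
        for a, b in zip(tones, tones[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError(
                    f"overlapping tones at {a.onset_s:g}s and {b.onset_s:g}s"
                )

    def tones(self, tone_type: EventType | str | None = None) -> list[Event]:
        """Tone events, optionally restricted to one type."""
        if tone_type is not None:
            tone_type = EventType(tone_type)
        return [
            e
            for e in self.events
            if e.event_type in TONE_TYPES
            and (tone_type is None or e.event_type == tone_type)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_type": [e.event_type.value for e in self.events],
                "onset_s": [e.onset_s for e in self.events],
                "duration_s": [e.duration_s for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSchedule":
        return cls(
            [
                Event(EventType(r.event_type), float(r.onset_s), float(r.duration_s))
                for r in df.itertuples()
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventSchedule":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class TraceMatrix:
    """Neurons x timepoints activity at a fixed sampling rate."""

    values: np.ndarray  # (n_neurons, n_samples), float
    rate_hz: float
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x timepoints)")
        if not np.isfinite(self.values).all():
            raise ValueError("trace matrix contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:04d}" for i in range(self.values.shape[0])]
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=self.values)
            d.attrs["rate_hz"] = self.rate_hz
            f.create_dataset(
                "neuron_ids", data=np.array(self.neuron_ids, dtype="S")
            )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TraceMatrix":
        with h5py.File(path, "r") as f:
            values = f["traces"][...]
            rate = float(f["traces"].attrs["rate_hz"])
            ids = [s.decode() for s in f["neuron_ids"][...]] if "neuron_ids" in f else []
        return cls(values=values, rate_hz=rate, neuron_ids=ids)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.neuron_ids)
        df.index.name = "neuron_id"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float) -> "TraceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(float),
            rate_hz=rate_hz,
            neuron_ids=[str(i) for i in df.index],
        )


@dataclass
class FreezingSeries:
    """Per-frame binary freezing indicator."""

    time_s: np.ndarray
    freezing: np.ndarray  # 0/1 per frame
    rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.freezing = np.asarray(self.freezing)
        if self.time_s.shape != self.freezing.shape:
            raise ValueError("time and freezing must be equal length")
        if not np.isin(self.freezing, (0, 1)).all():
            raise ValueError("freezing values must be binary")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time_s, "freezing": self.freezing}).to_csv(
            path, index=False, float_format="%.10g"
        )

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float | None = None) -> "FreezingSeries":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if rate_hz is None:
            dt = np.diff(t)
            if len(dt) == 0 or not np.allclose(dt, dt[0]):
                raise ValueError("cannot infer rate from irregular time axis")
            rate_hz = 1.0 / dt[0]
        return cls(time_s=t, freezing=df["freezing"].to_numpy(int), rate_hz=rate_hz)


@dataclass
class PhotometrySignal:
    """Two-channel fiber-photometry recording.

    ``signal`` is the activity-dependent sensor channel (465 nm excitation),
    ``isosbestic`` the activity-independent control channel (415 nm) used to
    regress out shared motion/bleaching artifacts.
    """

    t: np.ndarray
    signal: np.ndarray
    isosbestic: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.signal = np.asarray(self.signal, float)
        self.isosbestic = np.asarray(self.isosbestic, float)
        if not (len(self.t) == len(self.signal) == len(self.isosbestic)):
            raise ValueError("photometry channels must be time-aligned, equal length")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.t, "signal": self.signal, "isosbestic": self.isosbestic}
        ).to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float) -> "PhotometrySignal":
        df = pd.read_csv(path)
        return cls(
            t=df["time_s"].to_numpy(float),
            signal=df["signal"].to_numpy(float),
            isosbestic=df["isosbestic"].to_numpy(float),
            rate_hz=rate_hz,
        )


@dataclass
class AlignedZTensor:
    """Peri-tone z-scored activity: neurons x trial-blocks x 1-s bins.

    Bin 0 is tone onset; the preceding ``baseline_bins`` bins are the
    pre-tone normalisation window.  ``flags`` marks neuron x block entries
    whose baseline SD was zero (z forced to 0).
    """

    z: np.ndarray  # (n_neurons, n_blocks, n_bins)
    baseline_bins: int
    tone_bins: int
    bin_s: float = 1.0
    block_size: int = 2
    neuron_ids: list[str] = field(default_factory=list)
    flags: np.ndarray | None = None  # (n_neurons, n_blocks) bool

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        if self.z.ndim != 3:
            raise ValueError("z must be 3-D (neurons, blocks, bins)")
        if self.z.shape[2] != self.baseline_bins + self.tone_bins:
            raise ValueError("bin count must equal baseline_bins + tone_bins")
        if not np.isfinite(self.z).all():
            raise ValueError("z tensor contains non-finite values")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:04d}" for i in range(self.z.shape[0])]
        if self.flags is None:
            self.flags = np.zeros(self.z.shape[:2], dtype=bool)

    def tone_z(self) -> np.ndarray:
        """Tone-period bins only (neurons x blocks x tone_bins)."""
        return self.z[:, :, self.baseline_bins :]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("z", data=self.z)
            d.attrs.update(
                baseline_bins=self.baseline_bins,
                tone_bins=self.tone_bins,
                bin_s=self.bin_s,
                block_size=self.block_size,
            )
            f.create_dataset("neuron_ids", data=np.array(self.neuron_ids, dtype="S"))
            f.create_dataset("flags", data=self.flags)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "AlignedZTensor":
        with h5py.File(path, "r") as f:
            d = f["z"]
            return cls(
                z=d[...],
                baseline_bins=int(d.attrs["baseline_bins"]),
                tone_bins=int(d.attrs["tone_bins"]),
                bin_s=float(d.attrs["bin_s"]),
                block_size=int(d.attrs["block_size"]),
                neuron_ids=[s.decode() for s in f["neuron_ids"][...]],
                flags=f["flags"][...].astype(bool),
            )


def regular_tone_schedule(
    n_nt: int,
    n_cs: int,
    tone_duration_s: float = 15.0,
    iti_s: float = 45.0,
    pre_session_s: float = 30.0,
    cs_type: EventType = EventType.CS_PLUS,
    interleave: bool = True,
) -> EventSchedule:
    """Build a non-overlapping tone schedule with fixed inter-tone interval.

    By default NT and CS tones alternate (NT first); with ``interleave=False``
    all NT tones precede all CS tones.
    """
    if interleave:
        order: list[EventType] = []
        a, b = n_nt, n_cs
        while a > 0 or b > 0:
            if a > 0:
                order.append(EventType.NT)
                a -= 1
            if b > 0:
                order.append(cs_type)
                b -= 1
    else:
        order = [EventType.NT] * n_nt + [cs_type] * n_cs
    events = []
    t = pre_session_s
    for et in order:
        events.append(Event(et, t, tone_duration_s))
        t += tone_duration_s + iti_s
    return EventSchedule(events)
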