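"""Shared domain containers and error types.

Canonical units: spike/event/interval timestamps in seconds; everything
inside a sweep (sampling interval, step onset/offset, AP times) in
milliseconds; voltages in mV; currents in pA. Unit conversions happen only
at I/O boundaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

STATE_LABELS = ("RUN", "QUIET", "NREM", "REM")
INTERVAL_LABELS = STATE_LABELS + ("UP", "DOWN")


class Id2PhysError(Exception):
    """Base class for all package errors."""


class FormatError(Id2PhysError):
    """On-disk structure is malformed (e.g. a sidecar field is missing)."""


class IntegrityError(Id2PhysError):
    """On-disk structure is well-formed but internally inconsistent."""


class ValidationError(Id2PhysError):
    """A container invariant is violated."""


class DomainError(Id2PhysError, ValueError):
    """An analysis operation was handed inputs outside its domain."""


class ModeError(DomainError):
    """Sweep recorded in the wrong clamp mode for this operation."""


class ContaminationError(DomainError):
    """A passive-property measurement window contains action potentials."""


class TruncationError(DomainError):
    """The trace ends before the measurement window does."""


class InsufficientSpikesError(DomainError):
    """Too few spikes/ISIs for the statistic to be defined."""


class SubthresholdError(DomainError):
    """No sweep in the set elicited an action potential."""


class ExtrapolationError(DomainError):
    """Requested amplitude lies outside the tested range."""


class ShapeError(DomainError):
    """Waveform lacks the expected trough/peak structure."""


class SpecError(Id2PhysError, ValueError):
    """A synthetic-data specification is infeasible or inconsistent."""


class FitError(Id2PhysError):
    """A model fit failed to converge.

    Carries optional diagnostics (``residuals``, ``data``) for inspection.
    """

    def __init__(self, message: str, residuals=None, data=None):
        super().__init__(message)
        self.residuals = residuals
        self.data = data


@dataclass
class Sweep:
    """One clamp sweep: a uniformly sampled trace plus its stimulus step.

    Parameters
    ----------
    samples
        Voltage in mV (current clamp) or current in pA (voltage clamp).
    dt
        Sampling interval in ms.
    step_amplitude
        Injected current in pA (current clamp) or command potential in mV
        (voltage clamp).
    step_onset, step_offset
        Step timing in ms relative to the start of the sweep.
    mode
        ``"current_clamp"`` or ``"voltage_clamp"``.
    """

    samples: np.ndarray
    dt: float
    step_amplitude: float
    step_onset: float
    step_offset: float
    mode: str = CURRENT_CLAMP

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("Sweep.samples must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("Sweep.samples must be finite")
        if not self.dt > 0:
            raise ValidationError("Sweep.dt must be > 0")
        if not (0 <= self.step_onset < self.step_offset <= self.duration_ms + 1e-9):
            raise ValidationError(
                "require 0 <= step_onset < step_offset <= sweep duration "
                f"(got onset={self.step_onset}, offset={self.step_offset}, "
                f"duration={self.duration_ms})"
            )
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValidationError(f"unknown clamp mode {self.mode!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.dt

    @property
    def step_duration_ms(self) -> float:
        return self.step_offset - self.step_onset

    def times_ms(self) -> np.ndarray:
        """Sample timestamps in ms (t = i * dt)."""
        return np.arange(self.samples.size) * self.dt

    def index(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms, clipped into range."""
        return int(np.clip(round(t_ms / self.dt), 0, self.samples.size - 1))


@dataclass
class EventSeries:
    """Strictly increasing point-event timestamps in seconds."""

    times: np.ndarray
    label: str = "event"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValidationError("EventSeries.times must be 1-D")
        if self.times.size and self.times[0] < 0:
            raise ValidationError("event times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class IntervalSet:
    """Labeled, per-label non-overlapping time intervals in seconds."""

    starts: np.ndarray
    stops: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.float64)
        self.stops = np.asarray(self.stops, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (self.starts.shape == self.stops.shape == self.labels.shape):
            raise ValidationError("starts/stops/labels must have equal shapes")
        if np.any(self.stops <= self.starts):
            raise ValidationError("each interval requires start < stop")
        for lab in set(self.labels.tolist()):
            seg = self.for_label(lab)
            order = np.argsort(seg[:, 0])
            seg = seg[order]
            if np.any(seg[1:, 0] < seg[:-1, 1] - 1e-12):
                raise ValidationError(f"intervals with label {lab!r} overlap")

    @classmethod
    def from_records(cls, records: Sequence[Tuple[float, float, str]]) -> "IntervalSet":
        if len(records) == 0:
            return cls(np.empty(0), np.empty(0), np.empty(0, dtype=object))
        starts, stops, labels = zip(*records)
        return cls(np.array(starts), np.array(stops), np.array(labels, dtype=object))

    def __len__(self) -> int:
        return int(self.starts.size)

    def for_label(self, label: str) -> np.ndarray:
        """(n, 2) array of [start, stop] for one label, in time order."""
        m = self.labels == label
        seg = np.column_stack([self.starts[m], self.stops[m]])
        return seg[np.argsort(seg[:, 0])] if seg.size else seg.reshape(0, 2)

    def total_duration(self, label: str) -> float:
        seg = self.for_label(label)
        return float(np.sum(seg[:, 1] - seg[:, 0])) if seg.size else 0.0

    def records(self) -> List[Tuple[float, float, str]]:
        return [
            (float(a), float(b), str(l))
            for a, b, l in zip(self.starts, self.stops, self.labels)
        ]


@dataclass
class UnitRecord:
    """One sorted unit: spike times plus an optional mean waveform.

    ``waveform`` is in µV sampled at ``waveform_fs`` Hz; ``ground_truth``
    carries the planted phenotype label for synthetic sessions.
    """

    unit_id: str
    spike_times: np.ndarray
    waveform: Optional[np.ndarray] = None
    waveform_fs: Optional[float] = None
    depth_um: Optional[float] = None
    ground_truth: Optional[str] = None

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike_times must be sorted")
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=np.float64)
            if self.waveform_fs is None or not self.waveform_fs > 0:
                raise ValidationError(
                    f"unit {self.unit_id}: waveform requires a positive waveform_fs"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class CountTable:
    """Category -> non-negative count, with at least one nonzero entry."""

    counts: Dict[str, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class Trace:
    """A single continuous channel (LFP, EMG, motion) in arbitrary units."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.fs > 0:
            raise ValidationError("Trace.fs must be > 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SessionBundle:
    """Units + events + intervals + continuous channels for one recording."""

    units: List[UnitRecord]
    events: Dict[str, EventSeries] = field(default_factory=dict)
    intervals: Optional[IntervalSet] = None
    lfp: Optional[Trace] = None
    aux: Dict[str, Trace] = field(default_factory=dict)
    duration_s: float = 0.0
    ground_truth: Dict = field(default_factory=dict)


def tally_percentages(counts: CountTable) -> Dict[str, int]:
    """Integer percentages of a count table, rounded half up.

    Uses exact integer arithmetic: percent = floor(100*c/total + 1/2).
    The outputs need not sum to 100.

    Examples
    --------
    >>> tally_percentages(CountTable({"Id2": 680, "other": 3132}))
    {'Id2': 18, 'other': 82}
    """
    total = counts.total
    if total == 0:
        raise DomainError("tally_percentages: all counts are zero")
    return {
        lab: (200 * c + total) // (2 * total) for lab, c in counts.counts.items()
    }
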