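"""Core domain types for single-unit spike-train / LFP sessions.

Conventions used throughout the package:

* all times are in seconds (float64);
* behavioural epochs are half-open intervals ``[start, end)`` — a spike
  falling exactly on an interval end belongs to the *next* epoch, never to
  two at once;
* spike times of one unit are strictly increasing and bounded by the
  recording interval ``[t_start, t_stop]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "InsufficientDataError",
    "SpikeTrain",
    "EpochSet",
    "LfpSignal",
    "SpeedTrace",
    "UnitMetrics",
    "restrict",
]


class ValidationError(ValueError):
    """A domain-type invariant was violated; message names the field."""


class InsufficientDataError(ValueError):
    """Not enough spikes / events / cycles for a well-defined estimate."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name}: expected a 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: contains non-finite values")
    return arr


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit over a recording.

    Parameters
    ----------
    unit_id : str
        Text label of the unit.
    spike_times : array-like of float
        Spike times in seconds, strictly increasing.
    t_start, t_stop : float
        Recording bounds in seconds; all spikes lie in ``[t_start, t_stop]``.
    """

    unit_id: str
    spike_times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self):
        times = _as_float_array(self.spike_times, "spike_times")
        object.__setattr__(self, "spike_times", times)
        if not self.t_start < self.t_stop:
            raise ValidationError("t_start: must be < t_stop")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValidationError("spike_times: must be strictly increasing")
            if times[0] < self.t_start or times[-1] > self.t_stop:
                raise ValidationError(
                    "spike_times: must lie within [t_start, t_stop]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class EpochSet:
    """Labelled, pairwise-disjoint behavioural intervals (e.g. RUN / REST).

    Intervals are half-open ``[start, end)``.
    """

    intervals: tuple  # of (label, start, end)

    def __init__(self, intervals: Iterable[tuple]):
        ivs = []
        for row in intervals:
            label, start, end = row
            start, end = float(start), float(end)
            if not start < end:
                raise ValidationError(
                    f"interval ({label}, {start}, {end}): start must be < end"
                )
            ivs.append((str(label), start, end))
        ivs.sort(key=lambda iv: (iv[1], iv[2]))
        for (la, sa, ea), (lb, sb, eb) in zip(ivs, ivs[1:]):
            if sb < ea:  # any overlap, same or different label
                raise ValidationError(
                    f"intervals: ({la}, {sa}, {ea}) and ({lb}, {sb}, {eb}) overlap"
                )
        object.__setattr__(self, "intervals", tuple(ivs))

    @property
    def labels(self) -> tuple:
        seen = []
        for label, _, _ in self.intervals:
            if label not in seen:
                seen.append(label)
        return tuple(seen)

    def of_label(self, label: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals carrying ``label``."""
        ivs = [(s, e) for (l, s, e) in self.intervals if l == label]
        if not ivs:
            raise ValidationError(f"label: no '{label}' intervals present")
        return np.asarray(ivs, dtype=float)

    def total_duration(self, label: str) -> float:
        """Summed length (s) of all intervals of ``label``."""
        ivs = self.of_label(label)
        return float(np.sum(ivs[:, 1] - ivs[:, 0]))

    @property
    def t_start(self) -> float:
        return self.intervals[0][1]

    @property
    def t_stop(self) -> float:
        return max(e for _, _, e in self.intervals)


def restrict(train: SpikeTrain, epochs: EpochSet, label: str) -> SpikeTrain:
    """Spikes of ``train`` falling inside the ``label`` epochs.

    Containment is half-open: a spike with ``start <= t < end`` is kept, a
    spike exactly at an interval end is excluded.  The restricted train keeps
    the parent recording bounds; the effective duration of the restriction is
    ``epochs.total_duration(label)``.
    """
    ivs = epochs.of_label(label)
    t = train.spike_times
    keep = np.zeros(t.size, dtype=bool)
    for start, end in ivs:
        lo = np.searchsorted(t, start, side="left")
        hi = np.searchsorted(t, end, side="left")
        keep[lo:hi] = True
    return SpikeTrain(train.unit_id, t[keep], train.t_start, train.t_stop)


def split_by_intervals(train: SpikeTrain, intervals: np.ndarray) -> list:
    """Per-interval spike-time arrays (half-open containment)."""
    t = train.spike_times
    out = []
    for start, end in np.asarray(intervals, dtype=float):
        lo = np.searchsorted(t, start, side="left")
        hi = np.searchsorted(t, end, side="left")
        out.append(t[lo:hi])
    return out


@dataclass(frozen=True)
class LfpSignal:
    """Regularly sampled local-field-potential trace.

    ``samples`` are in microvolts; sample k sits at ``t_start + k / fs``.
    """

    samples: np.ndarray
    fs: float
    t_start: float = 0.0
    channel_label: str = "lfp"

    def __post_init__(self):
        samples = _as_float_array(self.samples, "samples")
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValidationError("fs: must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.fs

    @property
    def t_stop(self) -> float:
        return self.t_start + self.samples.size / self.fs

    def segment(self, start: float, end: float) -> tuple:
        """(sample_times, samples) for ``[start, end)``."""
        i0 = max(0, int(np.ceil((start - self.t_start) * self.fs - 1e-9)))
        i1 = min(self.samples.size, int(np.ceil((end - self.t_start) * self.fs - 1e-9)))
        idx = np.arange(i0, i1)
        return self.t_start + idx / self.fs, self.samples[i0:i1]


@dataclass(frozen=True)
class SpeedTrace:
    """Running-speed trace: sample times (s, ascending) and speeds (cm/s)."""

    times: np.ndarray
    speed: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        speed = _as_float_array(self.speed, "speed")
        if times.size != speed.size:
            raise ValidationError("speed: must have same length as times")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValidationError("times: must be strictly increasing")
        if np.any(speed < 0):
            raise ValidationError("speed: must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "speed", speed)


@dataclass
class UnitMetrics:
    """Per-unit physiological metric record (one report-table row)."""

    unit_id: str
    rate_rest: float = np.nan
    rate_run: float = np.nan
    rate_change_score: float = np.nan
    mean_burst_duration_ms: float = np.nan
    phase_deg: float = np.nan
    phase_R: float = np.nan
    phase_p: float = np.nan
    RI: float = np.nan
    OF: float = np.nan
    speed_r: float = np.nan
    speed_p: float = np.nan
    speed_class: str = "none"
    cluster_id: int = -1
    group_label: str = ""

    FIELDS = (
        "unit_id", "rate_rest", "rate_run", "rate_change_score",
        "mean_burst_duration_ms", "phase_deg", "phase_R", "phase_p",
        "RI", "OF", "speed_r", "speed_p", "speed_class",
        "cluster_id", "group_label",
    )

    def __post_init__(self):
        for name, lo, hi in (
            ("rate_change_score", -1.0, 1.0),
            ("RI", 0.0, 1.0),
            ("phase_R", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if np.isfinite(v) and not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValidationError(f"{name}: {v} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}
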