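"""Burst segmentation, firing rates, rate-change score, speed modulation.

Bursts are maximal runs of >= 2 consecutive spikes whose interspike
intervals (ISIs) do not exceed a data-derived threshold, the mean ISI of the
state-restricted train.  A spike whose ISIs to both neighbours exceed the
threshold belongs to no burst.  The behavioural rate-change score is
``(rate_RUN - rate_REST) / (rate_RUN + rate_REST)``, bounded in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .core import EpochSet, InsufficientDataError, SpeedTrace, SpikeTrain, restrict
from .core import split_by_intervals

__all__ = [
    "Burst",
    "SpeedFit",
    "detect_bursts",
    "mean_burst_duration",
    "firing_rate",
    "rate_change_score",
    "speed_modulation",
]


@dataclass(frozen=True)
class Burst:
    """One burst: contiguous spikes with intra-burst ISIs <= threshold."""

    spike_indices: np.ndarray   # indices into the (restricted) train
    onset_s: float
    offset_s: float

    @property
    def n_spikes(self) -> int:
        return int(self.spike_indices.size)

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0


def _runs_at_most(isis: np.ndarray, threshold: float):
    """Maximal index runs [i, j] with all isis[i:j] <= threshold (j > i)."""
    ok = isis <= threshold
    runs = []
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            runs.append((i, j + 1))  # spikes i .. j+1 inclusive
            i = j + 1
        i += 1
    return runs


def detect_bursts(
    train: SpikeTrain,
    epochs: Optional[EpochSet] = None,
    label: Optional[str] = None,
    threshold_s: Optional[float] = None,
) -> list:
    """Segment a (state-restricted) spike train into bursts.

    The ISI threshold defaults to the mean ISI of the restricted train; ISIs
    spanning an epoch gap are excluded from both the threshold and the
    grouping, so bursts never bridge excised time.  Returns time-ordered,
    disjoint :class:`Burst` objects with >= 2 spikes each.
    """
    if epochs is not None and label is not None:
        segments = split_by_intervals(train, epochs.of_label(label))
    else:
        segments = [train.spike_times]
    all_isis = np.concatenate([np.diff(seg) for seg in segments]) if segments else np.array([])
    if sum(seg.size for seg in segments) < 2 or all_isis.size == 0:
        warnings.warn("detect_bursts: fewer than 2 spikes, no bursts defined")
        return []
    threshold = float(np.mean(all_isis)) if threshold_s is None else float(threshold_s)

    bursts = []
    offset = 0
    for seg in segments:
        if seg.size >= 2:
            for i0, i1 in _runs_at_most(np.diff(seg), threshold):
                idx = np.arange(offset + i0, offset + i1 + 1)
                bursts.append(Burst(idx, float(seg[i0]), float(seg[i1])))
        offset += seg.size
    return bursts


def mean_burst_duration(bursts: list) -> float:
    """Arithmetic mean burst duration in ms; NaN (with warning) if empty."""
    if not bursts:
        warnings.warn("mean_burst_duration: no bursts, undefined")
        return float("nan")
    return float(np.mean([b.duration_ms for b in bursts]))


def firing_rate(train: SpikeTrain, epochs: EpochSet, label: str) -> float:
    """Mean firing rate (Hz) within the ``label`` epochs."""
    duration = epochs.total_duration(label)
    if duration <= 0:
        raise InsufficientDataError(f"firing_rate: zero total duration for '{label}'")
    return restrict(train, epochs, label).n_spikes / duration


def rate_change_score(rate_rest: float, rate_run: float) -> float:
    """(RUN - REST) / (RUN + REST); -1 = silent during RUN, +1 = RUN-only."""
    if rate_rest < 0 or rate_run < 0:
        raise ValueError("rates must be non-negative")
    if rate_rest == 0 and rate_run == 0:
        warnings.warn("rate_change_score: both rates zero, undefined")
        return float("nan")
    return (rate_run - rate_rest) / (rate_run + rate_rest)


@dataclass
class SpeedFit:
    """Weighted linear fit of firing rate against running speed.

    ``bin_table`` columns: speed-bin centre (cm/s), firing rate (Hz) and
    occupancy (s); weights in the fit are sqrt(occupancy).
    """

    slope: float          # Hz per cm/s
    intercept: float      # Hz
    r: float              # weighted correlation coefficient
    p: float              # two-sided p of the slope (WLS t-test)
    speed_class: str      # positive / negative / none
    bin_table: np.ndarray  # (n_bins, 3): centre, rate, occupancy_s
    valid: bool = True


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def speed_modulation(
    train: SpikeTrain,
    speed: SpeedTrace,
    bin_cm_s: float = 1.0,
    min_speed: float = 2.0,
    min_bins: int = 3,
    alpha: float = 0.05,
) -> SpeedFit:
    """Firing rate vs running speed, binned at 1 cm/s above ``min_speed``.

    Each occupied speed bin contributes (rate, occupancy); the rate-vs-speed
    line is fitted by weighted least squares with weight sqrt(occupancy).
    The unit is classed positive (r > 0, p < alpha), negative (r < 0,
    p < alpha) or none.
    """
    times, sp = speed.times, speed.speed
    if times.size < 2:
        raise InsufficientDataError("speed_modulation: speed trace too short")
    dt = np.empty_like(times)
    dt[:-1] = np.diff(times)
    dt[-1] = dt[-2]

    bins = np.floor(sp / bin_cm_s).astype(int)
    # instantaneous speed at each spike: nearest speed sample
    st = train.spike_times
    st = st[(st >= times[0]) & (st <= times[-1] + dt[-1])]
    pos = np.searchsorted(times, st)
    pos = np.clip(pos, 1, times.size - 1)
    nearest = np.where(
        np.abs(st - times[pos - 1]) <= np.abs(times[pos] - st), pos - 1, pos
    )
    spike_bins = bins[nearest]

    max_bin = bins.max()
    occupancy = np.bincount(bins, weights=dt, minlength=max_bin + 1)
    counts = np.bincount(spike_bins, minlength=max_bin + 1)

    first = int(np.ceil(min_speed / bin_cm_s))
    sel = np.nonzero(occupancy > 0)[0]
    sel = sel[sel >= first]
    if sel.size < min_bins:
        warnings.warn("speed_modulation: fewer than %d occupied bins above "
                      "%g cm/s, undefined" % (min_bins, min_speed))
        return SpeedFit(np.nan, np.nan, np.nan, np.nan, "none",
                        np.zeros((0, 3)), valid=False)

    centres = (sel + 0.5) * bin_cm_s
    occ = occupancy[sel]
    rates = counts[sel] / occ
    w = np.sqrt(occ)

    wls = sm.WLS(rates, sm.add_constant(centres), weights=w).fit()
    slope, intercept = float(wls.params[1]), float(wls.params[0])
    p = float(wls.pvalues[1])
    r = _weighted_corr(centres, rates, w)
    if p < alpha and r > 0:
        klass = "positive"
    elif p < alpha and r < 0:
        klass = "negative"
    else:
        klass = "none"
    table = np.column_stack([centres, rates, occ])
    return SpeedFit(slope, intercept, r, p, klass, table)
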