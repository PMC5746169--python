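"""Theta-phase extraction and circular statistics for spike phase locking.

Phase convention: 0 deg at the trough of the band-passed reference LFP,
increasing linearly to 360 deg at the next trough.  Interpolating between
detected troughs (rather than taking the analytic-signal angle) makes the
phase exact at the anchor that defines the convention; the analytic-signal
alternative is available via ``method="hilbert"``.

Angles are degrees at the API surface and radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .core import EpochSet, InsufficientDataError, LfpSignal, SpikeTrain

__all__ = [
    "PhaseSeries",
    "CircularStat",
    "theta_phase",
    "spike_phases",
    "rayleigh",
    "watson_u2",
    "angular_linear_correlation",
]


@dataclass(frozen=True)
class PhaseSeries:
    """Piecewise-linear theta phase anchored at LFP troughs.

    ``trough_times`` holds trough times per contiguous analysed segment;
    phase runs 0 -> 360 deg between consecutive troughs of a segment and is
    undefined (NaN) elsewhere.
    """

    trough_times: tuple  # tuple of 1-D arrays, one per segment

    @property
    def all_troughs(self) -> np.ndarray:
        if not self.trough_times:
            return np.array([])
        return np.concatenate(self.trough_times)

    @property
    def n_cycles(self) -> int:
        return int(sum(max(0, tr.size - 1) for tr in self.trough_times))

    def phase_at(self, times) -> np.ndarray:
        """Interpolated phase (deg, [0, 360)) at ``times``; NaN outside."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.full(times.shape, np.nan)
        for tr in self.trough_times:
            if tr.size < 2:
                continue
            idx = np.searchsorted(tr, times, side="right")
            ok = (idx >= 1) & (idx <= tr.size - 1)
            # a time exactly on the last trough belongs to the last cycle end
            at_last = (times == tr[-1])
            ok |= at_last
            i = np.clip(idx, 1, tr.size - 1)
            frac = (times - tr[i - 1]) / (tr[i] - tr[i - 1])
            ph = (frac * 360.0) % 360.0
            out[ok] = ph[ok]
        return out

    def cycle_index(self, times) -> np.ndarray:
        """Index of the containing cycle (-1 outside coverage)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.full(times.shape, -1, dtype=int)
        base = 0
        for tr in self.trough_times:
            if tr.size < 2:
                continue
            idx = np.searchsorted(tr, times, side="right")
            ok = (idx >= 1) & (idx <= tr.size - 1)
            out[ok] = base + idx[ok] - 1
            base += tr.size - 1
        return out


def _bandpass(x: np.ndarray, fs: float, band, order: int = 3) -> np.ndarray:
    nyq = fs / 2.0
    b, a = butter(order, [band[0] / nyq, band[1] / nyq], btype="band")
    return filtfilt(b, a, x)


def theta_phase(
    lfp: LfpSignal,
    epochs: Optional[EpochSet] = None,
    label: str = "RUN",
    band=(4.0, 12.0),
    method: str = "trough",
) -> PhaseSeries:
    """Extract theta phase (0 deg = trough) within the ``label`` epochs.

    Each epoch is band-passed (zero-phase Butterworth); troughs are local
    minima of the filtered trace separated by at least one period of the
    band's upper edge.  Epochs shorter than two cycles of the band's lower
    edge are skipped with a warning.
    """
    if method not in ("trough", "hilbert"):
        raise ValueError("method must be 'trough' or 'hilbert'")
    if epochs is not None:
        intervals = epochs.of_label(label)
    else:
        intervals = np.array([[lfp.t_start, lfp.t_stop]])
    min_len = 2.0 / band[0]
    min_dist = int(round(lfp.fs / band[1]))
    troughs = []
    for start, end in intervals:
        if end - start < min_len:
            warnings.warn(
                f"theta_phase: epoch [{start}, {end}) shorter than 2 cycles, skipped"
            )
            continue
        t, x = lfp.segment(start, end)
        if x.size <= 3 * max(min_dist, 9):
            continue
        xf = _bandpass(x, lfp.fs, band)
        if method == "hilbert":
            from scipy.signal import hilbert

            ph = np.angle(hilbert(xf))  # 0 at peaks; trough at +-pi
            # trough anchors: the wrap from +pi to -pi of the wrapped angle
            idx = np.nonzero(np.diff(ph) < -np.pi)[0] + 1
        else:
            idx, _ = find_peaks(-xf, distance=min_dist)
        if idx.size >= 2:
            troughs.append(t[idx])
    return PhaseSeries(tuple(troughs))


def spike_phases(
    train: SpikeTrain, phases: PhaseSeries, return_dropped: bool = False
):
    """Theta phase (deg) of each covered spike; uncovered spikes dropped.

    Raises :class:`InsufficientDataError` if no spike falls within the
    covered cycles.
    """
    ph = phases.phase_at(train.spike_times)
    ok = np.isfinite(ph)
    n_dropped = int(np.sum(~ok))
    if not np.any(ok):
        raise InsufficientDataError("spike_phases: no spikes in covered cycles")
    if return_dropped:
        return ph[ok], n_dropped
    return ph[ok]


@dataclass(frozen=True)
class CircularStat:
    """Circular summary of an angle sample (degrees)."""

    mean_deg: float
    R: float            # mean resultant length, [0, 1]
    circ_sd_deg: float  # sqrt(-2 ln R), in degrees
    p: float            # Rayleigh uniformity p
    n: int
    valid: bool = True


def rayleigh(angles_deg: Sequence[float], min_n: int = 10) -> CircularStat:
    """Rayleigh test of circular uniformity with mean phase and depth R.

    Uses the standard approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with ``Rn = n R``.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = a.size
    valid = n >= min_n
    if not valid:
        warnings.warn(f"rayleigh: n={n} below minimum {min_n}")
    if n == 0:
        return CircularStat(np.nan, np.nan, np.nan, np.nan, 0, False)
    C, S = np.cos(a).sum(), np.sin(a).sum()
    R = float(np.hypot(C, S) / n)
    mean_deg = float(np.rad2deg(np.arctan2(S, C)) % 360.0)
    Rn = n * R
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2.0 * n)))
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    with np.errstate(divide="ignore"):
        circ_sd = float(np.rad2deg(np.sqrt(-2.0 * np.log(R)))) if R > 0 else np.inf
    return CircularStat(mean_deg, R, circ_sd, p, int(n), valid)


def _u2_stat(z: np.ndarray, n: int, m: int) -> float:
    """Watson two-sample U^2 from pooled-order labels (z=1 for sample A)."""
    N = n + m
    cum_a = np.cumsum(z) / n
    cum_b = np.cumsum(1 - z) / m
    d = cum_a - cum_b
    return float(n * m / N**2 * (np.sum(d**2) - np.sum(d) ** 2 / N))


def watson_u2(
    angles_a_deg: Sequence[float],
    angles_b_deg: Sequence[float],
    n_perm: int = 9999,
    seed: Optional[int] = None,
    min_n: int = 8,
):
    """Watson's two-sample U^2 with a permutation p-value.

    The statistic is computed on pooled circular ranks (it is invariant to
    rotating both samples together); ties are broken by stable ordering.  The
    p-value comes from ``n_perm`` seeded random relabellings.
    Returns ``(U2, p)``.
    """
    a = np.asarray(angles_a_deg, dtype=float) % 360.0
    b = np.asarray(angles_b_deg, dtype=float) % 360.0
    n, m = a.size, b.size
    if n < min_n or m < min_n:
        raise InsufficientDataError(f"watson_u2: need n >= {min_n} per sample")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: all angles identical
        return 0.0, 1.0
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(m, dtype=int)])
    order = np.argsort(pooled, kind="mergesort")
    z = labels[order]
    u2 = _u2_stat(z, n, m)

    rng = np.random.default_rng(seed)
    count = 0
    block = 2000  # vectorise permutations in blocks
    remaining = n_perm
    while remaining > 0:
        k = min(block, remaining)
        zs = np.tile(z, (k, 1))
        zs = rng.permuted(zs, axis=1)
        cum_a = np.cumsum(zs, axis=1) / n
        cum_b = np.cumsum(1 - zs, axis=1) / m
        d = cum_a - cum_b
        N = n + m
        u2s = n * m / N**2 * (np.sum(d**2, axis=1) - np.sum(d, axis=1) ** 2 / N)
        count += int(np.sum(u2s >= u2 - 1e-12))
        remaining -= k
    p = (1.0 + count) / (n_perm + 1.0)
    return u2, float(p)


def angular_linear_correlation(angles_deg, values):
    """Correlation between a circular and a linear variable.

    r^2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2) with
    r_xc = corr(x, cos th), r_xs = corr(x, sin th), r_cs = corr(cos, sin);
    the p-value uses n r^2 ~ chi^2(2).  Returns ``(r, p)``.
    """
    from scipy.stats import chi2

    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    x = np.asarray(values, dtype=float)
    if th.size != x.size:
        raise ValueError("angles and values must have equal length")
    n = x.size
    if n < 8:
        raise InsufficientDataError("angular_linear_correlation: need n >= 8")
    if np.ptp(x) == 0:
        warnings.warn("angular_linear_correlation: zero variance in values")
        return 0.0, 1.0
    c, s = np.cos(th), np.sin(th)

    def corr(u, v):
        du, dv = u - u.mean(), v - v.mean()
        denom = np.sqrt(np.sum(du**2) * np.sum(dv**2))
        return float(np.sum(du * dv) / denom) if denom > 0 else 0.0

    r_xc, r_xs, r_cs = corr(x, c), corr(x, s), corr(c, s)
    r2 = (r_xc**2 + r_xs**2 - 2.0 * r_xc * r_xs * r_cs) / (1.0 - r_cs**2)
    r2 = float(np.clip(r2, 0.0, 1.0))
    p = float(chi2.sf(n * r2, df=2))
    return float(np.sqrt(r2)), p
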