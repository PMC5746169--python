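"""Synthetic session generator with known ground truth.

Emulates the statistical structure the analysis assumes: theta-modulated
bursty unit firing with controllable burst duration, theta-phase preference
and REST->RUN rate change; a CA1-like LFP with theta during RUN, slow
irregular activity (LIA) plus sharp-wave-ripple transients during REST; and
a running-speed trace coupled to the RUN epochs.

The generative model is burst-based, not rate-modulated Poisson: the
report metrics (burst duration, rhythmicity index) are burst-structure
statistics, so burst parameters must be ground truth.  During RUN a unit
emits, per theta cycle and with a Bernoulli probability calibrated to the
target rate, a burst of ``spikes_per_burst`` spikes at ``intraburst_isi_ms``
spacing whose *centre* phase is a von Mises draw around the preferred
phase; during REST bursts occur at cycle-free Poisson times.

Archetypes mirror the four physiological groups of rhythmic medial-septal
units (teevra, komal, group1, group4) plus a non-rhythmic homogeneous
``poisson`` control.  Cohort draws take per-unit parameters uniformly from
each group's published interquartile range.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from .core import EpochSet, LfpSignal, SpeedTrace, SpikeTrain, ValidationError

__all__ = [
    "UnitSpec",
    "LfpSpec",
    "ARCHETYPES",
    "make_epochs",
    "generate_lfp",
    "generate_unit",
    "generate_speed",
    "generate_speed_coupled_train",
    "generate_cohort",
    "SessionBundle",
]

MIN_ISI_S = 5e-4  # enforced refractory when merging burst spikes


@dataclass
class UnitSpec:
    """Ground-truth parameters of one synthetic unit."""

    archetype: str = "teevra"
    rate_rest: float = 30.0          # Hz
    rate_run: float = 30.0           # Hz
    burst_len_ms: float = 38.0       # nominal burst duration
    spikes_per_burst: Optional[int] = None  # derived from burst_len if None
    intraburst_isi_ms: float = 5.0
    pref_phase_deg: float = 0.0      # 0 = theta trough
    phase_kappa: float = 8.0         # von Mises concentration of burst centre
    seed: Optional[int] = None

    def __post_init__(self):
        if self.rate_rest < 0 or self.rate_run < 0:
            raise ValidationError("rates: must be >= 0")
        if self.burst_len_ms <= 0:
            raise ValidationError("burst_len_ms: must be > 0")
        if self.phase_kappa < 0:
            raise ValidationError("phase_kappa: must be >= 0")
        if self.spikes_per_burst is None:
            self.spikes_per_burst = max(
                2, int(round(self.burst_len_ms / self.intraburst_isi_ms)) + 1
            )
        if self.spikes_per_burst < 2:
            raise ValidationError("spikes_per_burst: must be >= 2")
        # keep the realised burst duration exactly burst_len_ms
        self.intraburst_isi_ms = self.burst_len_ms / (self.spikes_per_burst - 1)


@dataclass
class LfpSpec:
    """Ground-truth parameters of the synthetic CA1-like LFP."""

    theta_freq: float = 7.0          # Hz, RUN theta
    theta_amp: float = 100.0         # uV
    lia_band: tuple = (2.0, 6.0)     # Hz, REST slow irregular activity
    lia_amp: float = 150.0           # uV (SD of the band-limited activity)
    ripple_rate: float = 0.2         # events/s during REST
    ripple_freq: float = 160.0       # Hz
    ripple_len_ms: float = 50.0
    ripple_amp: float = 60.0         # uV envelope peak
    noise_sd: float = 10.0           # uV broadband noise
    fs: float = 1000.0               # Hz
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("theta_freq", "theta_amp", "lia_amp", "ripple_freq",
                     "ripple_len_ms", "ripple_amp", "noise_sd", "fs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be positive")
        if self.ripple_rate < 0:
            raise ValidationError("ripple_rate: must be >= 0")
        if not 130.0 <= self.ripple_freq <= 240.0:
            raise ValidationError("ripple_freq: must lie within 130-240 Hz")


# Archetype defaults; per-unit cohort draws sample `score_iqr`, `run_iqr`
# and `burst_iqr` uniformly (the published group interquartile ranges).
ARCHETYPES: dict = {
    "teevra": dict(
        burst_len_ms=38.0, intraburst_isi_ms=5.0, pref_phase_deg=0.0,
        phase_kappa=8.0, score_iqr=(-0.14, 0.005), run_iqr=(22.8, 51.4),
        burst_iqr=(33.5, 42.2),
    ),
    "komal": dict(
        burst_len_ms=57.0, intraburst_isi_ms=6.0, pref_phase_deg=160.0,
        phase_kappa=3.0, score_iqr=(0.16, 0.29), run_iqr=(30.6, 62.9),
        burst_iqr=(53.4, 64.0),
    ),
    "group1": dict(
        burst_len_ms=45.0, intraburst_isi_ms=6.0, pref_phase_deg=60.0,
        phase_kappa=2.0, score_iqr=(-0.40, -0.20), run_iqr=(4.0, 13.0),
        burst_iqr=(40.0, 50.0),
    ),
    "group4": dict(
        burst_len_ms=45.0, intraburst_isi_ms=6.0, pref_phase_deg=240.0,
        phase_kappa=2.0, score_iqr=(0.18, 0.32), run_iqr=(13.2, 37.1),
        burst_iqr=(40.0, 50.0),
    ),
    "poisson": dict(
        burst_len_ms=38.0, intraburst_isi_ms=5.0, pref_phase_deg=0.0,
        phase_kappa=0.0, score_iqr=(0.0, 0.0), run_iqr=(30.0, 30.0),
        burst_iqr=(38.0, 38.0),
    ),
}

DEFAULT_MIX = {"teevra": 48, "komal": 23, "group1": 4, "group4": 14}


def make_epochs(total_s: float = 360.0, run_s: float = 30.0,
                rest_s: float = 30.0, start_label: str = "REST") -> EpochSet:
    """Alternating REST/RUN blocks covering ``[0, total_s)``."""
    ivs = []
    t = 0.0
    label = start_label
    while t < total_s - 1e-9:
        dur = run_s if label == "RUN" else rest_s
        end = min(t + dur, total_s)
        ivs.append((label, t, end))
        label = "RUN" if label == "REST" else "REST"
        t = end
    return EpochSet(ivs)


def generate_lfp(spec: LfpSpec, epochs: EpochSet,
                 rng: Optional[np.random.Generator] = None):
    """Synthesize the session LFP; returns ``(LfpSignal, ground_truth)``.

    RUN intervals carry a theta cosine whose troughs define phase 0; REST
    intervals carry band-limited slow irregular activity with embedded
    Gaussian-windowed ripple transients at Poisson times.  Broadband
    Gaussian noise is added throughout.  ``ground_truth`` holds the inserted
    ripple peak times and the theta trough times.
    """
    if not epochs.intervals:
        raise ValidationError("epochs: must be nonempty")
    if spec.fs < 4.0 * spec.ripple_freq:
        raise ValidationError(
            f"fs: {spec.fs} < 4 x ripple_freq ({spec.ripple_freq}); aliasing"
        )
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    t_stop = epochs.t_stop
    n = int(round(t_stop * spec.fs))
    t = np.arange(n) / spec.fs
    x = rng.normal(0.0, spec.noise_sd, n)

    trough_times = []
    run_ivs = (epochs.of_label("RUN")
               if "RUN" in epochs.labels else np.zeros((0, 2)))
    for start, end in run_ivs:
        mask = (t >= start) & (t < end)
        # theta cosine; troughs at (k + 1/2) / f on the session clock
        x[mask] += spec.theta_amp * np.cos(2 * np.pi * spec.theta_freq * t[mask])
        k0 = int(np.ceil(start * spec.theta_freq - 0.5))
        k1 = int(np.floor(end * spec.theta_freq - 0.5))
        if k1 >= k0:
            trough_times.append((np.arange(k0, k1 + 1) + 0.5) / spec.theta_freq)
    trough_times = (np.concatenate(trough_times)
                    if trough_times else np.array([]))

    ripple_times = []
    rest_ivs = (epochs.of_label("REST")
                if "REST" in epochs.labels else np.zeros((0, 2)))
    if rest_ivs.size:
        # slow irregular activity: band-limited Gaussian noise, REST only
        nyq = spec.fs / 2.0
        b, a = butter(3, [spec.lia_band[0] / nyq, spec.lia_band[1] / nyq],
                      btype="band")
        slow = filtfilt(b, a, rng.normal(0.0, 1.0, n))
        sd = slow.std()
        if sd > 0:
            slow *= spec.lia_amp / sd
        for start, end in rest_ivs:
            mask = (t >= start) & (t < end)
            x[mask] += slow[mask]
        # ripple transients at Poisson times, kept clear of interval edges
        half = spec.ripple_len_ms / 1000.0 / 2.0
        sigma = spec.ripple_len_ms / 1000.0 / 6.0
        for start, end in rest_ivs:
            usable = (end - start) - 2 * half
            if usable <= 0 or spec.ripple_rate <= 0:
                continue
            n_ev = rng.poisson(spec.ripple_rate * usable)
            centres = np.sort(rng.uniform(start + half, end - half, n_ev))
            for c in centres:
                i0 = int((c - half) * spec.fs)
                i1 = int((c + half) * spec.fs)
                tt = t[i0:i1] - c
                x[i0:i1] += (spec.ripple_amp
                             * np.exp(-tt**2 / (2 * sigma**2))
                             * np.sin(2 * np.pi * spec.ripple_freq * tt))
                ripple_times.append(float(c))

    lfp = LfpSignal(x, spec.fs, 0.0, "synthetic-CA1")
    truth = {"ripple_times": np.asarray(ripple_times),
             "trough_times": trough_times}
    return lfp, truth


def _burst_times(centre: float, n_spikes: int, isi_s: float) -> np.ndarray:
    offs = (np.arange(n_spikes) - (n_spikes - 1) / 2.0) * isi_s
    return centre + offs


def generate_unit(
    spec: UnitSpec,
    epochs: EpochSet,
    theta_trough_times: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    unit_id: str = "unit",
    theta_freq: float = 7.0,
) -> SpikeTrain:
    """Synthesize one unit's spike train over the session.

    RUN firing is organised by the theta cycles delimited by consecutive
    trough times; REST firing consists of identical bursts at cycle-free
    Poisson times.  The ``poisson`` archetype emits homogeneous Poisson
    spikes at the state rates instead.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    t_start, t_stop = epochs.t_start, epochs.t_stop
    times = []

    run_ivs = epochs.of_label("RUN") if "RUN" in epochs.labels else np.zeros((0, 2))
    rest_ivs = epochs.of_label("REST") if "REST" in epochs.labels else np.zeros((0, 2))

    if spec.archetype == "poisson":
        for ivs, rate in ((run_ivs, spec.rate_run), (rest_ivs, spec.rate_rest)):
            for start, end in ivs:
                n = rng.poisson(rate * (end - start))
                times.append(rng.uniform(start, end, n))
    else:
        isi_s = spec.intraburst_isi_ms / 1000.0
        spb = spec.spikes_per_burst
        # ---- RUN: one Bernoulli burst opportunity per theta cycle
        if run_ivs.size and spec.rate_run > 0:
            if theta_trough_times is None or len(theta_trough_times) == 0:
                raise ValidationError(
                    "theta_trough_times: required for RUN bursting"
                )
            tr = np.asarray(theta_trough_times, dtype=float)
            for start, end in run_ivs:
                cyc = tr[(tr >= start) & (tr <= end)]
                for c0, c1 in zip(cyc, cyc[1:]):
                    cycle_len = c1 - c0
                    p = spec.rate_run * cycle_len / spb
                    if p > 1.0:
                        raise ValidationError(
                            f"rate_run: infeasible, needs burst probability {p:.2f} > 1"
                        )
                    if rng.random() >= p:
                        continue
                    phase = rng.vonmises(np.deg2rad(spec.pref_phase_deg),
                                         spec.phase_kappa)
                    centre = c0 + (phase % (2 * np.pi)) / (2 * np.pi) * cycle_len
                    times.append(_burst_times(centre, spb, isi_s))
        # ---- REST: bursts at cycle-free Poisson times
        if rest_ivs.size and spec.rate_rest > 0:
            burst_rate = spec.rate_rest / spb
            for start, end in rest_ivs:
                n = rng.poisson(burst_rate * (end - start))
                for c in rng.uniform(start, end, n):
                    times.append(_burst_times(c, spb, isi_s))

    if times:
        t = np.sort(np.concatenate([np.atleast_1d(x) for x in times]))
        t = t[(t >= t_start) & (t <= t_stop)]
        # enforce a strict refractory by dropping the later spike of any
        # too-close pair; iterate until the train is strictly increasing
        while t.size and np.any(np.diff(t) < MIN_ISI_S):
            drop = np.zeros(t.size, dtype=bool)
            drop[1:] = np.diff(t) < MIN_ISI_S
            t = t[~drop]
    else:
        t = np.array([])
    return SpikeTrain(unit_id, t, t_start, t_stop)


def generate_speed(
    epochs: EpochSet,
    rng: Optional[np.random.Generator] = None,
    fs: float = 50.0,
    run_mean: float = 15.0,
    run_sd: float = 4.0,
    tau_s: float = 2.0,
    seed: Optional[int] = None,
) -> SpeedTrace:
    """Running-speed trace coupled to the RUN epochs.

    During RUN the speed follows a mean-reverting (Ornstein-Uhlenbeck)
    process around ``run_mean`` cm/s, clipped at 0; during REST it is ~0
    with small sensor noise.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    t_stop = epochs.t_stop
    n = int(round(t_stop * fs))
    t = np.arange(n) / fs
    speed = np.abs(rng.normal(0.0, 0.2, n))  # REST baseline jitter
    dt = 1.0 / fs
    run_ivs = epochs.of_label("RUN") if "RUN" in epochs.labels else np.zeros((0, 2))
    for start, end in run_ivs:
        idx = np.nonzero((t >= start) & (t < end))[0]
        if idx.size == 0:
            continue
        v = np.empty(idx.size)
        v[0] = max(0.0, rng.normal(run_mean, run_sd))
        a = dt / tau_s
        noise = rng.normal(0.0, run_sd * np.sqrt(2 * a), idx.size)
        for i in range(1, idx.size):
            v[i] = v[i - 1] + a * (run_mean - v[i - 1]) + noise[i]
        speed[idx] = np.maximum(v, 0.0)
    return SpeedTrace(t, speed)


def generate_speed_coupled_train(
    speed: SpeedTrace,
    intercept_hz: float,
    slope_hz_per_cms: float,
    seed: Optional[int] = None,
    unit_id: str = "speed-unit",
) -> SpikeTrain:
    """Inhomogeneous Poisson train with rate = intercept + slope * speed(t).

    Generated by thinning a homogeneous process at the peak rate; used to
    validate the speed-modulation regression against ground truth.
    """
    rng = np.random.default_rng(seed)
    rate = np.maximum(intercept_hz + slope_hz_per_cms * speed.speed, 0.0)
    rmax = float(rate.max())
    t0, t1 = speed.times[0], speed.times[-1]
    if rmax <= 0:
        return SpikeTrain(unit_id, np.array([]), t0, t1)
    n = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    idx = np.clip(np.searchsorted(speed.times, cand), 0, rate.size - 1)
    keep = rng.random(n) < rate[idx] / rmax
    t = cand[keep]
    t = t[np.concatenate([[True], np.diff(t) > 0])]
    return SpikeTrain(unit_id, t, t0, t1)


@dataclass
class SessionBundle:
    """A generated multi-unit session plus its ground truth."""

    spike_trains: dict
    epochs: EpochSet
    lfp: LfpSignal
    speed: SpeedTrace
    ground_truth: dict   # unit_id -> spec dict; plus 'lfp' key
    seed: int


def generate_cohort(
    n_units: int = 89,
    mix: Optional[dict] = None,
    seed: int = 0,
    session_s: float = 360.0,
    lfp_spec: Optional[LfpSpec] = None,
) -> SessionBundle:
    """Generate a full cohort session with ground-truth labels.

    ``mix`` maps archetype -> unit count (default 48 teevra / 23 komal /
    4 group1 / 14 group4) or archetype -> fraction summing to 1.  A single
    master seed fans out deterministic per-component seeds.
    """
    if mix is None:  # default mix scales with n_units as fractions
        total_default = sum(DEFAULT_MIX.values())
        mix = {a: c / total_default for a, c in DEFAULT_MIX.items()}
    else:
        mix = dict(mix)
    for a in mix:
        if a not in ARCHETYPES:
            raise ValidationError(f"archetype: unknown '{a}'")
    total = sum(mix.values())
    if abs(total - 1.0) < 1e-9:  # fractions
        counts = {a: int(round(f * n_units)) for a, f in mix.items()}
        drift = n_units - sum(counts.values())
        if drift:  # assign the rounding remainder to the largest share
            counts[max(mix, key=mix.get)] += drift
    else:
        counts = {a: int(c) for a, c in mix.items()}
        if sum(counts.values()) != n_units:
            raise ValidationError("mix: counts must sum to n_units")
    n_nonzero = sum(1 for c in counts.values() if c > 0)
    if n_units < n_nonzero:
        raise ValidationError("n_units: fewer units than archetypes in the mix")

    ss = np.random.SeedSequence(seed)
    lfp_seed, speed_seed, *unit_seeds = ss.spawn(2 + n_units)

    epochs = make_epochs(session_s)
    spec_lfp = lfp_spec if lfp_spec is not None else LfpSpec()
    lfp, lfp_truth = generate_lfp(spec_lfp, epochs,
                                  rng=np.random.default_rng(lfp_seed))
    speed = generate_speed(epochs, rng=np.random.default_rng(speed_seed))

    trains = {}
    truth = {"lfp": {"ripple_times": lfp_truth["ripple_times"].tolist(),
                     "theta_freq": spec_lfp.theta_freq}}
    i = 0
    for archetype in sorted(counts):
        arch = ARCHETYPES[archetype]
        for _ in range(counts[archetype]):
            rng = np.random.default_rng(unit_seeds[i])
            score = rng.uniform(*arch["score_iqr"])
            rate_run = rng.uniform(*arch["run_iqr"])
            rate_rest = (rate_run * (1 - score) / (1 + score)
                         if archetype != "poisson" else rate_run)
            burst_len = rng.uniform(*arch["burst_iqr"])
            uid = f"u{i:03d}-{archetype}"
            spec = UnitSpec(
                archetype=archetype, rate_rest=rate_rest, rate_run=rate_run,
                burst_len_ms=burst_len,
                intraburst_isi_ms=arch["intraburst_isi_ms"],
                pref_phase_deg=arch["pref_phase_deg"],
                phase_kappa=arch["phase_kappa"],
            )
            trains[uid] = generate_unit(
                spec, epochs, lfp_truth["trough_times"], rng=rng,
                unit_id=uid, theta_freq=spec_lfp.theta_freq,
            )
            rec = asdict(spec)
            rec["target_score"] = float(score)
            truth[uid] = rec
            i += 1
    return SessionBundle(trains, epochs, lfp, speed, truth, seed)


def write_bundle(bundle: SessionBundle, directory: str) -> None:
    """Write the session files plus ``ground_truth.json`` next to them."""
    from .io import Session, save_session

    os.makedirs(directory, exist_ok=True)
    session = Session(bundle.spike_trains, bundle.epochs, bundle.lfp,
                      bundle.speed)
    session.config["seed"] = bundle.seed
    save_session(session, directory)
    with open(os.path.join(directory, "ground_truth.json"), "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, default=float)
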