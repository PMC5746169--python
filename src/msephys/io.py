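"""Readers and writers for tab-delimited session files.

A session directory holds:

* ``spikes.tsv``  — columns ``unit_id``, ``spike_time_s``
* ``epochs.tsv``  — columns ``label``, ``start_s``, ``end_s``
* ``speed.tsv``   — columns ``time_s``, ``speed_cm_s``
* ``lfp.tsv``     — column  ``sample_uv`` (sampling rate in the config), or
  ``lfp.bin``     — flat little-endian int16 with ``lfp_scale_uv`` per LSB
* ``config.yaml`` — key/value parameters (sampling rates, bands, thresholds,
  seed); see :data:`DEFAULT_CONFIG`

All tables carry exactly one header line.  Unsorted spike times are rejected
by default; set ``sort_spikes: true`` in the config to sort on load.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    EpochSet,
    LfpSignal,
    SpeedTrace,
    SpikeTrain,
    UnitMetrics,
    ValidationError,
)

__all__ = [
    "ParseError",
    "Session",
    "DEFAULT_CONFIG",
    "load_config",
    "save_config",
    "load_session",
    "save_session",
    "read_spikes",
    "write_spikes",
    "read_epochs",
    "write_epochs",
    "read_speed",
    "write_speed",
    "read_lfp",
    "write_lfp",
    "write_metrics",
    "read_metrics",
]


class ParseError(ValueError):
    """Malformed session file; message carries file and line number."""


DEFAULT_CONFIG: dict = {
    "lfp_fs": 1000.0,          # Hz; sampling rate of lfp.tsv / lfp.bin
    "lfp_scale_uv": 0.1,       # microvolt per int16 LSB (binary LFP only)
    "lfp_channel": "CA1-pyr",
    "sort_spikes": False,      # reject unsorted spike files unless True
    "theta_band": [4.0, 12.0],  # Hz, phase extraction
    "ripple_band": [130.0, 240.0],  # Hz, event detection
    "min_spikes_acg": 300,     # minimum spikes for an autocorrelogram
    "ri_threshold": 0.1,       # rhythmicity-index filter (strict >)
    "seed": 0,
}


def load_config(path: str) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ParseError(f"{path}: config must be a mapping")
    cfg.update(user)
    return cfg


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclass
class Session:
    """One recording session: units, behavioural epochs, LFP, speed."""

    spike_trains: dict          # unit_id -> SpikeTrain
    epochs: EpochSet
    lfp: Optional[LfpSignal] = None
    speed: Optional[SpeedTrace] = None
    config: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))


def _read_table(path: str, columns: tuple) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # delegate dialect errors with file context
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing} in header")
    for i, col in enumerate(columns):
        if col == "unit_id" or col == "label":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if bad.size:
            # +2: one header line, 1-based numbering
            raise ParseError(
                f"{path}: line {bad[0] + 2}: cannot parse '{col}' value "
                f"{df[col].iloc[bad[0]]!r}"
            )
        df[col] = vals
    return df


def read_spikes(path: str, t_start: float, t_stop: float,
                sort_spikes: bool = False) -> dict:
    """Read ``spikes.tsv`` into a dict of unit_id -> SpikeTrain."""
    df = _read_table(path, ("unit_id", "spike_time_s"))
    trains = {}
    for unit_id, grp in df.groupby("unit_id", sort=True):
        times = grp["spike_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            if sort_spikes:
                times = np.unique(times)
            else:
                raise ValidationError(
                    f"spike_times: unit '{unit_id}' not strictly increasing "
                    "(set sort_spikes to sort on load)"
                )
        trains[str(unit_id)] = SpikeTrain(str(unit_id), times, t_start, t_stop)
    return trains


def write_spikes(trains: dict, path: str) -> None:
    rows = []
    for unit_id in sorted(trains):
        for t in trains[unit_id].spike_times:
            rows.append((unit_id, repr(float(t))))
    with open(path, "w") as fh:
        fh.write("unit_id\tspike_time_s\n")
        for uid, t in rows:
            fh.write(f"{uid}\t{t}\n")


def read_epochs(path: str) -> EpochSet:
    df = _read_table(path, ("label", "start_s", "end_s"))
    return EpochSet(
        (str(r.label), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    )


def write_epochs(epochs: EpochSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart_s\tend_s\n")
        for label, start, end in epochs.intervals:
            fh.write(f"{label}\t{float(start)!r}\t{float(end)!r}\n")


def read_speed(path: str) -> SpeedTrace:
    df = _read_table(path, ("time_s", "speed_cm_s"))
    return SpeedTrace(df["time_s"].to_numpy(float), df["speed_cm_s"].to_numpy(float))


def write_speed(speed: SpeedTrace, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tspeed_cm_s\n")
        for t, s in zip(speed.times, speed.speed):
            fh.write(f"{float(t)!r}\t{float(s)!r}\n")


def read_lfp(path: str, fs: float, t_start: float = 0.0,
             channel_label: str = "lfp", scale_uv: float = 1.0) -> LfpSignal:
    """Read an LFP trace from ``.tsv`` (one column) or flat int16 ``.bin``."""
    if path.endswith(".bin"):
        raw = np.fromfile(path, dtype="<i2").astype(float) * scale_uv
        return LfpSignal(raw, fs, t_start, channel_label)
    df = _read_table(path, ("sample_uv",))
    return LfpSignal(df["sample_uv"].to_numpy(float), fs, t_start, channel_label)


def write_lfp(lfp: LfpSignal, path: str, scale_uv: float = 1.0) -> None:
    if path.endswith(".bin"):
        np.round(lfp.samples / scale_uv).astype("<i2").tofile(path)
        return
    with open(path, "w") as fh:
        fh.write("sample_uv\n")
        for v in lfp.samples:
            fh.write(f"{float(v)!r}\n")


def load_session(directory: str, config: Optional[dict] = None) -> Session:
    """Load and validate a session directory (see module docstring)."""
    cfg_path = os.path.join(directory, "config.yaml")
    if config is None:
        config = load_config(cfg_path) if os.path.exists(cfg_path) else dict(DEFAULT_CONFIG)
    epochs = read_epochs(os.path.join(directory, "epochs.tsv"))
    t_start = config.get("t_start", epochs.t_start)
    t_stop = config.get("t_stop", epochs.t_stop)
    trains = read_spikes(
        os.path.join(directory, "spikes.tsv"), t_start, t_stop,
        sort_spikes=bool(config.get("sort_spikes", False)),
    )
    lfp = None
    for name in ("lfp.tsv", "lfp.bin"):
        p = os.path.join(directory, name)
        if os.path.exists(p):
            lfp = read_lfp(
                p, fs=float(config["lfp_fs"]), t_start=t_start,
                channel_label=str(config.get("lfp_channel", "lfp")),
                scale_uv=float(config.get("lfp_scale_uv", 1.0)),
            )
            break
    speed = None
    sp = os.path.join(directory, "speed.tsv")
    if os.path.exists(sp):
        speed = read_speed(sp)
    return Session(trains, epochs, lfp, speed, config)


def save_session(session: Session, directory: str, lfp_binary: bool = False) -> None:
    os.makedirs(directory, exist_ok=True)
    cfg = dict(session.config)
    cfg.setdefault("t_start", min(t.t_start for t in session.spike_trains.values())
                   if session.spike_trains else session.epochs.t_start)
    cfg.setdefault("t_stop", max(t.t_stop for t in session.spike_trains.values())
                  if session.spike_trains else session.epochs.t_stop)
    write_spikes(session.spike_trains, os.path.join(directory, "spikes.tsv"))
    write_epochs(session.epochs, os.path.join(directory, "epochs.tsv"))
    if session.lfp is not None:
        cfg["lfp_fs"] = float(session.lfp.fs)
        cfg["lfp_channel"] = session.lfp.channel_label
        name = "lfp.bin" if lfp_binary else "lfp.tsv"
        write_lfp(session.lfp, os.path.join(directory, name),
                  scale_uv=float(cfg.get("lfp_scale_uv", 1.0)))
    if session.speed is not None:
        write_speed(session.speed, os.path.join(directory, "speed.tsv"))
    save_config(cfg, os.path.join(directory, "config.yaml"))


def write_metrics(metrics: list, path: str) -> None:
    """Write UnitMetrics records as TSV (``.tsv``) or JSON (``.json``)."""
    rows = [m.to_dict() if isinstance(m, UnitMetrics) else dict(m) for m in metrics]
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1, default=float)
        return
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metrics(path: str) -> pd.DataFrame:
    if path.endswith(".json"):
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path, sep="\t")
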