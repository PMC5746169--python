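"""End-to-end orchestration: per-unit metrics -> rhythmicity filter ->
hierarchical classification -> group phase statistics -> report.

Mirrors the full analysis workflow for a cohort of medial-septal units:
behavioural-state rates and rate-change score, RUN burst duration, the
autocorrelogram rhythmicity fit, theta-phase locking, optional speed
modulation; then a strict RI > 0.1 filter, Ward classification on (score,
burst duration), and the between-group circular comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import ClusterResult, classify_units
from .core import EpochSet, InsufficientDataError, UnitMetrics
from .io import Session
from .phase import (
    PhaseSeries,
    rayleigh,
    spike_phases,
    theta_phase,
    watson_u2,
    angular_linear_correlation,
)
from .rhythmicity import (
    NormalizationError,
    RhythmicityModel,
    filter_rhythmic,
)
from .spike_metrics import (
    detect_bursts,
    firing_rate,
    mean_burst_duration,
    rate_change_score,
    speed_modulation,
)

__all__ = ["PipelineError", "PipelineResult", "compute_unit_metrics", "run_pipeline"]

# Table display rounding: rates and scores to 1 decimal, RI to 2, OF to 1
REPORT_DECIMALS = {
    "rate_rest": 1, "rate_run": 1, "rate_change_score": 1,
    "mean_burst_duration_ms": 1, "phase_deg": 1, "phase_R": 2,
    "RI": 2, "OF": 1, "speed_r": 2,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def compute_unit_metrics(
    train,
    epochs: EpochSet,
    phases: Optional[PhaseSeries] = None,
    speed=None,
    min_spikes_acg: int = 300,
) -> UnitMetrics:
    """All per-unit metrics for one spike train (NaN where undefined)."""
    m = UnitMetrics(unit_id=train.unit_id)
    m.rate_rest = firing_rate(train, epochs, "REST")
    m.rate_run = firing_rate(train, epochs, "RUN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.rate_change_score = rate_change_score(m.rate_rest, m.rate_run)
        m.mean_burst_duration_ms = mean_burst_duration(
            detect_bursts(train, epochs, "RUN")
        )
    try:
        fit = RhythmicityModel.from_spike_train(
            train, epochs, "RUN", min_spikes=min_spikes_acg
        ).fit()
        if fit.converged:
            m.RI, m.OF = fit.RI, fit.OF
    except (InsufficientDataError, NormalizationError):
        pass
    if phases is not None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat = rayleigh(spike_phases(train, phases))
            m.phase_deg, m.phase_R, m.phase_p = stat.mean_deg, stat.R, stat.p
        except InsufficientDataError:
            pass
    if speed is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sf = speed_modulation(train, speed)
        if sf.valid:
            m.speed_r, m.speed_p, m.speed_class = sf.r, sf.p, sf.speed_class
    return m


@dataclass
class PipelineResult:
    """Cohort analysis output."""

    metrics: pd.DataFrame            # all units, one row each
    rhythmic: pd.DataFrame           # RI-filtered subset, with cluster labels
    clusters: Optional[ClusterResult]
    group_stats: pd.DataFrame        # per-group medians / IQRs / silhouettes
    phase_comparison: dict           # Watson U2 Teevra vs Komal, etc.
    stage_counts: dict               # units surviving each stage

    def report_table(self) -> pd.DataFrame:
        """Display table with the report rounding conventions."""
        out = self.metrics.copy()
        for col, dec in REPORT_DECIMALS.items():
            if col in out:
                out[col] = out[col].round(dec)
        return out

    def summary(self) -> str:
        lines = ["Cohort analysis summary", "-" * 40]
        for stage, n in self.stage_counts.items():
            lines.append(f"  {stage:<28s}: {n}")
        if not self.group_stats.empty:
            lines.append("")
            lines.append(self.group_stats.to_string(index=False))
        pc = self.phase_comparison
        if pc.get("watson_p") is not None:
            lines.append("")
            lines.append(
                f"  Teevra vs Komal phase: U2={pc['watson_u2']:.3f}, "
                f"p={pc['watson_p']:.4f}, "
                f"mean diff={pc['mean_phase_diff_deg']:.0f} deg"
            )
        return "\n".join(lines)


def run_pipeline(
    session: Session,
    ri_threshold: float = 0.1,
    min_spikes_acg: int = 300,
    seed: Optional[int] = 0,
) -> PipelineResult:
    """Run the full cohort analysis on a session.

    Deterministic given the session and ``seed`` (used only for the Watson
    permutation test).  Raises :class:`PipelineError` naming the stage that
    leaves no analysable units.
    """
    epochs = session.epochs
    phases = None
    if session.lfp is not None:
        band = tuple(session.config.get("theta_band", (4.0, 12.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phases = theta_phase(session.lfp, epochs, "RUN", band=band)

    rows = []
    for uid in sorted(session.spike_trains):
        m = compute_unit_metrics(
            session.spike_trains[uid], epochs, phases, session.speed,
            min_spikes_acg=min_spikes_acg,
        )
        rows.append(m.to_dict())
    metrics = pd.DataFrame(rows)
    if metrics.empty:
        raise PipelineError("metrics stage: no units in session")

    fittable = metrics[np.isfinite(metrics["RI"])]
    rhythmic = filter_rhythmic(fittable, threshold=ri_threshold).copy()
    counts = {
        "units in session": len(metrics),
        "units with RI fit": len(fittable),
        f"units with RI > {ri_threshold}": len(rhythmic),
    }
    if rhythmic.empty:
        raise PipelineError(
            f"rhythmicity filter: no units with RI > {ri_threshold}"
        )

    clusters = None
    group_stats = pd.DataFrame()
    phase_comparison = {"watson_u2": None, "watson_p": None,
                        "mean_phase_diff_deg": None,
                        "teevra_phase_ri_r": None, "teevra_phase_ri_p": None}
    if len(rhythmic) >= 4:
        clusters = classify_units(
            rhythmic["unit_id"].tolist(),
            rhythmic["rate_change_score"].to_numpy(),
            rhythmic["mean_burst_duration_ms"].to_numpy(),
            rhythmic["rate_run"].to_numpy(),
        )
        rhythmic["cluster_id"] = clusters.labels
        rhythmic["group_label"] = [
            clusters.group_names.get(int(c), "") for c in clusters.labels
        ]
        metrics = metrics.merge(
            rhythmic[["unit_id", "cluster_id", "group_label"]],
            on="unit_id", how="left", suffixes=("_drop", ""),
        )
        metrics["cluster_id"] = metrics["cluster_id"].fillna(-1).astype(int)
        metrics["group_label"] = metrics["group_label"].fillna("")
        metrics = metrics.drop(
            columns=[c for c in metrics.columns if c.endswith("_drop")]
        )

        stats_rows = []
        for cid, name in sorted(clusters.group_names.items()):
            sub = rhythmic[rhythmic["cluster_id"] == cid]
            stats_rows.append({
                "group": name, "n": len(sub),
                "median_score": sub["rate_change_score"].median(),
                "median_burst_ms": sub["mean_burst_duration_ms"].median(),
                "median_rate_run": sub["rate_run"].median(),
                "median_RI": sub["RI"].median(),
                "mean_silhouette": clusters.mean_silhouette(cid),
            })
        group_stats = pd.DataFrame(stats_rows)

        teevra = rhythmic[rhythmic["group_label"] == "Teevra"]
        komal = rhythmic[rhythmic["group_label"] == "Komal"]
        tp = teevra["phase_deg"].to_numpy()
        kp = komal["phase_deg"].to_numpy()
        tp, kp = tp[np.isfinite(tp)], kp[np.isfinite(kp)]
        if tp.size >= 8 and kp.size >= 8:
            u2, p = watson_u2(tp, kp, seed=seed)
            diff = np.rad2deg(np.angle(
                np.exp(1j * np.deg2rad(tp)).mean()
                / np.exp(1j * np.deg2rad(kp)).mean()
            ))
            phase_comparison.update(
                watson_u2=u2, watson_p=p,
                mean_phase_diff_deg=float(abs(diff)),
            )
        t_ri = teevra["RI"].to_numpy()
        tp_all = teevra["phase_deg"].to_numpy()
        ok = np.isfinite(t_ri) & np.isfinite(tp_all)
        if ok.sum() >= 8:
            r, p = angular_linear_correlation(tp_all[ok], t_ri[ok])
            phase_comparison.update(teevra_phase_ri_r=r, teevra_phase_ri_p=p)

    counts["units clustered"] = 0 if clusters is None else len(rhythmic)
    return PipelineResult(metrics, rhythmic, clusters, group_stats,
                          phase_comparison, counts)
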