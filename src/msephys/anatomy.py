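"""Septo-temporal distance, target-selectivity and bouton-distribution
computations for juxtacellularly labelled projection neurons.

Distances along the hippocampal long axis are 3-D Euclidean distances of
stereotaxic (ML, AP, DV) atlas coordinates (mm) from the septal pole of the
hippocampal formation, or linear section-count distances.  Target
selectivity is the probability that ``n`` sequentially sampled synaptic
targets all belong to a class making up a given ``fraction`` of the
candidate population: ``fraction ** n``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .phase import angular_linear_correlation

__all__ = [
    "SEPTAL_POLE_MM",
    "StereotaxicPoint",
    "BoutonTally",
    "septotemporal_distance",
    "linear_section_distance",
    "selectivity_probability",
    "truncate_sigfigs",
    "format_probability",
    "bouton_region_fractions",
    "metric_distance_correlation",
]

# Septal pole of the hippocampal formation, atlas coordinates (mm)
SEPTAL_POLE_MM = (0.0, -0.98, -1.4)


@dataclass(frozen=True)
class StereotaxicPoint:
    """Atlas coordinates in mm: medio-lateral, antero-posterior, dorso-ventral."""

    ML: float
    AP: float
    DV: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.ML, self.AP, self.DV)):
            raise ValueError("StereotaxicPoint: coordinates must be finite")


def septotemporal_distance(point, pole=SEPTAL_POLE_MM) -> float:
    """3-D Euclidean distance (mm) from the septal pole of the hippocampus."""
    if isinstance(point, StereotaxicPoint):
        p = (point.ML, point.AP, point.DV)
    else:
        p = tuple(point)
    return float(np.sqrt(sum((a - b) ** 2 for a, b in zip(p, pole))))


def linear_section_distance(soma_section: int, target_section: int,
                            thickness_um: float) -> float:
    """|section index difference| * section thickness, in mm."""
    return abs(int(target_section) - int(soma_section)) * thickness_um / 1000.0


def selectivity_probability(fraction: float, n_targets: int) -> float:
    """P(all ``n_targets`` sequential targets fall in a class of prevalence
    ``fraction``) = fraction ** n_targets."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    return float(fraction) ** int(n_targets)


def truncate_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Truncate (not round) the mantissa to ``sigfigs`` significant figures.

    0.0002187 -> 0.00021 at 2 significant figures.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - sigfigs + 1)
    return math.trunc(x / scale) * scale


def format_probability(p: float, sigfigs: int = 2) -> str:
    """Display form, mantissa truncated: 0.0002187 -> '2.1e-04'."""
    t = truncate_sigfigs(p, sigfigs)
    return f"{t:.{sigfigs - 1}e}"


@dataclass(frozen=True)
class BoutonTally:
    """Axonal bouton counts per (region, layer)."""

    counts: dict  # (region, layer) -> count

    def __post_init__(self):
        for key, v in self.counts.items():
            if v < 0:
                raise ValueError(f"BoutonTally: negative count for {key}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def by_region(self) -> dict:
        out = {}
        for key, v in self.counts.items():
            region = key[0] if isinstance(key, tuple) else key
            out[region] = out.get(region, 0) + int(v)
        return out


def bouton_region_fractions(tally) -> dict:
    """Per-region bouton percentages (0-100, full precision)."""
    if isinstance(tally, BoutonTally):
        counts = tally.by_region()
    else:
        counts = dict(tally)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("bouton_region_fractions: zero total")
    return {region: 100.0 * v / total for region, v in counts.items()}


def metric_distance_correlation(values, distances_mm, kind: str = "linear"):
    """Correlation of a per-cell metric with septo-temporal distance.

    ``kind='linear'`` -> Pearson r with the exact two-sided t-test p;
    ``kind='angular'`` -> angular-linear correlation (values are the
    distances, angles the metric).  Returns ``(r, p)``.
    """
    x = np.asarray(values, dtype=float)
    d = np.asarray(distances_mm, dtype=float)
    if x.size != d.size:
        raise ValueError("values and distances must have equal length")
    if x.size < 4:
        raise ValueError("metric_distance_correlation: need n >= 4")
    if kind == "linear":
        if np.ptp(x) == 0 or np.ptp(d) == 0:
            warnings.warn("metric_distance_correlation: degenerate variance")
            return float("nan"), float("nan")
        res = pearsonr(x, d)
        return float(res.statistic), float(res.pvalue)
    if kind == "angular":
        return angular_linear_correlation(x, d)
    raise ValueError("kind must be 'linear' or 'angular'")
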