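"""Induction / sensitivity / adaptation statistics and the integer distance.

A trajectory responds to one of two Shh ramps.  Its induction is the peak
level reached within the first 40 h relative to the pre-stimulation basal
level; its adaptation is the peak relative to the mean level over the late
window (40-70 h); the sensitivity contrasts the peaks under the two ramps.
Each ratio is scored against a required minimum by an incremental integer
ladder (larger shortfall, larger penalty; meeting the requirement scores
zero), and the distance used in the ABC screen is the sum of penalties over
the model's readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .pathway_models import ModelVariant

__all__ = [
    "AdaptationMetrics",
    "DistanceScore",
    "MRNA_REQUIREMENTS",
    "GLIA_REQUIREMENTS",
    "compute_metrics",
    "score_ratio",
    "total_distance",
]

#: Required minimum ratios for mRNA readouts: 50-fold induction under the
#: strong ramp, 30-fold under the weak one, 1.5-fold peak sensitivity
#: between ramps, and 2.5-fold peak-over-adapted decline for both.
MRNA_REQUIREMENTS: dict[str, float] = {
    "induction1": 50.0,
    "induction2": 30.0,
    "sensitivity": 1.5,
    "adaptation1": 2.5,
    "adaptation2": 2.5,
}

#: Auxiliary respond-and-adapt requirement on the GliA trajectory itself.
#: The screen demands only that GliA visibly responds and declines again;
#: the thresholds are a package default and can be overridden per run.
GLIA_REQUIREMENTS: dict[str, float] = {
    "induction1": 2.0,
    "induction2": 2.0,
    "adaptation1": 2.0,
    "adaptation2": 2.0,
}

_BASAL_FLOOR = 1e-12


@dataclass(frozen=True)
class AdaptationMetrics:
    """Per-readout response statistics under the two Shh ramps."""

    basal: float
    max1: float
    max2: float
    adapted1: float
    adapted2: float

    @property
    def induction1(self) -> float:
        return self.max1 / max(self.basal, _BASAL_FLOOR)

    @property
    def induction2(self) -> float:
        return self.max2 / max(self.basal, _BASAL_FLOOR)

    @property
    def sensitivity(self) -> float:
        return self.max1 / max(self.max2, _BASAL_FLOOR)

    @property
    def adaptation1(self) -> float:
        return self.max1 / max(self.adapted1, _BASAL_FLOOR)

    @property
    def adaptation2(self) -> float:
        return self.max2 / max(self.adapted2, _BASAL_FLOOR)

    def ratio(self, name: str) -> float:
        return getattr(self, name)

    def to_dict(self) -> dict[str, float]:
        return {
            k: float(getattr(self, k))
            for k in (
                "basal",
                "max1",
                "max2",
                "adapted1",
                "adapted2",
                "induction1",
                "induction2",
                "sensitivity",
                "adaptation1",
                "adaptation2",
            )
        }


@dataclass
class DistanceScore:
    """Integer penalties keyed by (readout, criterion); zero total means the
    trajectory meets every requirement."""

    penalties: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.penalties.values()))

    def records(self) -> list[dict]:
        return [
            {"readout": r, "criterion": c, "penalty": int(p)}
            for (r, c), p in self.penalties.items()
        ]


def _series(traj) -> tuple[np.ndarray, np.ndarray]:
    """Accept a pandas Series (index = hours) or a (times, values) pair."""
    if hasattr(traj, "index") and hasattr(traj, "values"):
        return np.asarray(traj.index, float), np.asarray(traj.values, float)
    t, y = traj
    return np.asarray(t, float), np.asarray(y, float)


def _window_mean(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal mean of y over [lo, hi], interpolating the endpoints."""
    grid = np.unique(np.concatenate(([lo, hi], t[(t > lo) & (t < hi)])))
    vals = np.interp(grid, t, y)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def compute_metrics(
    traj1,
    traj2,
    basal: float,
    window_peak: float = 40.0,
    window_adapted: tuple[float, float] = (40.0, 70.0),
) -> AdaptationMetrics:
    """Peak / late-window statistics of one readout under the two ramps.

    ``traj1`` / ``traj2`` are the readout's time courses under the strong
    and weak Shh ramp (pandas Series indexed by hours, or (t, y) pairs)
    and must cover [0, window_adapted[1]] h.  ``basal`` is the
    pre-stimulation steady-state level of the same readout (floored at
    1e-12 in the ratios).  Peaks are maxima over grid points with
    t <= ``window_peak``; adapted levels are trapezoidal means over
    ``window_adapted``.
    """
    lo, hi = window_adapted
    out = []
    for traj in (traj1, traj2):
        t, y = _series(traj)
        if t[0] > 0.0 or t[-1] < hi:
            raise ValueError(
                f"trajectory must cover [0, {hi}] h, got [{t[0]}, {t[-1]}]"
            )
        peak = float(np.max(y[t <= window_peak]))
        adapted = _window_mean(t, y, lo, hi)
        out.append((peak, adapted))
    (max1, adapted1), (max2, adapted2) = out
    return AdaptationMetrics(
        basal=float(basal), max1=max1, max2=max2, adapted1=adapted1, adapted2=adapted2
    )


def score_ratio(ratio: float, required: float) -> int:
    """Incremental integer penalty for a ratio against its required minimum.

    For the adaptation requirement of 2.5 the ladder is: ratio < 1 scores
    10, < 1.1 scores 5, < 1.5 scores 2, < 2 scores 1, >= 2.5 scores 0; the
    uncovered band [2, 2.5) carries the last nonzero penalty (1).  For any
    other requirement R the breakpoints scale proportionally
    (R * {1, 1.1, 1.5, 2} / 2.5) with the same penalties, so a ratio at or
    above its requirement always scores 0 and exceeding it never helps.
    """
    if not (ratio > 0 and required > 0):
        raise ValueError("ratio and required must be positive")
    if ratio >= required:
        return 0
    s = required / 2.5
    if ratio < 1.0 * s:
        return 10
    if ratio < 1.1 * s:
        return 5
    if ratio < 1.5 * s:
        return 2
    return 1


def required_readouts(variant: ModelVariant) -> tuple[str, ...]:
    """Readouts entering the distance: the Gli reporter always, ptch1 mRNA
    only where its transcription is Gli-coupled, GliA as auxiliary."""
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(variant)
    if variant.ptc_regulated:
        return ("gfp_mRNA", "ptc_mRNA", "GliA")
    return ("gfp_mRNA", "GliA")


def total_distance(
    metrics_by_readout: Mapping[str, AdaptationMetrics],
    variant: ModelVariant,
    glia_requirements: Mapping[str, float] | None = None,
) -> DistanceScore:
    """Sum the ladder penalties over every readout the variant requires.

    mRNA readouts are scored on induction under both ramps (required 50-
    and 30-fold), peak sensitivity (1.5) and adaptation under both ramps
    (2.5 each); the GliA trajectory is scored on the softer
    respond-and-adapt requirements.  A missing required readout raises.
    """
    if glia_requirements is None:
        glia_requirements = GLIA_REQUIREMENTS
    score = DistanceScore()
    for readout in required_readouts(variant):
        if readout not in metrics_by_readout:
            raise KeyError(f"metrics for required readout {readout!r} missing")
        m = metrics_by_readout[readout]
        reqs = glia_requirements if readout == "GliA" else MRNA_REQUIREMENTS
        for criterion, required in reqs.items():
            score.penalties[(readout, criterion)] = score_ratio(
                m.ratio(criterion), required
            )
    return score
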