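"""Rupture-event detection, bond-multiplicity classification, binding probability.

A rupture shows up on the retract trace as tensile force built up over many
samples that collapses sharply toward the post-rupture baseline.  Detection
uses a local step statistic d[i] = mean(force over the ``pre_window`` samples
ending at i) - mean(force over the ``post_window`` samples after a short
gap): d peaks at the last loaded sample of a rupture.  Local maxima of d are
events iff d exceeds ``snr_threshold`` times the baseline noise sd.  Because
d averages over windows on both sides, its noise-only standard deviation is
well below the per-sample noise, which is what keeps the false-positive rate
on pure-noise traces essentially zero even at an SNR threshold of 2 while
near-threshold steps (below snr * sd) stay unreported.  Rupture forces are
read from the unsmoothed trace at the peak, relative to the far-from-surface
baseline; per-event noise is the post-rupture baseline fluctuation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import find_peaks
from statsmodels.stats.proportion import proportion_confint

from .curve_io import CurveSet, ForceCurve

__all__ = [
    "RuptureEvent",
    "BindingClass",
    "BindingProbability",
    "detect_events",
    "classify_curve",
    "binding_probability",
    "binding_probability_from_counts",
]

logger = logging.getLogger(__name__)


@dataclass
class RuptureEvent:
    """One detected unbinding: the unit of all downstream kinetic analysis."""

    force: float                 # rupture force, pN (baseline-corrected, unsmoothed)
    position: float              # piezo position at rupture, nm
    noise_sd: float              # post-rupture baseline force fluctuation, pN
    loading_rate: float = field(default=float("nan"))  # pN/s, filled by elasticity
    order: int = 0               # index within the curve, by position
    curve_id: str = ""
    detection_floor: float = 0.0  # pN; smallest step the detector could report
    kl: float = field(default=float("nan"))    # molecular stiffness at rupture, pN/nm
    keff: float = field(default=float("nan"))  # effective spring constant, pN/nm
    fit_status: str = ""

    def __post_init__(self) -> None:
        if not (self.force > 0):
            raise ValueError(f"force must be positive, got {self.force}")
        if not (self.noise_sd > 0):
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")


class BindingClass(str, Enum):
    NONE = "none"
    SINGLE = "single"
    DOUBLE_SIMULTANEOUS = "double_simultaneous"
    DOUBLE_SEQUENTIAL = "double_sequential"


def _robust_sd(x: np.ndarray) -> float:
    """Trend-insensitive noise sd from first differences (MAD-based)."""
    if x.size < 3:
        return 0.0
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def detect_events(
    curve: ForceCurve,
    snr_threshold: float = 2.0,
    *,
    pre_window: int = 20,
    gap: int = 2,
    post_window: int = 12,
    baseline_window: int = 50,
    min_separation: int = 6,
) -> list[RuptureEvent]:
    """Detect rupture events on the retract segment of one curve.

    Parameters
    ----------
    snr_threshold : float
        Minimum force step in units of the baseline noise sd.
    pre_window : int
        Samples over which the pre-rupture force level is averaged.
    gap, post_window : int
        Post-peak averaging window (after a short gap) for the step
        statistic; short enough to resolve closely spaced sequential
        ruptures.
    baseline_window : int
        Far-from-surface window (end of the retract trace) from which the
        zero-force baseline and the per-event post-rupture noise sd are
        estimated.
    min_separation : int
        Minimum distance (samples) between reported events.
    """
    if not (snr_threshold > 0):
        raise ValueError(f"snr_threshold must be positive, got {snr_threshold}")
    if not curve.has_segment("retract"):
        raise ValueError(f"curve {curve.curve_id!r} has no retract segment")
    sl = curve.segment_slice("retract")
    z = curve.z[sl]
    f = curve.force[sl]
    n = f.size
    if n < pre_window + gap + post_window + 2:
        return []

    # rolling means via cumulative sums
    c = np.concatenate([[0.0], np.cumsum(f)])
    idx = np.arange(n)
    pre_ok = idx >= pre_window - 1
    pre_mean = np.full(n, -np.inf)
    pre_mean[pre_ok] = (c[idx[pre_ok] + 1] - c[idx[pre_ok] + 1 - pre_window]) / pre_window
    post_ok = idx + gap + post_window < n
    post_mean = np.full(n, np.inf)
    j = idx[post_ok]
    post_mean[post_ok] = (c[j + gap + post_window + 1] - c[j + gap + 1]) / post_window
    d = pre_mean - post_mean

    # noise sd robust to sparse jumps: MAD of first differences
    sigma = max(_robust_sd(f), 1e-6)
    threshold = snr_threshold * sigma
    raw_peaks, _ = find_peaks(d, height=threshold, distance=min_separation)
    # snap each d-peak to the last sample that still sits at the loaded
    # level (the peak of d can wander a couple of samples onto the
    # post-drop plateau under noise).  The sample must carry sustained load
    # -- a short pre-average above the post level -- which rejects both the
    # declining flank of d downstream of a genuine rupture and isolated
    # noise spikes riding on it.
    kept: list[int] = []
    for p in raw_peaks:
        window = range(min(p + 2, n - 1), max(p - 5, 3), -1)
        snapped = next(
            (i for i in window
             if np.isfinite(post_mean[i])
             and f[i] - post_mean[i] >= threshold
             and np.mean(f[i - 3:i + 1]) - post_mean[i] >= threshold),
            None)
        if snapped is not None and (not kept or snapped - kept[-1] >= min_separation):
            kept.append(snapped)

    if not kept:
        return []

    # zero-force baseline and post-rupture noise from the trace tail
    tail = f[-baseline_window:]
    baseline = float(np.median(tail))
    noise_sd = max(_robust_sd(tail), 1e-6)

    # second pass: a double bond whose surviving arm ruptures within a few
    # samples of the first produces two steps closer than min_separation,
    # merged by the primary peak search.  Look for a step down onto a still-
    # loaded intermediate plateau just upstream of each confirmed rupture.
    # Safe on single-bond curves because there the trace upstream of the
    # rupture is a rising ramp: the level difference comes out negative.
    extra: list[int] = []
    for p0 in kept:
        best, best_score = None, threshold
        for i in range(p0 - 1, max(p0 - min_separation - 3, 3), -1):
            level1 = float(np.mean(f[max(i - 3, 0):i + 1]))
            plateau = float(np.mean(f[i + 1:p0 + 1]))
            score = level1 - plateau
            if plateau - baseline >= threshold and score >= best_score:
                best, best_score = i, score
        if best is not None:
            extra.append(best)
    kept = sorted(set(kept + extra))

    out = []
    prev = -n
    for p in kept:
        # rupture force from the endpoint of a short line fit through the
        # last loaded samples: averages sampling noise without the downward
        # bias of a single early sample on a rising ramp
        lo = max(p - 4, prev + 1, 0)
        seg = f[lo:p + 1]
        if seg.size >= 3:
            t = np.arange(seg.size, dtype=float)
            coef = np.polyfit(t, seg, 1)
            level = float(np.polyval(coef, seg.size - 1))
        else:
            level = float(f[p])
        prev = p
        force = level - baseline
        if force <= 0:
            continue
        out.append(RuptureEvent(force=force, position=float(z[p]), noise_sd=noise_sd,
                                curve_id=curve.curve_id, detection_floor=threshold))
    for order, e in enumerate(out):
        e.order = order
    return out


def classify_curve(events: list[RuptureEvent], simultaneity_window: float = 5.0) -> BindingClass:
    """Bond-multiplicity class of one curve from its detected events.

    Two ruptures separated by at most ``simultaneity_window`` nm count as
    simultaneous.  Curves with more than two events are classified from the
    last two (a warning is logged); only the final unbinding is counted in
    binding statistics.
    """
    if len(events) == 0:
        return BindingClass.NONE
    if len(events) == 1:
        return BindingClass.SINGLE
    if len(events) > 2:
        logger.warning("curve %s has %d rupture events; classifying from the last two",
                       events[0].curve_id, len(events))
    a, b = sorted(events, key=lambda e: e.position)[-2:]
    if abs(b.position - a.position) <= simultaneity_window:
        return BindingClass.DOUBLE_SIMULTANEOUS
    return BindingClass.DOUBLE_SEQUENTIAL


@dataclass
class BindingProbability:
    """Binding statistics of a curve set with a Wilson binomial CI."""

    probability: float
    ci_low: float
    ci_high: float
    n_curves: int
    n_bound: int
    n_double: int

    @property
    def double_fraction(self) -> float:
        return self.n_double / self.n_curves


def binding_probability_from_counts(
    n_bound: int, n_curves: int, n_double: int = 0, alpha: float = 0.05
) -> BindingProbability:
    if n_curves <= 0:
        raise ValueError("n_curves must be positive")
    if not (0 <= n_bound <= n_curves) or not (0 <= n_double <= n_bound):
        raise ValueError("need 0 <= n_double <= n_bound <= n_curves")
    lo, hi = proportion_confint(n_bound, n_curves, alpha=alpha, method="wilson")
    return BindingProbability(probability=n_bound / n_curves, ci_low=float(lo),
                              ci_high=float(hi), n_curves=n_curves,
                              n_bound=n_bound, n_double=n_double)


def binding_probability(
    curves: CurveSet,
    events_per_curve: list[list[RuptureEvent]],
    simultaneity_window: float = 5.0,
) -> BindingProbability:
    """Fraction of curves showing at least one specific unbinding event.

    A curve with sequential ruptures still contributes a single bound count
    (only its final unbinding is counted); the double-bond fraction is
    returned alongside for association analysis.
    """
    if len(events_per_curve) != len(curves):
        raise ValueError("events_per_curve must align with curves")
    classes = [classify_curve(ev, simultaneity_window) for ev in events_per_curve]
    n_bound = sum(c is not BindingClass.NONE for c in classes)
    n_double = sum(c in (BindingClass.DOUBLE_SIMULTANEOUS, BindingClass.DOUBLE_SEQUENTIAL)
                   for c in classes)
    return binding_probability_from_counts(n_bound, len(curves), n_double)
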