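"""End-to-end analysis: curve sets in, per-condition kinetics summary out.

Stages: rupture detection on every retract trace -> bond-class statistics
per (velocity, dwell) cell -> loading-rate assignment (WLC fit) -> bimodal
decomposition and +/-2 sigma single-bond gating -> Bell-Evans ML off-rate
fit -> dwell-curve association fits -> summary table.  Each stage is an
importable function; the numbered analysis scripts and the CLI are thin
wrappers around :func:`analyze_condition`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curve_io import CurveSet, compute_dwell_time
from .elasticity import annotate_loading_rates
from .events import (
    BindingClass,
    RuptureEvent,
    binding_probability_from_counts,
    classify_curve,
    detect_events,
)
from .off_kinetics import (
    BellFitResult,
    DegenerateFit,
    build_pdf,
    fit_bell_ml,
    fit_bimodal,
    gate_single_bond,
)
from .on_kinetics import (
    DwellCurveFit,
    OnRateFit,
    effective_concentration,
    fit_dwell_curve,
    on_rate,
    two_bond_on_rate,
)
from .report import KineticsSummary, summarize

__all__ = ["DetectionResult", "ConditionAnalysis", "detect_curveset",
           "association_table", "analyze_condition", "events_dataframe"]

logger = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Events and bond classes for one curve set."""

    curveset: CurveSet
    events_per_curve: list
    classes: list
    dwell_times: list

    @property
    def n_bound(self) -> int:
        return sum(c is not BindingClass.NONE for c in self.classes)

    @property
    def n_double(self) -> int:
        return sum(c in (BindingClass.DOUBLE_SIMULTANEOUS, BindingClass.DOUBLE_SEQUENTIAL)
                   for c in self.classes)

    def final_rupture_events(self) -> list:
        """Only the last unbinding of each bound curve is counted."""
        out = []
        for ev in self.events_per_curve:
            if ev:
                out.append(max(ev, key=lambda e: e.position))
        return out


def detect_curveset(
    curveset: CurveSet,
    snr_threshold: float = 2.0,
    simultaneity_window: float = 5.0,
    assign_rates: bool = True,
) -> DetectionResult:
    """Detect + classify every curve; optionally assign loading rates."""
    events_per_curve, classes, dwells = [], [], []
    for curve in curveset:
        events = detect_events(curve, snr_threshold=snr_threshold)
        if assign_rates and events:
            annotate_loading_rates(curve, events)
        events_per_curve.append(events)
        classes.append(classify_curve(events, simultaneity_window))
        dwells.append(compute_dwell_time(curve))
    return DetectionResult(curveset=curveset, events_per_curve=events_per_curve,
                           classes=classes, dwell_times=dwells)


def association_table(detections: list[DetectionResult]) -> pd.DataFrame:
    """Per-cell association statistics: measured dwell, binding and
    double-bond fractions with counts (cells pooled by nominal dwell)."""
    rows = []
    for det in detections:
        bp = binding_probability_from_counts(det.n_bound, len(det.curveset), det.n_double)
        rows.append({
            "condition": det.curveset.condition,
            "velocity_nm_per_s": det.curveset.curves[0].velocity,
            "nominal_dwell_s": det.curveset.dwell_time_s,
            "measured_dwell_s": float(np.median(det.dwell_times)),
            "n_curves": bp.n_curves,
            "n_bound": bp.n_bound,
            "n_double": bp.n_double,
            "binding_probability": bp.probability,
            "ci_low": bp.ci_low,
            "ci_high": bp.ci_high,
            "double_fraction": bp.double_fraction,
        })
    return pd.DataFrame(rows)


def events_dataframe(detections: list[DetectionResult]) -> pd.DataFrame:
    """Flat event table (one row per detected rupture) for export."""
    rows = []
    for det in detections:
        for curve, events, cls in zip(det.curveset, det.events_per_curve, det.classes):
            for e in events:
                rows.append({
                    "curve_id": e.curve_id, "order": e.order, "force_pN": e.force,
                    "position_nm": e.position, "noise_sd_pN": e.noise_sd,
                    "detection_floor_pN": e.detection_floor,
                    "kl_pN_per_nm": e.kl, "keff_pN_per_nm": e.keff,
                    "loading_rate_pN_per_s": e.loading_rate,
                    "velocity_nm_per_s": curve.velocity,
                    "fit_status": e.fit_status, "class": cls.value,
                })
    return pd.DataFrame(rows)


@dataclass
class ConditionAnalysis:
    condition: str
    bell: BellFitResult
    on_fit: OnRateFit
    summary: KineticsSummary
    association: pd.DataFrame
    bimodal: object = None
    n_events_total: int = 0
    n_events_gated: int = 0
    diagnostics: dict = field(default_factory=dict)


def _fit_association(table: pd.DataFrame, ceff: float) -> OnRateFit:
    t = table["measured_dwell_s"].to_numpy()
    n = table["n_curves"].to_numpy()
    p = table["binding_probability"].to_numpy()
    p2 = table["double_fraction"].to_numpy()
    bind_fit: DwellCurveFit = fit_dwell_curve(t, p, n_curves=n)
    kon = on_rate(bind_fit.tau, ceff)
    log_kon_err = (bind_fit.tau_err / bind_fit.tau / np.log(10)
                   if np.isfinite(bind_fit.tau_err) else float("nan"))
    double_fit = two_bond_on_rate(t, p2, n_curves=n)
    kon2 = 1.0 / double_fit.tau
    log_kon2_err = (double_fit.tau_err / double_fit.tau / np.log(10)
                    if np.isfinite(double_fit.tau_err) else float("nan"))
    return OnRateFit(A=bind_fit.A, t0=bind_fit.t0, tau=bind_fit.tau, ceff=ceff,
                     kon=kon, log_kon_err=log_kon_err,
                     kon2=kon2, log_kon2_err=log_kon2_err)


def analyze_condition(
    curvesets: list[CurveSet],
    condition: str | None = None,
    snr_threshold: float = 2.0,
    linker_length: float = 6.0,
    antibody_half_length: float = 4.0,
    convolve_noise: bool = False,
    kd_mode: str = "single_bond",
) -> ConditionAnalysis:
    """Run the full pipeline on all curve sets of one condition.

    Off-rate analysis pools final-rupture events across all cells (the
    loading-rate spread comes from the velocity grid); association analysis
    uses the per-cell binding and double-bond fractions versus measured
    dwell time.
    """
    if not curvesets:
        raise ValueError("need at least one curve set")
    condition = condition or curvesets[0].condition
    detections = [detect_curveset(cs, snr_threshold=snr_threshold) for cs in curvesets]

    table = association_table(detections)
    # association: fit only cells at the dominant retraction velocity --
    # detection efficiency (hence apparent saturation) varies with pulling
    # speed, so mixing velocities would distort the dwell curve.  Every
    # remaining cell is its own point at its own measured dwell time.
    velocity_counts = table.groupby("velocity_nm_per_s")["n_curves"].sum()
    v_assoc = float(velocity_counts.idxmax())
    assoc = table[table["velocity_nm_per_s"] == v_assoc]
    ceff = effective_concentration(linker_length, antibody_half_length)
    on_fit = _fit_association(assoc, ceff)

    # off-rate: final ruptures only, bimodal gate within each confined
    # loading-rate range (one per retraction velocity -- pooling velocities
    # would smear the single/double modes together), then ML Bell-Evans fit
    by_velocity: dict[float, list[RuptureEvent]] = {}
    n_final = 0
    for det in detections:
        v = det.curveset.curves[0].velocity
        # curves classified as multi-bond by morphology are excluded up
        # front; their final ruptures start from a pre-loaded surviving
        # bond and do not follow the fresh single-bond statistics
        final = [max(ev, key=lambda e: e.position)
                 for ev, cls in zip(det.events_per_curve, det.classes)
                 if ev and cls is BindingClass.SINGLE]
        n_final += len(final)
        by_velocity.setdefault(v, []).extend(final)
    if n_final < 3:
        raise RuntimeError(f"condition {condition!r}: too few events for off-rate analysis")
    gated: list[RuptureEvent] = []
    bimodal = {}
    for v, group in sorted(by_velocity.items()):
        try:
            bm = fit_bimodal(group)
            gated.extend(gate_single_bond(group, bm))
            bimodal[v] = bm
        except (DegenerateFit, ValueError) as exc:
            # no resolvable second mode: fall back to a robust unimodal
            # +/-2 sd gate, which still strips stray multi-bond ruptures
            forces = np.array([e.force for e in group])
            med = float(np.median(forces))
            sd = max(1.4826 * float(np.median(np.abs(forces - med))), 1e-6)
            gated.extend(e for e in group if med - 2 * sd <= e.force <= med + 2 * sd)
            logger.info("condition %s, v=%g nm/s: unimodal +/-2sd gate (%s)",
                        condition, v, exc)
    bell = fit_bell_ml(gated, convolve_noise=convolve_noise)
    summary = summarize(bell.params, on_fit, condition, kd_mode=kd_mode)

    logger.info("condition %s: %d curves, %d bound, %d events gated, koff=%.3g, kon=%.3g",
                condition, int(table["n_curves"].sum()), int(table["n_bound"].sum()),
                len(gated), bell.params.koff, on_fit.kon)
    all_final = [e for group in by_velocity.values() for e in group]
    pdf = build_pdf(all_final) if all_final else None
    return ConditionAnalysis(
        condition=condition, bell=bell, on_fit=on_fit, summary=summary,
        association=table, bimodal=bimodal,
        n_events_total=n_final, n_events_gated=len(gated),
        diagnostics={"force_pdf": pdf, "detections": detections},
    )
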