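"""Molecular elasticity: worm-like-chain fits and loading-rate assignment.

The force on the bond during retraction rises at a rate set by the pulling
velocity and the *effective* stiffness of the cantilever-linker-membrane
series: r = v * Keff with Keff = (1/Kc + 1/KL)^-1, where KL is the stiffness
of the molecular tether (PEG linker plus membrane compliance, lumped) at the
moment of rupture.  KL is obtained by fitting the pre-rupture stretch with
the interpolated worm-like-chain force-extension law (Marko-Siggia form)

    F(x) = (kBT/Lp) * [ 1/(4*(1 - x/Lc)^2) - 1/4 + x/Lc ]

and taking its analytic derivative at the rupture force.  Extension is the
piezo travel corrected for cantilever deflection, x = z - F/Kc.  Events whose
WLC fit fails fall back to a local linear slope over the final samples before
rupture (flagged in ``fit_status``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .constants import KBT_PN_NM
from .curve_io import ForceCurve
from .events import RuptureEvent

__all__ = [
    "SpringSystem",
    "WlcFit",
    "FitFailure",
    "wlc_force",
    "wlc_stiffness",
    "fit_wlc",
    "effective_spring_constant",
    "loading_rate",
    "annotate_loading_rates",
]

logger = logging.getLogger(__name__)


class FitFailure(RuntimeError):
    """WLC fit did not converge or had too few samples."""


@dataclass
class SpringSystem:
    """Cantilever + molecular tether in series."""

    kc: float    # cantilever, pN/nm
    kl: float    # molecular tether at rupture, pN/nm
    keff: float  # series combination, pN/nm

    def __post_init__(self) -> None:
        if not (self.kc > 0 and self.kl > 0 and self.keff > 0):
            raise ValueError("all stiffnesses must be positive")
        if self.keff > min(self.kc, self.kl) * (1 + 1e-9):
            raise ValueError("keff cannot exceed either series component")


@dataclass
class WlcFit:
    contour_length: float      # Lc, nm
    persistence_length: float  # Lp, nm
    kl: float                  # dF/dx at the rupture force, pN/nm
    status: str = "wlc"


def wlc_force(x, contour_length: float, persistence_length: float, kbt: float = KBT_PN_NM):
    """Interpolated WLC force-extension law, pN.  Valid for 0 <= x < Lc."""
    t = np.clip(np.asarray(x, dtype=float) / contour_length, 0.0, 1.0 - 1e-9)
    return (kbt / persistence_length) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)


def wlc_stiffness(x, contour_length: float, persistence_length: float, kbt: float = KBT_PN_NM):
    """Analytic derivative dF/dx of the interpolated WLC law, pN/nm."""
    t = np.clip(np.asarray(x, dtype=float) / contour_length, 0.0, 1.0 - 1e-9)
    return (kbt / persistence_length) * (0.5 / (1.0 - t) ** 3 + 1.0) / contour_length


def _wlc_extension(force: float, contour_length: float, persistence_length: float,
                   kbt: float = KBT_PN_NM) -> float:
    """Invert the WLC law numerically for the extension at a given force."""
    grid = np.linspace(0.0, 1.0 - 1e-6, 20001) * contour_length
    fg = wlc_force(grid, contour_length, persistence_length, kbt)
    return float(np.interp(force, fg, grid))


def fit_wlc(
    curve: ForceCurve,
    event: RuptureEvent,
    min_samples: int = 10,
    noise_floor: float = 0.5,
    kbt: float = KBT_PN_NM,
) -> WlcFit:
    """Fit the pre-rupture stretch with the WLC law; return (Lc, Lp, KL).

    The stretch segment is taken from the tensile part of the retract trace
    between the surface and the event position.  Raises :class:`FitFailure`
    on non-convergence or when fewer than ``min_samples`` points are
    available; callers may fall back to a linear slope estimate.
    """
    sl = curve.segment_slice("retract")
    z, f = curve.z[sl], curve.force[sl]
    mask = (z >= 0) & (z <= event.position) & (f > noise_floor)
    if mask.sum() < min_samples:
        raise FitFailure(f"only {int(mask.sum())} stretch samples (need {min_samples})")
    x = z[mask] - f[mask] / curve.kc  # deflection-corrected extension
    y = f[mask]
    x_max = float(x.max())

    model = Model(wlc_force, independent_vars=["x"])
    params = model.make_params(
        contour_length=dict(value=1.3 * x_max, min=1.001 * x_max, max=100.0 * x_max + 10.0),
        persistence_length=dict(value=0.4, min=1e-4, max=50.0),
    )
    params.add("kbt", value=kbt, vary=False)
    try:
        res = model.fit(y, params, x=x)
    except Exception as exc:  # lmfit raises a zoo of numeric errors
        raise FitFailure(str(exc)) from exc
    if not res.success:
        raise FitFailure(res.message)
    lc = float(res.params["contour_length"].value)
    lp = float(res.params["persistence_length"].value)
    x_rup = _wlc_extension(event.force, lc, lp, kbt)
    kl = float(wlc_stiffness(x_rup, lc, lp, kbt))
    if not np.isfinite(kl) or kl <= 0:
        raise FitFailure(f"non-physical stiffness {kl}")
    return WlcFit(contour_length=lc, persistence_length=lp, kl=kl)


def _linear_slope_kl(curve: ForceCurve, event: RuptureEvent, window: int = 20) -> float:
    """Fallback molecular stiffness: local slope of F vs extension before rupture."""
    sl = curve.segment_slice("retract")
    z, f = curve.z[sl], curve.force[sl]
    idx = np.flatnonzero((z <= event.position) & (z >= 0))
    if idx.size < 3:
        raise FitFailure("too few samples for slope fallback")
    idx = idx[-window:]
    x = z[idx] - f[idx] / curve.kc
    slope = float(np.polyfit(x, f[idx], 1)[0])
    if slope <= 0:
        raise FitFailure(f"non-positive local slope {slope}")
    return slope


def effective_spring_constant(kc: float, kl: float) -> float:
    """Series (compliance-sum) combination (1/kc + 1/kl)^-1, pN/nm."""
    if not (kc > 0 and kl > 0):
        raise ValueError("kc and kl must be positive")
    return 1.0 / (1.0 / kc + 1.0 / kl)


def loading_rate(velocity: float, keff: float) -> float:
    """r = retraction velocity x effective spring constant, pN/s."""
    if not (velocity > 0 and keff > 0):
        raise ValueError("velocity and keff must be positive")
    return velocity * keff


def annotate_loading_rates(curve: ForceCurve, events: list[RuptureEvent]) -> list[RuptureEvent]:
    """Fill ``kl``, ``keff`` and ``loading_rate`` on each event in place.

    The WLC derivative at the rupture force is cross-checked against the
    local linear slope of the final stretch samples: when the two disagree
    by more than a factor 2 (the WLC extrapolation diverges when the fitted
    contour length lands close to the rupture extension) the slope estimate
    is used instead (flagged ``linear_fallback``).  Events where both fail
    keep NaN rates and are excluded from rate-resolved analysis downstream
    (logged).
    """
    for ev in events:
        kl_wlc = kl_slope = None
        try:
            kl_wlc = fit_wlc(curve, ev).kl
        except FitFailure:
            pass
        try:
            kl_slope = _linear_slope_kl(curve, ev)
        except FitFailure:
            pass
        if kl_wlc is not None and (kl_slope is None or 0.5 <= kl_wlc / kl_slope <= 2.0):
            ev.kl, ev.fit_status = kl_wlc, "wlc"
        elif kl_slope is not None:
            ev.kl, ev.fit_status = kl_slope, "linear_fallback"
        else:
            ev.fit_status = "failed"
            logger.info("loading-rate fit failed for %s event %d", ev.curve_id, ev.order)
            continue
        ev.keff = effective_spring_constant(curve.kc, ev.kl)
        ev.loading_rate = loading_rate(curve.velocity, ev.keff)
    return events
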