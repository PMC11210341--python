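"""Association kinetics from dwell-time-resolved binding probabilities.

Bond formation during tip-cell contact follows pseudo-first-order kinetics:
the probability of observing an unbinding event saturates with dwell time t
as

    P(t) = A * (1 - exp(-(t - t0)/tau)),   t > t0   (0 otherwise)

with saturation level A, lag time t0 and characteristic time tau.  Because a
single tethered antibody explores a hemisphere of radius r_eff = linker
length + half antibody length, it presents an effective concentration
Ceff = 1/(N_A * V) with V = (2/3)*pi*r_eff^3, and the bimolecular on-rate
follows as kon = 1/(tau * Ceff).  The second (double-bond) formation rate is
intramolecular -- the already-bound antibody's second Fab finding a
receptor -- and is reported directly as kon_2bonds = 1/tau2 in 1/s from the
same saturating-exponential fit to the double-bond fraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .constants import AVOGADRO, NM3_TO_L

__all__ = [
    "OnRateFit",
    "DwellCurveFit",
    "effective_concentration",
    "dwell_curve",
    "fit_dwell_curve",
    "on_rate",
    "two_bond_on_rate",
]

logger = logging.getLogger(__name__)

LN10 = float(np.log(10.0))


@dataclass
class DwellCurveFit:
    """Parameters of one saturating-exponential dwell-curve fit."""

    A: float           # saturated probability, fraction
    t0: float          # lag time, s
    tau: float         # characteristic time, s
    A_err: float = float("nan")
    tau_err: float = float("nan")
    at_boundary: bool = False


@dataclass
class OnRateFit:
    """Association summary for one condition."""

    A: float
    t0: float
    tau: float                    # s
    ceff: float                   # mol/L
    kon: float                    # 1/(M*s)
    log_kon_err: float = float("nan")
    kon2: float = float("nan")    # 1/s
    log_kon2_err: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.A <= 1):
            raise ValueError(f"A must be in (0, 1], got {self.A}")
        if not (self.tau > 0 and self.ceff > 0 and self.kon > 0):
            raise ValueError("tau, ceff and kon must be positive")


def effective_concentration(linker_length: float, antibody_half_length: float) -> float:
    """Effective molar concentration of one tethered ligand.

    Ceff = 1/(N_A * V) with V the hemisphere volume (2/3)*pi*r_eff^3 and
    r_eff = linker length + half antibody length (nm); result in mol/L.
    """
    if not (linker_length > 0 and antibody_half_length > 0):
        raise ValueError("lengths must be positive")
    r_eff = linker_length + antibody_half_length
    volume_l = (2.0 / 3.0) * np.pi * r_eff**3 * NM3_TO_L
    return 1.0 / (AVOGADRO * volume_l)


def dwell_curve(t, A: float, t0: float, tau: float):
    """P(t) = A*(1 - exp(-(t - t0)/tau)), clipped at zero below the lag."""
    t = np.asarray(t, dtype=float)
    return np.where(t > t0, A * (1.0 - np.exp(-(t - t0) / tau)), 0.0)


def _binomial_weights(probabilities: np.ndarray, n_curves) -> np.ndarray:
    """1/sigma weights from binomial counting error, with a floor so that
    zero-count points keep finite weight."""
    p = np.asarray(probabilities, dtype=float)
    n = np.asarray(n_curves, dtype=float)
    pc = np.clip(p, 1.0 / (n + 2), 1.0 - 1.0 / (n + 2))
    return 1.0 / np.sqrt(pc * (1.0 - pc) / n)


def fit_dwell_curve(
    dwell_times,
    probabilities,
    n_curves=None,
    weights=None,
    fit_t0: bool = False,
) -> DwellCurveFit:
    """Weighted least-squares fit of the saturating-exponential dwell curve.

    Weights default to inverse binomial standard errors when per-point curve
    counts are given, else unweighted.  ``t0`` is constrained >= 0 and held
    at 0 unless ``fit_t0``.  Raises RuntimeError when there is no
    association signal (all probabilities zero) or the fit fails.
    """
    t = np.asarray(dwell_times, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if t.size != p.size or t.size < 4:
        raise ValueError("need >= 4 aligned (dwell, probability) pairs")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.all(p == 0):
        raise RuntimeError("no association signal: all probabilities are zero")
    if weights is None and n_curves is not None:
        weights = _binomial_weights(p, n_curves)

    model = Model(dwell_curve, independent_vars=["t"])
    # the least-squares surface has a flat degenerate valley at tau -> 0
    # (model == constant A); start from several characteristic times and
    # keep the best fit
    res = None
    for tau0 in (float(np.min(t[t > 0])) if np.any(t > 0) else 1e-3,
                 float(np.median(t)), float(np.max(t))):
        params = model.make_params(
            A=dict(value=max(float(p.max()), 1e-3), min=1e-6, max=1.0),
            t0=dict(value=0.0, min=0.0, max=float(t.max()), vary=fit_t0),
            tau=dict(value=max(tau0, 1e-5), min=1e-6, max=100.0 * float(t.max())),
        )
        trial = model.fit(p, params, t=t, weights=weights)
        if trial.success and (res is None or trial.chisqr < res.chisqr):
            res = trial
    if res is None:
        raise RuntimeError("dwell-curve fit failed to converge from any start")
    A = float(res.params["A"].value)
    tau = float(res.params["tau"].value)
    at_boundary = bool(A > 0.999 or tau <= 1.1e-6)
    if at_boundary:
        logger.warning("dwell-curve fit pinned at a parameter bound (A=%.3g, tau=%.3g)", A, tau)
    def _err(name):
        e = res.params[name].stderr
        return float(e) if e is not None else float("nan")
    return DwellCurveFit(A=A, t0=float(res.params["t0"].value), tau=tau,
                         A_err=_err("A"), tau_err=_err("tau"), at_boundary=at_boundary)


def on_rate(tau: float, ceff: float) -> float:
    """Bimolecular on-rate kon = 1/(tau * Ceff), 1/(M*s).

    The unique dimensionally consistent inversion of the pseudo-first-order
    dwell-curve model given the hemisphere effective concentration.
    """
    if not (tau > 0 and ceff > 0):
        raise ValueError("tau and ceff must be positive")
    return 1.0 / (tau * ceff)


def two_bond_on_rate(dwell_times, double_fractions, n_curves=None, weights=None) -> DwellCurveFit:
    """Fit the double-bond fraction vs dwell time; kon_2bonds = 1/tau (1/s).

    Same saturating-exponential form as the binding probability; no
    concentration conversion because second-bond formation is an
    intramolecular step.
    """
    fit = fit_dwell_curve(dwell_times, double_fractions, n_curves=n_curves, weights=weights)
    return fit
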