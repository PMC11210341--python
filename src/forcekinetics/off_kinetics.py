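"""Dissociation kinetics from rupture forces.

Workflow, per condition:

1. :func:`build_pdf` -- the empirical probability density of unbinding
   forces: one Gaussian of unit area per event, centred on its force with
   width equal to the per-event measurement error (post-rupture cantilever
   fluctuation), summed.  A continuous force histogram whose maxima are the
   most probable unbinding forces.
2. :func:`fit_bimodal` -- two-component Gaussian mixture on the raw forces;
   the lower mode collects single-bond ruptures, the upper one double-bond
   (two-Fab) ruptures.
3. :func:`gate_single_bond` -- keep events within mean +/- 2 sd of the first
   Gaussian, isolating single-bond characteristics.
4. :func:`fit_bell_ml` -- maximum-likelihood fit of the Bell-Evans
   rupture-force density to the gated (force, loading-rate) pairs, giving
   koff (zero-force extrapolation) and the barrier width xbeta with
   log-scale standard errors from the observed information.
5. :func:`two_bond_off_rate` / :func:`bond_lifetime` -- whole-molecule
   off-rate koff/1.5 (uncorrelated two-bond Markov reduction) and lifetime
   tau = 1/koff.
6. :func:`predict_double_bond` -- master-equation prediction of the
   double-bond rupture-force density for overlay on the upper branch of the
   force vs loading-rate plot; an independent numerical route cross-checking
   the stochastic simulator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.mixture import GaussianMixture

from .bell import BellParameters, most_probable_force
from .constants import KBT_PN_NM
from .events import RuptureEvent
from .markov import LOAD_SHARING_FACTORS

__all__ = [
    "ForcePDF",
    "BimodalFit",
    "BellFitResult",
    "DoubleBondPrediction",
    "DegenerateFit",
    "build_pdf",
    "fit_bimodal",
    "gate_single_bond",
    "fit_bell_ml",
    "two_bond_off_rate",
    "bond_lifetime",
    "predict_double_bond",
]

logger = logging.getLogger(__name__)

LN10 = float(np.log(10.0))


class DegenerateFit(RuntimeError):
    """Mixture fit collapsed (components coincide or one is empty)."""


@dataclass
class ForcePDF:
    """Empirical unbinding-force density; integrates to the event count."""

    grid: np.ndarray     # force axis, pN
    density: np.ndarray  # per-pN
    n_events: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class BimodalFit:
    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float

    def __post_init__(self) -> None:
        if not (self.mu1 <= self.mu2):
            raise ValueError("components must be ordered mu1 <= mu2")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("component widths must be positive")
        if abs(self.w1 + self.w2 - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")


def build_pdf(events: list[RuptureEvent], grid_step: float = 0.25) -> ForcePDF:
    """Sum one unit-area Gaussian per event; grid spans [0, Fmax + 5*sigma_max]."""
    if len(events) == 0:
        raise ValueError("need at least one event to build a PDF")
    if not (grid_step > 0):
        raise ValueError("grid_step must be positive")
    forces = np.array([e.force for e in events])
    sigmas = np.array([e.noise_sd for e in events])
    top = float(forces.max() + 5.0 * sigmas.max())
    grid = np.arange(0.0, top + grid_step, grid_step)
    dens = np.zeros_like(grid)
    for f, s in zip(forces, sigmas):
        dens += np.exp(-0.5 * ((grid - f) / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
    return ForcePDF(grid=grid, density=dens, n_events=len(events))


def fit_bimodal(
    events_or_forces,
    min_events: int = 20,
    min_weight: float = 0.02,
    random_state: int = 0,
) -> BimodalFit:
    """Two-component Gaussian mixture (ML on raw forces), components ordered.

    Raises :class:`DegenerateFit` when a component carries less than
    ``min_weight`` of the mass or the two components coincide; callers may
    fall back to a unimodal description.
    """
    forces = np.array([e.force for e in events_or_forces]
                      if events_or_forces and isinstance(events_or_forces[0], RuptureEvent)
                      else events_or_forces, dtype=float)
    if forces.size < min_events:
        raise ValueError(f"need >= {min_events} events, got {forces.size}")
    gm = GaussianMixture(n_components=2, n_init=5, random_state=random_state,
                         covariance_type="full")
    gm.fit(forces.reshape(-1, 1))
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    ws = gm.weights_.ravel()
    order = np.argsort(mus)
    mu1, mu2 = mus[order]
    s1, s2 = sds[order]
    w1, w2 = ws[order]
    fit = BimodalFit(mu1=float(mu1), sigma1=float(s1), w1=float(w1),
                     mu2=float(mu2), sigma2=float(s2), w2=float(w2))
    if min(w1, w2) < min_weight:
        raise DegenerateFit(f"minor component weight {min(w1, w2):.3f} < {min_weight}")
    # Ashman's D < 2: the two Gaussians do not form distinct modes
    ashman = np.sqrt(2.0) * abs(mu2 - mu1) / np.sqrt(s1**2 + s2**2)
    if ashman < 2.0:
        raise DegenerateFit(f"components unresolved (Ashman D = {ashman:.2f} < 2)")
    return fit


def gate_single_bond(events: list[RuptureEvent], bimodal: BimodalFit) -> list[RuptureEvent]:
    """Keep events with force within mu1 +/- 2*sigma1 of the first Gaussian."""
    lo = bimodal.mu1 - 2.0 * bimodal.sigma1
    hi = bimodal.mu1 + 2.0 * bimodal.sigma1
    return [e for e in events if lo <= e.force <= hi]


@dataclass
class BellFitResult:
    params: BellParameters
    n_events: int
    loglik: float
    convolved: bool
    warnings: list = field(default_factory=list)

    def most_probable_force(self, loading_rate: float) -> float:
        return most_probable_force(self.params, loading_rate)


def _bell_nll(theta: np.ndarray, forces: np.ndarray, rates: np.ndarray,
              sigmas: np.ndarray | None, floors: np.ndarray | None, kbt: float,
              outlier_fraction: float = 0.0, outlier_span: float = 1.0) -> float:
    """Negative log-likelihood in theta = (ln koff, ln xbeta).

    With ``floors`` given (per-event detection floor, pN) each event's
    density is left-truncated: divided by the survival S(floor | r), which
    conditions the likelihood on the rupture being detectable and removes
    the bias from sub-noise ruptures the detector cannot report.  With
    ``sigmas`` given, the density is additionally convolved with each
    event's Gaussian measurement error via Gauss-Hermite quadrature
    (21 nodes).  ``outlier_fraction`` mixes in a uniform background over
    ``outlier_span`` pN: the Bell density decays doubly exponentially above
    its mode, so a single stray multi-bond event would otherwise dominate
    the objective; the mixture bounds any event's influence.
    """
    koff = np.exp(theta[0])
    xb = np.exp(theta[1])
    b = xb / kbt
    a = koff * kbt / (rates * xb)
    # -log S(floor) = a*(exp(b*floor) - 1)
    log_s_floor = a * (1.0 - np.exp(b * floors)) if floors is not None else 0.0
    if sigmas is None:
        bf = b * forces
        ll = np.log(koff / rates) + bf + a * (1.0 - np.exp(bf)) - log_s_floor
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(21)
        # integrate p(F') * N(F; F', sigma) dF' with F' = F + sigma*node
        fprime = forces[:, None] + sigmas[:, None] * nodes[None, :]
        bf = b * np.clip(fprime, 0.0, None)
        dens = (koff / rates)[:, None] * np.exp(bf + a[:, None] * (1.0 - np.exp(bf)))
        dens = np.where(fprime >= 0, dens, 0.0)
        p = dens @ (weights / np.sqrt(2.0 * np.pi))
        ll = np.log(np.clip(p, 1e-300, None)) - log_s_floor
    if outlier_fraction > 0:
        ll = np.logaddexp(np.log1p(-outlier_fraction) + ll,
                          np.log(outlier_fraction / outlier_span))
    return -float(np.sum(ll))


def _bell_start(forces: np.ndarray, rates: np.ndarray, kbt: float) -> np.ndarray:
    """Moment-based starting point: the Bell-Evans mode is linear in ln r,
    F* = (kBT/xb) * (ln r + ln(xb/(koff*kBT))), so a straight-line fit of
    median force against ln r seeds (ln koff, ln xbeta)."""
    lr = np.log(rates)
    if np.ptp(lr) > 0.1:
        slope, intercept = np.polyfit(lr, forces, 1)
    else:
        slope, intercept = kbt / max(np.median(forces) / 5.0, 0.1), 0.0
    slope = max(slope, 1e-3)
    xb = np.clip(kbt / slope, 1e-3, 100.0)
    # F* = slope*ln(r*xb/(koff*kbt)) => koff = r*xb/kbt * exp(-F/slope)
    koff = np.median(rates * xb / kbt * np.exp(-forces / slope))
    koff = np.clip(koff, 1e-8, 1e6)
    return np.array([np.log(koff), np.log(xb)])


def _numeric_hessian(fun, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x0.size
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            hess[i, j] = hess[j, i] = (
                fun(x0 + ei + ej) - fun(x0 + ei - ej)
                - fun(x0 - ei + ej) + fun(x0 - ei - ej)
            ) / (4.0 * h * h)
    return hess


def fit_bell_ml(
    events: list[RuptureEvent],
    convolve_noise: bool = False,
    kbt: float = KBT_PN_NM,
    min_events: int = 50,
    min_rate_span: float = 5.0,
    outlier_fraction: float = 0.01,
) -> BellFitResult:
    """Maximum-likelihood Bell-Evans fit to gated (force, loading-rate) pairs.

    Optimises over (ln koff, ln xbeta); standard errors on log10 of each
    parameter come from the inverse observed information.  With
    ``convolve_noise=True`` each event's per-event measurement error
    broadens its likelihood contribution (default off: the raw-force
    likelihood).  A uniform background of weight ``outlier_fraction``
    bounds the influence of stray multi-bond events on the doubly
    exponential Bell tail; set it to 0 for the pure likelihood.
    """
    ok = [e for e in events if np.isfinite(e.loading_rate) and e.loading_rate > 0]
    warn: list[str] = []
    if len(ok) < len(events):
        warn.append(f"dropped {len(events) - len(ok)} events without loading rates")
    # the truncated likelihood is defined on F >= floor; events reported
    # below their own detection floor are baseline artefacts
    consistent = [e for e in ok if e.force >= getattr(e, "detection_floor", 0.0)]
    if len(consistent) < len(ok):
        warn.append(f"dropped {len(ok) - len(consistent)} events below their detection floor")
    ok = consistent
    if len(ok) < min_events:
        warn.append(f"only {len(ok)} usable events (< {min_events}); estimates may be unstable")
    if len(ok) < 3:
        raise RuntimeError("too few events with loading rates for a Bell-Evans fit")
    forces = np.array([e.force for e in ok])
    rates = np.array([e.loading_rate for e in ok])
    sigmas = np.array([e.noise_sd for e in ok]) if convolve_noise else None
    floors = np.array([getattr(e, "detection_floor", 0.0) for e in ok])
    if not np.any(floors > 0):
        floors = None
    span = rates.max() / rates.min()
    if span < min_rate_span:
        warn.append(f"loading-rate span {span:.2f}x < {min_rate_span}x; "
                    "koff and xbeta are weakly identified")
    for w in warn:
        logger.warning(w)

    x0 = _bell_start(forces, rates, kbt)
    span = 1.5 * float(forces.max())
    nll_args = (forces, rates, sigmas, floors, kbt, outlier_fraction, span)
    res = minimize(_bell_nll, x0, args=nll_args, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    if not res.success:
        raise RuntimeError(f"Bell-Evans ML fit did not converge: {res.message}")
    theta = res.x
    hess = _numeric_hessian(lambda t: _bell_nll(t, *nll_args), theta)
    se_ln = np.full(2, np.nan)
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.all(d > 0):
            se_ln = np.sqrt(d)
        else:
            warn.append("observed information not positive definite; errors undefined")
    except np.linalg.LinAlgError:
        warn.append("singular observed information; errors undefined")
    params = BellParameters(
        koff=float(np.exp(theta[0])), xbeta=float(np.exp(theta[1])),
        log_koff_err=float(se_ln[0] / LN10), log_xbeta_err=float(se_ln[1] / LN10),
        kbt=kbt,
    )
    return BellFitResult(params=params, n_events=len(ok), loglik=-float(res.fun),
                         convolved=convolve_noise, warnings=warn)


def two_bond_off_rate(koff: float) -> float:
    """Whole-molecule off-rate of two uncorrelated bonds: koff/1.5.

    At zero force the mean lifetime of the two-bond system is
    1/(2*koff) + 1/koff = 1.5/koff, so the effective rate is koff/1.5.
    """
    if not (koff > 0):
        raise ValueError(f"koff must be positive, got {koff}")
    return koff / 1.5


def bond_lifetime(koff: float) -> float:
    """Mean bond lifetime tau = 1/koff, s."""
    if not (koff > 0):
        raise ValueError(f"koff must be positive, got {koff}")
    return 1.0 / koff


@dataclass
class DoubleBondPrediction:
    loading_rate: float
    grid: np.ndarray     # force, pN
    density: np.ndarray  # per-pN, normalised
    mode: float          # most probable double-bond rupture force, pN

    def cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid
        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        return c / c[-1]


def _double_bond_density(bell: BellParameters, loading_rate: float, s: float,
                         n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Master-equation density of the final rupture force under a ramp.

    State occupancies P2 -> P1 -> ruptured with force-dependent rates
    k2 = 2*koff*exp(s*b*F), k1 = koff*exp(b*F); in force space
    dP1/dF = lam2*P2 - lam1*P1 with lam = k/r.  P2 is analytic; P1 is
    integrated with a stiff ODE solver (LSODA, rtol 1e-10) on a uniform
    output grid.  The grid extends far enough above the single-bond mode
    that the truncated tail mass is negligible; the returned density is
    renormalised.
    """
    from scipy.integrate import solve_ivp

    r = loading_rate
    k = bell.koff
    b = bell.xbeta / bell.kbt
    fstar = most_probable_force(bell, r)
    fmax = max(3.0 * fstar + 25.0 * bell.kbt / bell.xbeta, 50.0)
    grid = np.linspace(0.0, fmax, n_grid)
    lam1 = k * np.exp(b * grid) / r

    def rhs(f, y):
        l2 = 2.0 * k * np.exp(s * b * f) / r
        l1 = k * np.exp(b * f) / r
        big_l2 = 2.0 * k * (np.exp(s * b * f) - 1.0) / (r * s * b)
        return [l2 * np.exp(-big_l2) - l1 * y[0]]

    sol = solve_ivp(rhs, (grid[0], grid[-1]), [0.0], t_eval=grid,
                    method="LSODA", rtol=1e-10, atol=1e-18)
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    p1 = np.clip(sol.y[0], 0.0, None)
    dens = lam1 * p1
    mass = np.trapezoid(dens, grid)
    if not (0.99 < mass < 1.01):
        raise RuntimeError(f"master-equation mass {mass:.4f} off unity; integration unreliable")
    return grid, dens / mass


def predict_double_bond(
    bell: BellParameters,
    loading_rates,
    load_sharing: str = "shared",
    n_grid: int = 8000,
) -> list[DoubleBondPrediction]:
    """Predicted double-bond rupture-force density and mode per loading rate.

    Numerical master-equation solution of the same two-state Markov model the
    stochastic simulator draws from -- an independent route used both for
    plot overlays (upper branch of F vs ln r) and as a cross-validation of
    the simulator.
    """
    try:
        s = LOAD_SHARING_FACTORS[load_sharing]
    except KeyError:
        raise ValueError(f"load_sharing must be one of {sorted(LOAD_SHARING_FACTORS)}") from None
    rates = np.atleast_1d(np.asarray(loading_rates, dtype=float))
    if np.any(rates <= 0):
        raise ValueError("loading rates must be positive")
    out = []
    for r in rates:
        grid, dens = _double_bond_density(bell, float(r), s, n_grid)
        if not np.all(np.isfinite(dens)):
            raise RuntimeError(f"master-equation integration failed at r={r}")
        out.append(DoubleBondPrediction(loading_rate=float(r), grid=grid, density=dens,
                                        mode=float(grid[int(np.argmax(dens))])))
    return out
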